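import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   5       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   5       1.458   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A   5       1.400   0.100   0.000  0.60  0.00           C
ATOM      4  C   SER A   5       2.009   1.420   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def write_backbone_pdb(path, residue_numbers, rng=None, chain="A"):
    """Synthetic multi-residue backbone PDB with random but finite coordinates."""
    rng = rng or np.random.default_rng(0)
    lines = []
    serial = 1
    for num in residue_numbers:
        base = rng.normal(scale=10.0, size=3)
        for j, name in enumerate(("N", "CA", "C")):
            x, y, z = base + j * np.array([1.2, 0.3, -0.1])
            lines.append(
                f"ATOM  {serial:5d} {name:>4s} ALA {chain}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
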