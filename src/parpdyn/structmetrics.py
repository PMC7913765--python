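"""Structure reading, atom selections and superposition metrics.

The central quantity here is the *cross-fitted* (two-set) rmsd used to
quantify rigid-body displacement of the PARP-1 HD subdomain relative to the
ART subdomain: one atom set ("set 1") is used to superpose two structures,
after which the rms difference is evaluated over a second set ("set 2")
without moving the coordinates again.  With set 1 = set 2 this reduces to
the conventional rmsd; with set 1 = ART and set 2 = HD it is mainly
sensitive to changes in the relative disposition of the two subdomains
rather than to internal differences within either.

Structures are parsed with :mod:`gemmi`; superposition is a proper-rotation
Kabsch fit implemented via SVD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "AtomSelection",
    "SuperpositionResult",
    "BUILTIN_SELECTIONS",
    "read_structure",
    "parse_selection",
    "resolve_atoms",
    "kabsch_fit",
    "two_set_rmsd",
    "ca_distance",
    "dihedral",
    "glycosidic_chi",
    "superposition_report",
]

BACKBONE_ATOMS = ("N", "CA", "C")

# Water residue names excluded from selections by default.
_WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Å, orthogonal coordinates
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    number: int  # author residue number, 1-based as deposited
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        """Return the atom called *name* after altloc resolution.

        Among alternate locations the highest-occupancy one wins; ties are
        broken by altloc label order (blank sorts first, then 'A', 'B', ...).
        """
        candidates = [a for a in self.atoms if a.name == name]
        if not candidates:
            return None
        return min(candidates, key=lambda a: (-a.occupancy, a.altloc))


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def get_residue(self, number: int) -> Residue | None:
        for res in self.residues:
            if res.number == number:
                return res
        return None


@dataclass
class StructureModel:
    """Chains, residues and atoms of one deposited model (first MODEL only)."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    def get_chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(
            f"chain {chain_id!r} not found in structure {self.id!r} "
            f"(available: {[c.id for c in self.chains]})"
        )

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]


@dataclass(frozen=True)
class AtomSelection:
    """A named, ordered list of (chain id or None, residue range, atom names).

    ``chain`` of ``None`` means "the chain supplied at resolution time",
    which is how the built-in CAT/HD/ART selections are expressed.
    """

    name: str
    items: tuple[tuple[str | None, tuple[int, int], tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: dict[str | None, list[tuple[int, int]]] = {}
        for chain, (start, end), atoms in self.items:
            if start > end:
                raise ValueError(f"selection {self.name!r}: empty range {start}-{end}")
            if not atoms:
                raise ValueError(f"selection {self.name!r}: no atom names in an item")
            for s, e in seen.setdefault(chain, []):
                if start <= e and end >= s:
                    raise ValueError(
                        f"selection {self.name!r}: overlapping ranges "
                        f"{s}-{e} and {start}-{end}"
                    )
            seen[chain].append((start, end))

    def residue_numbers(self) -> list[int]:
        nums: list[int] = []
        for _, (start, end), _ in self.items:
            nums.extend(range(start, end + 1))
        return nums


def _backbone_selection(name: str, ranges: Sequence[tuple[int, int]]) -> AtomSelection:
    return AtomSelection(
        name=name,
        items=tuple((None, rng, BACKBONE_ATOMS) for rng in ranges),
    )


#: Built-in backbone (N, CA, C) selections for the PARP-1 catalytic domain.
#: HD covers the regulatory helical subdomain, ART the ADP-ribosyl-transferase
#: subdomain, CAT their union.
BUILTIN_SELECTIONS: dict[str, AtomSelection] = {
    "HD": _backbone_selection("HD", [(666, 721), (730, 743), (750, 779)]),
    "ART": _backbone_selection("ART", [(790, 936), (939, 1009)]),
    "CAT": _backbone_selection(
        "CAT", [(666, 721), (730, 743), (750, 779), (790, 936), (939, 1009)]
    ),
}


def parse_selection(spec: str, name: str | None = None) -> AtomSelection:
    """Parse a selection string.

    Either the name of a built-in selection (``CAT``, ``HD``, ``ART``) or a
    comma-free grammar ``chain:start-end:atoms`` with multiple items joined
    by ``+``, e.g. ``A:666-721:N,CA,C+A:730-743:N,CA,C``.  A chain field of
    ``*`` defers the chain choice to resolution time.
    """
    if spec in BUILTIN_SELECTIONS:
        return BUILTIN_SELECTIONS[spec]
    items = []
    for part in spec.split("+"):
        fields = part.split(":")
        if len(fields) != 3:
            raise ValueError(f"bad selection item {part!r}; expected chain:start-end:atoms")
        chain = None if fields[0] in ("*", "") else fields[0]
        try:
            start_s, _, end_s = fields[1].partition("-")
            start, end = int(start_s), int(end_s or start_s)
        except ValueError as exc:
            raise ValueError(f"bad residue range in {part!r}") from exc
        atoms = tuple(a.strip() for a in fields[2].split(",") if a.strip())
        items.append((chain, (start, end), atoms))
    return AtomSelection(name=name or spec, items=tuple(items))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Å
    rmsd_fit: float  # Å over set 1 (the fitted pairs)
    n_fit: int
    rmsd_measure: float | None = None  # Å over set 2, transform unchanged
    n_measure: int | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Reading


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens and waters are dropped; occupancies and altloc tags are kept
    (all alternate locations are retained in the model and resolved only
    when atoms are looked up).  Only the first MODEL is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.name.lower()
        fmt = "mmcif" if suffix.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = StructureModel(id=st.name or path.stem)
    gm = st[0]
    for gchain in gm:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            res = Residue(number=gres.seqid.num, name=gres.name)
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                res.atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                        occupancy=float(ga.occ),
                        altloc=ga.altloc or "",
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise ValueError(f"{path}: empty model (no non-water atoms)")
    for chain in model.chains:
        numbers = [r.number for r in chain.residues]
        if len(numbers) != len(set(numbers)):
            # Microheterogeneity: merge duplicate residue numbers, keeping order.
            merged: dict[int, Residue] = {}
            for r in chain.residues:
                if r.number in merged:
                    merged[r.number].atoms.extend(r.atoms)
                else:
                    merged[r.number] = r
            chain.residues = list(merged.values())
    return model


# ---------------------------------------------------------------------------
# Selection resolution


def resolve_atoms(
    model: StructureModel, selection: AtomSelection, chain: str | None = "A"
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    """Resolve *selection* against *model*.

    Returns ``(coords, mask, labels)`` where ``labels`` lists every requested
    ``(chain, residue number, atom name)`` in selection order, ``mask`` flags
    which of them are present, and ``coords`` has one row per label (rows for
    absent atoms are NaN).  Missing residues or atoms are never silently
    skipped.  Altlocs are resolved to the highest-occupancy location.
    """
    labels: list[tuple[str, int, str]] = []
    rows: list[np.ndarray] = []
    present: list[bool] = []
    for item_chain, (start, end), atom_names in selection.items:
        chain_id = item_chain if item_chain is not None else chain
        if chain_id is None:
            raise ValueError(
                f"selection {selection.name!r} defers chain choice but none was given"
            )
        ch = model.get_chain(chain_id)
        for num in range(start, end + 1):
            res = ch.get_residue(num)
            for atom_name in atom_names:
                labels.append((chain_id, num, atom_name))
                atom = res.get_atom(atom_name) if res is not None else None
                if atom is None:
                    rows.append(np.full(3, np.nan))
                    present.append(False)
                else:
                    rows.append(atom.pos)
                    present.append(True)
    mask = np.array(present, dtype=bool)
    if not mask.any():
        raise ValueError(
            f"selection {selection.name!r} resolves to zero atoms on "
            f"structure {model.id!r} chain {chain!r}"
        )
    return np.array(rows, dtype=float), mask, labels


# ---------------------------------------------------------------------------
# Superposition


def _check_fittable(coords: np.ndarray, which: str) -> None:
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"{which}: expected an (n, 3) array, got {coords.shape}")
    if len(coords) < 3:
        raise ValueError(f"{which}: need at least 3 atoms, got {len(coords)}")
    centred = coords - coords.mean(axis=0)
    # Collinear (or coincident) points leave the rotation about the line
    # undetermined; rank of the centred cloud must be >= 2.
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise ValueError(f"{which}: degenerate (collinear) geometry")


def kabsch_fit(moving: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares proper-rotation superposition of *moving* onto *reference*.

    Returns the rotation R and translation t minimising
    ``rms(R @ moving_i + t - reference_i)`` over the paired atoms, with the
    reflection excluded (det R = +1 always; if the unconstrained optimum is a
    reflection, the best proper rotation is returned instead).
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(
            f"paired coordinate lists differ in shape: {moving.shape} vs {reference.shape}"
        )
    _check_fittable(moving, "moving set")
    _check_fittable(reference, "reference set")
    mu_m = moving.mean(axis=0)
    mu_r = reference.mean(axis=0)
    h = (moving - mu_m).T @ (reference - mu_r)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    diff = moving @ rot.T + trans - reference
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(
        rotation=rot, translation=trans, rmsd_fit=rmsd, n_fit=len(moving)
    )


def _paired(
    model_a: StructureModel,
    chain_a: str,
    model_b: StructureModel,
    chain_b: str,
    selection: AtomSelection,
) -> tuple[np.ndarray, np.ndarray, int]:
    coords_a, mask_a, _ = resolve_atoms(model_a, selection, chain_a)
    coords_b, mask_b, _ = resolve_atoms(model_b, selection, chain_b)
    both = mask_a & mask_b
    return coords_a[both], coords_b[both], int(both.sum())


def two_set_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection,
    chain_a: str = "A",
    chain_b: str = "A",
) -> SuperpositionResult:
    """Cross-fitted rmsd: superpose *model_b* onto *model_a* over *fit_sel*,
    then evaluate the rms difference over *measure_sel* without changing the
    coordinates further.

    Pairing uses only atoms present in both structures (intersection of the
    presence masks); paired counts are reported alongside both rmsds.  With
    ``fit_sel == measure_sel`` this is the conventional rmsd.
    """
    ref_fit, mov_fit, n_fit = _paired(model_a, chain_a, model_b, chain_b, fit_sel)
    if n_fit == 0:
        raise ValueError(f"no paired atoms in fit set {fit_sel.name!r}")
    result = kabsch_fit(mov_fit, ref_fit)
    ref_meas, mov_meas, n_meas = _paired(model_a, chain_a, model_b, chain_b, measure_sel)
    if n_meas == 0:
        raise ValueError(f"no paired atoms in measure set {measure_sel.name!r}")
    diff = result.apply(mov_meas) - ref_meas
    result.rmsd_measure = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    result.n_measure = n_meas
    return result


# ---------------------------------------------------------------------------
# Distances and torsions


def ca_distance(model: StructureModel, chain: str, res_i: int, res_j: int) -> float:
    """Cα–Cα Euclidean distance in Å between two residues of one chain."""
    ch = model.get_chain(chain)
    positions = []
    for num in (res_i, res_j):
        res = ch.get_residue(num)
        atom = res.get_atom("CA") if res is not None else None
        if atom is None:
            raise ValueError(f"residue {num} of chain {chain} has no CA atom")
        positions.append(atom.pos)
    return float(np.linalg.norm(positions[0] - positions[1]))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 to p3, a clockwise rotation of
    the far bond relative to the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    for a, b, name in ((p1, p2, "p1/p2"), (p2, p3, "p2/p3"), (p3, p4, "p3/p4")):
        if np.linalg.norm(b - a) < 1e-10:
            raise ValueError(f"degenerate geometry: coincident points {name}")
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1  # projections perpendicular to the central bond
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(w) < 1e-12:
        raise ValueError("degenerate geometry: collinear consecutive bonds")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


#: Atom quartet defining the purine glycosidic torsion χ.
CHI_PURINE_ATOMS = ("O4'", "C1'", "N9", "C4")


def _find_ligand(chain: Chain, residue_name: str | None, residue_number: int | None) -> Residue:
    for res in chain.residues:
        if residue_number is not None and res.number != residue_number:
            continue
        if residue_name is not None and res.name != residue_name:
            continue
        if residue_name is None and residue_number is None:
            continue
        return res
    raise ValueError(
        f"ligand residue (name={residue_name!r}, number={residue_number!r}) "
        f"not found in chain {chain.id}"
    )


def glycosidic_chi(
    model: StructureModel,
    residue_name: str | None = None,
    residue_number: int | None = None,
    chains: Iterable[str] | None = None,
    average: bool = True,
) -> float | dict[str, float]:
    """Glycosidic torsion χ of a purine nucleoside ligand.

    Uses the O4′–C1′–N9–C4 atom convention.  With ``average=True`` (default)
    the circular mean over the requested chains is returned; otherwise a
    per-chain mapping.
    """
    chain_ids = list(chains) if chains is not None else model.chain_ids()
    per_chain: dict[str, float] = {}
    for cid in chain_ids:
        ch = model.get_chain(cid)
        try:
            res = _find_ligand(ch, residue_name, residue_number)
        except ValueError:
            continue
        positions = []
        missing = []
        for name in CHI_PURINE_ATOMS:
            atom = res.get_atom(name)
            if atom is None:
                missing.append(name)
            else:
                positions.append(atom.pos)
        if missing:
            raise ValueError(
                f"ligand {res.name}{res.number} in chain {cid} lacks χ atoms: {missing}"
            )
        per_chain[cid] = dihedral(*positions)
    if not per_chain:
        raise ValueError("ligand residue not found in any requested chain")
    if not average:
        return per_chain
    angles = np.radians(list(per_chain.values()))
    mean = math.degrees(math.atan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))
    if mean <= -180.0:
        mean += 360.0
    return mean


# ---------------------------------------------------------------------------
# Reporting


def superposition_report(
    reference: StructureModel,
    others: Sequence[tuple[StructureModel, str]],
    pairs: Sequence[tuple[str, str]] = (
        ("CAT", "CAT"),
        ("ART", "ART"),
        ("HD", "HD"),
        ("ART", "HD"),
        ("HD", "ART"),
    ),
    chain_ref: str = "A",
) -> list[dict]:
    """Tabulate fit/measure rmsds of several structures against one reference.

    Returns one row per (structure, fit set, measure set) with paired atom
    counts, suitable for TSV export.
    """
    rows = []
    for model, chain in others:
        for fit_name, measure_name in pairs:
            fit_sel = BUILTIN_SELECTIONS.get(fit_name) or parse_selection(fit_name)
            meas_sel = BUILTIN_SELECTIONS.get(measure_name) or parse_selection(measure_name)
            res = two_set_rmsd(
                reference, model, fit_sel, meas_sel, chain_a=chain_ref, chain_b=chain
            )
            rows.append(
                {
                    "structure": model.id,
                    "chain": chain,
                    "fit_set": fit_name,
                    "measure_set": measure_name,
                    "n_fit": res.n_fit,
                    "n_measure": res.n_measure,
                    "rmsd_fit": round(res.rmsd_fit, 4),
                    "rmsd_measure": round(res.rmsd_measure, 4),
                }
            )
    return rows
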