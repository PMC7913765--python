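"""Chemical-shift perturbation (CSP) analysis of backbone amide groups.

The CSP between two sample conditions combines the amide ¹H and ¹⁵N shift
differences as

    CSP = sqrt( Δδ(¹H)² + (Δδ(¹⁵N) / 5)² )   [ppm]

with the conventional factor of 5 down-weighting the ¹⁵N dimension.  For
display, profiles from several samples are normalised against the single
largest CSP across all of them (CSP_max); the colour ramp is truncated at
0.2·CSP_max so a handful of very large, uninformative perturbations at the
binding site do not dominate the mapping, and every value at or above the
threshold saturates at colour value 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_ASSIGNED",
    "STATUS_PROLINE",
    "STATUS_UNASSIGNED",
    "STATUS_UNOBSERVED_LOOP",
    "ShiftTable",
    "CSPProfile",
    "read_shift_table",
    "compute_csp",
    "normalise_profiles",
    "export_residue_attributes",
]

STATUS_ASSIGNED = "assigned"
STATUS_PROLINE = "proline"
STATUS_UNASSIGNED = "overlapped/unassigned"
STATUS_UNOBSERVED_LOOP = "unobserved-loop"

_VALID_STATUS = {STATUS_ASSIGNED, STATUS_PROLINE, STATUS_UNASSIGNED, STATUS_UNOBSERVED_LOOP}

# Sanity bounds for assigned amides (warn, never fail).
_H_BOUNDS = (5.0, 13.0)
_N_BOUNDS = (95.0, 140.0)

#: ¹⁵N scaling constant of the CSP formula; exposed for other conventions.
DEFAULT_N15_SCALE = 5.0


@dataclass
class ShiftTable:
    """Per-residue amide ¹H/¹⁵N chemical shifts for one sample condition."""

    label: str
    data: pd.DataFrame  # columns: residue, code, dH, dN, status
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"residue", "code", "dH", "dN", "status"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"shift table {self.label!r} lacks columns {sorted(missing)}")
        if self.data["residue"].duplicated().any():
            dupes = self.data.loc[self.data["residue"].duplicated(), "residue"].tolist()
            raise ValueError(f"duplicate residue rows in {self.label!r}: {dupes}")
        bad = set(self.data["status"]) - _VALID_STATUS
        if bad:
            raise ValueError(f"unknown status flags in {self.label!r}: {sorted(bad)}")
        assigned = self.data[self.data["status"] == STATUS_ASSIGNED]
        out_h = assigned[(assigned["dH"] < _H_BOUNDS[0]) | (assigned["dH"] > _H_BOUNDS[1])]
        out_n = assigned[(assigned["dN"] < _N_BOUNDS[0]) | (assigned["dN"] > _N_BOUNDS[1])]
        for _, row in pd.concat([out_h, out_n]).iterrows():
            self.warnings.append(
                f"{self.label}: residue {int(row.residue)} shift outside amide "
                f"sanity bounds (dH={row.dH}, dN={row.dN})"
            )

    def assigned(self) -> pd.DataFrame:
        return self.data[self.data["status"] == STATUS_ASSIGNED]


@dataclass
class CSPProfile:
    """Per-residue CSPs plus the shared normalisation for colour mapping."""

    label: str
    data: pd.DataFrame  # columns: residue, csp, status  (csp NaN when not computed)
    csp_max: float = float("nan")
    threshold: float = float("nan")  # 0.2 * csp_max

    def colour_values(self) -> pd.Series:
        """min(CSP / threshold, 1) per residue; NaN where CSP is undefined."""
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise ValueError(
                f"profile {self.label!r} has no usable colour threshold; "
                "run normalise_profiles first"
            )
        return np.minimum(self.data["csp"] / self.threshold, 1.0)


# ---------------------------------------------------------------------------
# Readers

_SPARKY_RE = re.compile(r"^([A-Z])(\d+)N-?H?N?$", re.IGNORECASE)


def _finish_table(label: str, rows: list[dict]) -> ShiftTable:
    if not rows:
        raise ValueError(f"{label}: no residue rows parsed")
    df = pd.DataFrame(rows)
    # Prolines have no backbone amide: flag and drop their shifts.
    is_pro = df["code"].str.upper().isin(["P", "PRO"])
    df.loc[is_pro, "status"] = STATUS_PROLINE
    df.loc[is_pro, ["dH", "dN"]] = np.nan
    df = df.sort_values("residue", kind="stable").reset_index(drop=True)
    return ShiftTable(label=label, data=df[["residue", "code", "dH", "dN", "status"]])


def _read_tsv(path: Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    aliases = {"residue": "residue", "res": "residue", "code": "code", "aa": "code",
               "dh": "dH", "d1h": "dH", "h": "dH", "dn": "dN", "d15n": "dN", "n": "dN",
               "status": "status"}
    df = df.rename(columns={c: aliases[c] for c in df.columns if c in aliases})
    for col in ("residue", "dH", "dN"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing shift column {col!r}")
    if "code" not in df.columns:
        df["code"] = "X"
    if "status" not in df.columns:
        df["status"] = STATUS_ASSIGNED
    rows = []
    for _, r in df.iterrows():
        status = str(r["status"]).strip()
        d_h, d_n = float(r["dH"]), float(r["dN"])
        if status == STATUS_ASSIGNED and (np.isnan(d_h) or np.isnan(d_n)):
            status = STATUS_UNASSIGNED
        rows.append({"residue": int(r["residue"]), "code": str(r["code"]).strip(),
                     "dH": d_h, "dN": d_n, "status": status})
    return rows


def _read_sparky(path: Path) -> list[dict]:
    """Sparky resonance-list lines like ``G888N-H  110.55  8.22``."""
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith(("assignment", "#")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}: unparseable Sparky line {line!r}")
        m = _SPARKY_RE.match(parts[0])
        if not m:
            raise ValueError(f"{path}: unparseable Sparky assignment {parts[0]!r}")
        code, num = m.group(1).upper(), int(m.group(2))
        w1, w2 = float(parts[1]), float(parts[2])
        # w1 is the 15N dimension, w2 the 1H dimension in [15N,1H] lists.
        rows.append({"residue": num, "code": code, "dH": w2, "dN": w1,
                     "status": STATUS_ASSIGNED})
    return rows


def _read_nmrstar_loop(path: Path) -> list[dict]:
    """Minimal NMR-STAR chemical-shift-loop reader.

    Understands a single ``loop_`` whose tags include the ``_Atom_chem_shift``
    columns ``Seq_ID`` (or ``Comp_index_ID``), ``Comp_ID``, ``Atom_ID`` and
    ``Val``, which covers deposited amide shift loops.
    """
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    tags: list[str] = []
    data_rows: list[list[str]] = []
    in_loop = False
    reading_data = False
    for ln in lines:
        if ln == "loop_":
            in_loop, reading_data, tags = True, False, []
            continue
        if not in_loop:
            continue
        if ln.startswith("_"):
            if reading_data:  # a new tag block after data ends the loop we read
                break
            tags.append(ln.split(".")[-1] if "." in ln else ln.lstrip("_"))
            continue
        if ln in ("stop_",):
            if any(t.lower() in ("val", "chem_shift_val") for t in tags) and data_rows:
                break
            in_loop, reading_data = False, False
            data_rows = []
            continue
        if not ln or ln.startswith("#"):
            continue
        reading_data = True
        data_rows.append(ln.split())
    if not tags or not data_rows:
        raise ValueError(f"{path}: no chemical-shift loop found")
    idx = {t.lower(): i for i, t in enumerate(tags)}

    def col(row: list[str], *names: str) -> str:
        for n in names:
            if n in idx and idx[n] < len(row):
                return row[idx[n]]
        raise ValueError(f"{path}: loop lacks required tag(s) {names}")

    shifts: dict[int, dict] = {}
    for row in data_rows:
        atom = col(row, "atom_id").upper()
        if atom not in ("H", "HN", "N"):
            continue
        num = int(col(row, "seq_id", "comp_index_id"))
        comp = col(row, "comp_id")
        val = float(col(row, "val", "chem_shift_val"))
        entry = shifts.setdefault(num, {"residue": num, "code": comp,
                                        "dH": np.nan, "dN": np.nan,
                                        "status": STATUS_ASSIGNED})
        entry["dH" if atom in ("H", "HN") else "dN"] = val
    rows = []
    for entry in shifts.values():
        code = entry["code"]
        entry["code"] = _THREE_TO_ONE.get(code.upper(), code) if len(code) == 3 else code
        if np.isnan(entry["dH"]) or np.isnan(entry["dN"]):
            if entry["code"].upper() not in ("P", "PRO"):
                entry["status"] = STATUS_UNASSIGNED
        rows.append(entry)
    return rows


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_DIALECTS = {
    "tsv": _read_tsv,
    "sparky-list": _read_sparky,
    "nmrstar-loop-subset": _read_nmrstar_loop,
}


def read_shift_table(path: str | Path, dialect: str = "tsv", label: str | None = None) -> ShiftTable:
    """Read a per-residue amide shift table in one of the supported dialects."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    rows = _DIALECTS[dialect](path)
    return _finish_table(label or path.stem, rows)


# ---------------------------------------------------------------------------
# CSP computation


def compute_csp(
    reference: ShiftTable,
    perturbed: ShiftTable,
    n15_scale: float = DEFAULT_N15_SCALE,
) -> CSPProfile:
    """Per-residue CSP between two conditions sharing a numbering frame.

    A CSP is computed only where both residues are assigned; residues
    assigned in only one condition are carried with status
    "overlapped/unassigned" (no CSP — zero would fabricate agreement), and
    proline / unobserved-loop flags propagate.  The result is symmetric in
    its two arguments.
    """
    merged = reference.data.merge(
        perturbed.data, on="residue", how="outer", suffixes=("_ref", "_per")
    ).sort_values("residue").reset_index(drop=True)
    csp = np.sqrt(
        (merged["dH_ref"] - merged["dH_per"]) ** 2
        + ((merged["dN_ref"] - merged["dN_per"]) / n15_scale) ** 2
    )
    status = []
    for _, row in merged.iterrows():
        s_ref = row.get("status_ref")
        s_per = row.get("status_per")
        if s_ref == STATUS_ASSIGNED and s_per == STATUS_ASSIGNED:
            status.append(STATUS_ASSIGNED)
        elif STATUS_PROLINE in (s_ref, s_per):
            status.append(STATUS_PROLINE)
        elif STATUS_UNOBSERVED_LOOP in (s_ref, s_per):
            status.append(STATUS_UNOBSERVED_LOOP)
        else:
            status.append(STATUS_UNASSIGNED)
    status = pd.Series(status, index=merged.index)
    csp = csp.where(status == STATUS_ASSIGNED)
    if not (status == STATUS_ASSIGNED).any():
        raise ValueError(
            f"no residues assigned in both {reference.label!r} and {perturbed.label!r}"
        )
    data = pd.DataFrame(
        {"residue": merged["residue"].astype(int), "csp": csp, "status": status}
    )
    profile = CSPProfile(label=f"{perturbed.label} vs {reference.label}", data=data)
    profile.csp_max = float(np.nanmax(csp.to_numpy()))
    profile.threshold = 0.2 * profile.csp_max
    return profile


def normalise_profiles(profiles: list[CSPProfile]) -> list[CSPProfile]:
    """Apply one global CSP_max (and threshold 0.2·CSP_max) to all profiles."""
    if not profiles:
        raise ValueError("no profiles to normalise")
    finite = [
        float(np.nanmax(p.data["csp"].to_numpy()))
        for p in profiles
        if np.isfinite(p.data["csp"]).any()
    ]
    if not finite:
        raise ValueError("no finite CSP values in any profile")
    csp_max = max(finite)
    if csp_max == 0.0:
        raise ValueError("all CSPs are zero; colour normalisation is undefined")
    for p in profiles:
        p.csp_max = csp_max
        p.threshold = 0.2 * csp_max
    return profiles


def export_residue_attributes(profile: CSPProfile, path: str | Path) -> Path:
    """Write a viewer attribute file: residue, raw CSP, colour value, status.

    One line per residue in ascending residue order; residues without a CSP
    (prolines, unassigned, unobserved loop) carry their status tag and no
    colour value.
    """
    path = Path(path)
    colours = profile.colour_values()
    lines = [f"# CSP attributes for {profile.label}",
             f"# csp_max={profile.csp_max:.6g} ppm threshold={profile.threshold:.6g} ppm",
             "residue\tcsp_ppm\tcolour\tstatus"]
    for i, row in profile.data.iterrows():
        if row["status"] == STATUS_ASSIGNED and np.isfinite(row["csp"]):
            lines.append(
                f"{int(row['residue'])}\t{row['csp']:.6f}\t{colours[i]:.6f}\t{row['status']}"
            )
        else:
            lines.append(f"{int(row['residue'])}\t.\t.\t{row['status']}")
    path.write_text("\n".join(lines) + "\n")
    return path
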