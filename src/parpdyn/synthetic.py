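"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical and geometric structure of the real
measurements — two rigid subdomains joined at a hinge, shift tables with a
localised perturbation of known magnitude, mono-exponential relaxation
decays with Gaussian noise at the experimental delay schedules, and
first-order exchange time courses — while recording the planted parameters
so that every downstream operation can be scored exactly.  All generators
are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exchange import (
    CLASS_FAST,
    CLASS_UNOBSERVED,
    CLEANEX_RATE_FLOOR_PER_S,
    REALTIME_HOURS,
    SECONDS_PER_HOUR,
    ExchangeRecord,
    classify_slow,
)
from .relaxation import T1_DELAYS_MS, RelaxationSeries
from .shift_analysis import (
    STATUS_ASSIGNED,
    STATUS_PROLINE,
    DEFAULT_N15_SCALE,
    ShiftTable,
)
from .structmetrics import Atom, AtomSelection, Chain, Residue, StructureModel

import pandas as pd

__all__ = [
    "SyntheticTruth",
    "make_two_domain_pair",
    "make_shift_pair",
    "make_decay_series",
    "make_exchange_profile",
]


@dataclass
class SyntheticTruth:
    """Planted parameters of one synthetic scenario."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def write_manifest(self, path: str | Path) -> Path:
        """Flat key-value text manifest (deterministic ordering)."""
        path = Path(path)
        lines = [f"scenario\t{self.scenario}", f"seed\t{self.seed}"]
        for key in sorted(self.params):
            val = self.params[key]
            if isinstance(val, np.ndarray):
                val = " ".join(f"{v:.12g}" for v in np.asarray(val).ravel())
            lines.append(f"{key}\t{val}")
        path.write_text("\n".join(lines) + "\n")
        return path


# ---------------------------------------------------------------------------
# Ideal-helix geometry

# Ideal alpha-helix: 1.5 Å rise and 100 deg twist per residue; backbone atoms
# placed on coaxial cylinders with fixed phase/height offsets.  Geometrically
# plausible, rigid, and entirely sufficient for superposition arithmetic.
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
_ATOM_PARAMS = {  # name -> (radius Å, phase offset deg, z offset Å)
    "N": (1.58, -28.0, -0.70),
    "CA": (2.28, 0.0, 0.00),
    "C": (1.68, 27.0, 0.55),
}


def _helix_residue(index: int, origin: np.ndarray, axis_frame: np.ndarray) -> list[Atom]:
    """Backbone atoms of residue *index* of an ideal helix.

    *axis_frame* is a 3x3 matrix whose columns are the local x, y and helix
    axis (z) directions; *origin* is the helix start.
    """
    atoms = []
    for name, (radius, phase, dz) in _ATOM_PARAMS.items():
        angle = math.radians(_HELIX_TWIST_DEG * index + phase)
        local = np.array(
            [radius * math.cos(angle), radius * math.sin(angle), _HELIX_RISE * index + dz]
        )
        atoms.append(Atom(name=name, element=name[0], pos=origin + axis_frame @ local))
    return atoms


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _build_model(model_id: str, residues: list[Residue]) -> StructureModel:
    return StructureModel(id=model_id, chains=[Chain(id="A", residues=residues)])


def make_two_domain_pair(
    n_res_fixed: int = 30,
    n_res_mobile: int = 30,
    hinge_angle: float = 10.0,
    kink_angle: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, StructureModel, SyntheticTruth]:
    """Two-subdomain toy: a reference model and a copy with the mobile
    subdomain rigidly rotated about a hinge.

    Both models share a fixed helix (residues 1..n_res_fixed); the mobile
    helix (the following residues) is rotated by *hinge_angle* degrees about
    an axis through the hinge point in the displaced copy.  A non-zero
    *kink_angle* additionally kinks the displaced mobile helix at its
    midpoint, mimicking a helix kink at the point of a steric clash.  The
    exact applied transform (rotation matrix and hinge point) is recorded in
    the truth object.
    """
    if n_res_fixed < 10 or n_res_mobile < 10:
        raise ValueError("need at least 10 residues per subdomain")
    for name, angle in (("hinge_angle", hinge_angle), ("kink_angle", kink_angle)):
        if not 0.0 <= angle <= 60.0:
            raise ValueError(f"{name} must be in [0, 60] degrees, got {angle}")

    identity = np.eye(3)
    fixed_origin = np.zeros(3)
    # Mobile helix: offset sideways and along z from the fixed one.
    mobile_origin = np.array([12.0, 0.0, _HELIX_RISE * n_res_fixed + 4.0])
    hinge_point = np.array([6.0, 0.0, _HELIX_RISE * n_res_fixed + 2.0])
    hinge_axis = np.array([0.0, 1.0, 0.0])

    def build(displaced: bool) -> StructureModel:
        residues = []
        for i in range(n_res_fixed):
            residues.append(
                Residue(number=i + 1, name="ALA", atoms=_helix_residue(i, fixed_origin, identity))
            )
        rot = _rotation_about_axis(hinge_axis, hinge_angle) if displaced else identity
        kink_rot = _rotation_about_axis(
            np.array([1.0, 0.0, 0.0]), kink_angle
        ) if (displaced and kink_angle) else identity
        kink_index = n_res_mobile // 2
        kink_point = mobile_origin + np.array([0.0, 0.0, _HELIX_RISE * kink_index])
        for i in range(n_res_mobile):
            atoms = _helix_residue(i, mobile_origin, identity)
            for atom in atoms:
                pos = atom.pos
                if displaced and kink_angle and i >= kink_index:
                    pos = kink_rot @ (pos - kink_point) + kink_point
                if displaced:
                    pos = rot @ (pos - hinge_point) + hinge_point
                atom.pos = pos
            residues.append(Residue(number=n_res_fixed + i + 1, name="ALA", atoms=atoms))
        return _build_model("synthetic-displaced" if displaced else "synthetic-reference", residues)

    reference = build(displaced=False)
    displaced = build(displaced=True)
    rot = _rotation_about_axis(hinge_axis, hinge_angle)
    truth = SyntheticTruth(
        scenario="two_domain_pair",
        seed=seed,
        params={
            "n_res_fixed": n_res_fixed,
            "n_res_mobile": n_res_mobile,
            "hinge_angle_deg": hinge_angle,
            "kink_angle_deg": kink_angle,
            "hinge_point": hinge_point,
            "hinge_axis": hinge_axis,
            "rotation": rot,
            # translation of the equivalent (R, t) affine map x -> R x + t
            "translation": hinge_point - rot @ hinge_point,
        },
    )
    return reference, displaced, truth


def fixed_selection(truth: SyntheticTruth) -> AtomSelection:
    n = truth.params["n_res_fixed"]
    return AtomSelection("fixed", ((None, (1, n), ("N", "CA", "C")),))


def mobile_selection(truth: SyntheticTruth) -> AtomSelection:
    n_fixed = truth.params["n_res_fixed"]
    n_mob = truth.params["n_res_mobile"]
    return AtomSelection("mobile", ((None, (n_fixed + 1, n_fixed + n_mob), ("N", "CA", "C")),))


def analytic_rms_displacement(truth: SyntheticTruth, coords: np.ndarray) -> float:
    """RMS displacement of *coords* under the recorded hinge transform."""
    rot = truth.params["rotation"]
    trans = truth.params["translation"]
    moved = coords @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - coords) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Shift tables


def make_shift_pair(
    n_res: int = 100,
    site: int = 50,
    amplitude: float = 1.0,
    decay_length: float = 3.0,
    seed: int = 0,
    proline_fraction: float = 0.0,
    first_residue: int = 1,
) -> tuple[ShiftTable, ShiftTable, SyntheticTruth]:
    """A reference shift table and a copy with a localised perturbation.

    The planted CSP at residue r is amplitude·exp(−|r − site|/decay_length);
    each residue's perturbation is split between the ¹H and ¹⁵N dimensions
    at a random angle, with the ¹⁵N component pre-multiplied by the CSP
    scaling constant so the planted CSP magnitude is exact.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    residues = np.arange(first_residue, first_residue + n_res)
    if not (residues[0] <= site <= residues[-1]):
        raise ValueError(f"site {site} outside residue range {residues[0]}-{residues[-1]}")
    rng = np.random.default_rng(seed)
    d_h = rng.uniform(7.0, 9.5, n_res)
    d_n = rng.uniform(105.0, 130.0, n_res)
    codes = rng.choice(list("ACDEFGHIKLMNQRSTVWY"), n_res)  # no P yet
    n_pro = int(round(proline_fraction * n_res))
    if n_pro:
        pro_idx = rng.choice(n_res, size=n_pro, replace=False)
        codes[pro_idx] = "P"
    magnitudes = amplitude * np.exp(-np.abs(residues - site) / decay_length)
    angles = rng.uniform(0.0, 2.0 * math.pi, n_res)
    delta_h = magnitudes * np.cos(angles)
    delta_n = magnitudes * np.sin(angles) * DEFAULT_N15_SCALE

    def table(label: str, dh: np.ndarray, dn: np.ndarray) -> ShiftTable:
        df = pd.DataFrame(
            {
                "residue": residues,
                "code": codes,
                "dH": dh,
                "dN": dn,
                "status": STATUS_ASSIGNED,
            }
        )
        is_pro = df["code"] == "P"
        df.loc[is_pro, "status"] = STATUS_PROLINE
        df.loc[is_pro, ["dH", "dN"]] = np.nan
        return ShiftTable(label=label, data=df)

    reference = table("synthetic-reference", d_h, d_n)
    perturbed = table("synthetic-perturbed", d_h + delta_h, d_n + delta_n)
    planted = magnitudes.copy()
    planted[codes == "P"] = np.nan
    truth = SyntheticTruth(
        scenario="shift_pair",
        seed=seed,
        params={
            "site": site,
            "amplitude_ppm": amplitude,
            "decay_length_res": decay_length,
            "planted_csp_ppm": planted,
            "residues": residues,
        },
    )
    return reference, perturbed, truth


# ---------------------------------------------------------------------------
# Relaxation decays


def make_decay_series(
    t_true_ms: float,
    delays_ms: Sequence[float] = T1_DELAYS_MS,
    noise_sigma: float = 0.02,
    n_replicates: int = 1,
    seed: int = 0,
    kind: str = "T1",
) -> tuple[list[RelaxationSeries], SyntheticTruth]:
    """Mono-exponential decays I(t) = exp(−t/T) + Gaussian noise.

    *noise_sigma* is expressed as a fraction of I0 = 1; duplicate delays in
    the schedule are preserved as independent noisy observations.  One
    series per replicate, residue numbers 1..n_replicates.
    """
    if t_true_ms <= 0:
        raise ValueError("decay time must be positive")
    rng = np.random.default_rng(seed)
    delays = np.asarray(delays_ms, dtype=float)
    series = []
    for rep in range(n_replicates):
        clean = np.exp(-delays / t_true_ms)
        noisy = clean + rng.normal(0.0, noise_sigma, size=delays.shape) if noise_sigma else clean
        series.append(
            RelaxationSeries(
                residue=rep + 1,
                kind=kind,
                delays_ms=delays,
                intensities=noisy,
                noise=noise_sigma,
            )
        )
    truth = SyntheticTruth(
        scenario="decay_series",
        seed=seed,
        params={
            "t_true_ms": t_true_ms,
            "noise_sigma": noise_sigma,
            "n_replicates": n_replicates,
            "kind": kind,
        },
    )
    return series, truth


# ---------------------------------------------------------------------------
# Exchange profiles


def make_exchange_profile(
    rates_per_h: Mapping[int, float],
    time_points_h: tuple[float, float, float] = REALTIME_HOURS,
    cleanex_window_per_s: tuple[float, float] = (CLEANEX_RATE_FLOOR_PER_S, math.inf),
    noise_sigma: float = 0.0,
    seed: int = 0,
    detection_threshold: float = 1e-3,
) -> tuple[list[ExchangeRecord], SyntheticTruth]:
    """Exchange observables for per-residue first-order rates (h⁻¹).

    Real-time intensities are exp(−k·t) at the three time points (plus
    optional Gaussian noise, floored at zero); a CLEANEX signal is present
    iff the rate falls inside *cleanex_window_per_s*.  Ground-truth classes
    are computed analytically from the noiseless observables and stored.
    """
    for res, k in rates_per_h.items():
        if k <= 0:
            raise ValueError(f"residue {res}: exchange rate must be positive")
    rng = np.random.default_rng(seed)
    records: list[ExchangeRecord] = []
    truth_classes: dict[int, str] = {}
    noise = noise_sigma if noise_sigma else detection_threshold / 3.0
    thr = 3.0 * noise
    k_lo, k_hi = cleanex_window_per_s
    for res in sorted(rates_per_h):
        k_h = rates_per_h[res]
        k_s = k_h / SECONDS_PER_HOUR
        in_window = k_lo <= k_s <= k_hi
        clean_rt = np.exp(-k_h * np.asarray(time_points_h))
        # Analytic truth from the noiseless observables and the same rules.
        if in_window:
            truth_classes[res] = CLASS_FAST
        else:
            floored = np.where(clean_rt > thr, clean_rt, 0.0)
            if floored[0] > 0:
                truth_classes[res] = classify_slow(*floored)
            else:
                truth_classes[res] = CLASS_UNOBSERVED
        cleanex_val: float | None = 1.0 if in_window else None
        rt = clean_rt.copy()
        if noise_sigma:
            rt = np.maximum(rt + rng.normal(0.0, noise_sigma, size=rt.shape), 0.0)
            if cleanex_val is not None:
                cleanex_val = max(cleanex_val + rng.normal(0.0, noise_sigma), 0.0)
        records.append(
            ExchangeRecord(
                residue=res,
                cleanex=cleanex_val,
                reference=1.0,
                i3=float(rt[0]),
                i12=float(rt[1]),
                i39=float(rt[2]),
                noise=noise,
            )
        )
    truth = SyntheticTruth(
        scenario="exchange_profile",
        seed=seed,
        params={
            "rates_per_h": dict(rates_per_h),
            "classes": truth_classes,
            "noise_sigma": noise_sigma,
            "cleanex_window_per_s": cleanex_window_per_s,
        },
    )
    return records, truth
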