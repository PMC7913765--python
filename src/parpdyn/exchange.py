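"""Amide NH solvent-exchange normalisation and classification.

Two complementary experiments cover the very wide range of amide exchange
rates.  CLEANEX-PM detects the fastest exchangers (rates between roughly
the amide ¹H R1, ~0.5 s⁻¹, and the random-coil ceiling of ~10 s⁻¹ at pH 7
and 25 °C); its intensities are made comparable between samples by dividing
by a per-sample factor computed over reference residues in the unstructured
N-terminus (Val657, Gly660, Thr661 by default).  Slow exchangers are
followed in real time after dissolution in ²H₂O, and classified from the
normalised intensities at 3, 12 and 39 h:

    light blue  (slow-light) : I(3h) − I(12h) > 0.5·I(3h)
    medium blue (slow-medium): not light and I(12h) − I(39h) > 0.25·I(12h)
    dark blue   (slow-dark)  : not light and I(12h) − I(39h) ≤ 0.25·I(12h)

Equality at a boundary goes to the slower class (the conservative
protection call).  Residues with a CLEANEX signal are "fast" (red);
residues with no signal in either experiment are "unobserved" (white) —
many of these fall in the NMR blind window of roughly 0.5–500 s⁻¹, too
slow for equilibrium methods yet too fast for a real-time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_FAST",
    "CLASS_SLOW_LIGHT",
    "CLASS_SLOW_MEDIUM",
    "CLASS_SLOW_DARK",
    "CLASS_UNOBSERVED",
    "DEFAULT_REFERENCE_RESIDUES",
    "ExchangeRecord",
    "cleanex_factor",
    "normalise_cleanex",
    "classify_slow",
    "classify_residue",
    "simulate_class_from_rate",
    "class_table",
]

CLASS_FAST = "fast"  # red
CLASS_SLOW_LIGHT = "slow-light"  # light blue
CLASS_SLOW_MEDIUM = "slow-medium"  # medium blue
CLASS_SLOW_DARK = "slow-dark"  # dark blue
CLASS_UNOBSERVED = "unobserved"  # white

#: Ordering from slowest to fastest exchange, used for monotonicity checks.
CLASS_SPEED_ORDER = (
    CLASS_SLOW_DARK,
    CLASS_SLOW_MEDIUM,
    CLASS_SLOW_LIGHT,
    CLASS_UNOBSERVED,
    CLASS_FAST,
)

#: Unstructured N-terminal residues used for the CLEANEX per-sample factor.
DEFAULT_REFERENCE_RESIDUES = (657, 660, 661)

#: CLEANEX-detectable floor, s^-1 (≈ the amide 1H longitudinal relaxation rate).
CLEANEX_RATE_FLOOR_PER_S = 0.5

SECONDS_PER_HOUR = 3600.0

#: Real-time measurement time points, hours after dissolution in 2H2O.
REALTIME_HOURS = (3.0, 12.0, 39.0)


@dataclass
class ExchangeRecord:
    """Observables for one residue across the exchange experiments."""

    residue: int
    cleanex: float | None = None  # normalised CLEANEX intensity, or absent
    reference: float | None = None  # reference (TROSY) spectrum intensity
    i3: float | None = None  # real-time intensity at 3 h
    i12: float | None = None
    i39: float | None = None
    noise: float = 0.0  # spectrum RMS noise shared by the intensities
    exchange_class: str | None = None


def cleanex_factor(
    cleanex: Mapping[int, float],
    reference: Mapping[int, float],
    ref_residues: tuple[int, ...] = DEFAULT_REFERENCE_RESIDUES,
) -> float:
    """Per-sample CLEANEX normalisation factor.

    factor = (Σ I_CLEANEX over reference residues) / (Σ I_reference).
    """
    for res in ref_residues:
        for table, name in ((cleanex, "CLEANEX"), (reference, "reference")):
            if res not in table:
                raise ValueError(f"reference residue {res} missing from {name} table")
            if table[res] <= 0:
                raise ValueError(f"reference residue {res} non-positive in {name} table")
    num = sum(cleanex[r] for r in ref_residues)
    den = sum(reference[r] for r in ref_residues)
    return num / den


def normalise_cleanex(cleanex: Mapping[int, float], factor: float) -> dict[int, float]:
    """Divide every CLEANEX intensity by the per-sample factor."""
    if factor <= 0:
        raise ValueError(f"normalisation factor must be positive, got {factor}")
    return {res: val / factor for res, val in cleanex.items()}


def classify_slow(i3: float, i12: float, i39: float) -> str:
    """Classify a slow exchanger from its 3/12/39 h intensities.

    Boundary equality is assigned to the slower class.
    """
    for name, val in (("I(3h)", i3), ("I(12h)", i12), ("I(39h)", i39)):
        if val is None:
            raise ValueError(f"{name} is absent; route through classify_residue instead")
        if val < 0:
            raise ValueError(f"{name} must be >= 0 after noise flooring, got {val}")
    if i3 - i12 > 0.5 * i3:
        return CLASS_SLOW_LIGHT
    if i12 - i39 > 0.25 * i12:
        return CLASS_SLOW_MEDIUM
    return CLASS_SLOW_DARK


def classify_residue(record: ExchangeRecord, threshold_multiple: float = 3.0) -> str:
    """Assign the exchange class for one residue.

    Precedence: a CLEANEX signal above the detection threshold → fast;
    otherwise a detectable real-time series → the slow-class rules;
    otherwise unobserved.  The detection threshold is ``threshold_multiple``
    times the spectrum RMS noise; intensities below it are floored to 0.
    """
    if threshold_multiple <= 0:
        raise ValueError("detection threshold multiple must be positive")
    thr = threshold_multiple * record.noise

    def flo(v: float | None) -> float:
        if v is None:
            return 0.0
        return float(v) if v > thr else 0.0

    if record.cleanex is not None and record.cleanex > thr:
        return CLASS_FAST
    i3, i12, i39 = flo(record.i3), flo(record.i12), flo(record.i39)
    if i3 > 0.0:
        return classify_slow(i3, i12, i39)
    return CLASS_UNOBSERVED


def simulate_class_from_rate(
    k: float,
    unit: str = "per_h",
    time_points_h: tuple[float, float, float] = REALTIME_HOURS,
    cleanex_floor_per_s: float = CLEANEX_RATE_FLOOR_PER_S,
    detection_threshold: float = 1e-3,
) -> str:
    """Predicted exchange class for a first-order exchange rate *k*.

    Rates at or above the CLEANEX-detectable floor are fast (the random-coil
    regime, ~10 s⁻¹, lies well inside it); slower rates give real-time
    intensities I(t) = exp(−k·t) which are classified by the slow-class
    rules, with intensities below *detection_threshold* treated as
    unobservable.
    """
    if k <= 0:
        raise ValueError("exchange rate must be positive")
    if unit in ("per_h", "h", "h-1"):
        k_per_s = k / SECONDS_PER_HOUR
        k_per_h = k
    elif unit in ("per_s", "s", "s-1"):
        k_per_s = k
        k_per_h = k * SECONDS_PER_HOUR
    else:
        raise ValueError(f"unknown rate unit {unit!r}")
    if k_per_s >= cleanex_floor_per_s:
        return CLASS_FAST
    intensities = [math.exp(-k_per_h * t) for t in time_points_h]
    record = ExchangeRecord(
        residue=0,
        cleanex=None,
        i3=intensities[0],
        i12=intensities[1],
        i39=intensities[2],
        noise=detection_threshold / 3.0,
    )
    return classify_residue(record, threshold_multiple=3.0)


def class_table(
    records: list[ExchangeRecord], threshold_multiple: float = 3.0
) -> pd.DataFrame:
    """Classify every record; returns a per-residue table (deterministic order)."""
    rows = []
    for rec in sorted(records, key=lambda r: r.residue):
        cls = classify_residue(rec, threshold_multiple)
        rec.exchange_class = cls
        rows.append(
            {
                "residue": rec.residue,
                "cleanex": np.nan if rec.cleanex is None else rec.cleanex,
                "i3": np.nan if rec.i3 is None else rec.i3,
                "i12": np.nan if rec.i12 is None else rec.i12,
                "i39": np.nan if rec.i39 is None else rec.i39,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


#: Viewer colour encoding for the exchange classes.
CLASS_COLOURS = {
    CLASS_FAST: "red",
    CLASS_SLOW_LIGHT: "lightblue",
    CLASS_SLOW_MEDIUM: "mediumblue",
    CLASS_SLOW_DARK: "darkblue",
    CLASS_UNOBSERVED: "white",
}


def export_class_attributes(records: list[ExchangeRecord], path) -> None:
    """Write a viewer attribute file mapping residues to class colours."""
    from pathlib import Path

    df = class_table(records)
    lines = ["residue\tclass\tcolour"]
    for _, row in df.iterrows():
        lines.append(f"{int(row['residue'])}\t{row['class']}\t{CLASS_COLOURS[row['class']]}")
    Path(path).write_text("\n".join(lines) + "\n")
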