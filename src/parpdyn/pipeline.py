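"""Study orchestration: run all analysis stages over a sample manifest.

A study configuration is a flat declarative YAML file listing samples
(label → input file paths), the spectrometer field context, the subdomain
selections and an output directory.  ``run_study`` executes every stage for
every sample — CSP profiles against the reference sample, relaxation fits
and τc summaries, exchange classification and superposition metrics — and
writes per-stage TSV tables plus a human-readable summary.  Failures in one
sample are logged and flagged without aborting the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import exchange as ex
from . import relaxation as rx
from . import shift_analysis as sa
from . import structmetrics as sm

__all__ = [
    "REFERENCE_KD_MOLAR",
    "StudyConfig",
    "ComparisonReport",
    "fold_change",
    "load_config",
    "run_study",
]

logger = logging.getLogger(__name__)

#: Published SPR dissociation constants (molar) of full-length PARP-1 for a
#: DNA single-strand-break mimic, free and in inhibitor complexes.
REFERENCE_KD_MOLAR = {
    "free": 2.1e-9,
    "EB-47": 1.3e-10,
    "veliparib": 4.2e-9,
    "olaparib": 2.1e-9,
}

#: Default HD/ART residue ranges for subdomain τc summaries.
DEFAULT_SUBDOMAIN_RANGES = {
    "HD": [(666, 721), (730, 743), (750, 779)],
    "ART": [(790, 936), (939, 1009)],
}


def fold_change(kd_reference: float, kd_sample: float) -> tuple[float, str]:
    """Fold change between two dissociation constants.

    Returns ``(ratio, direction)`` where the ratio is larger/smaller (≥ 1)
    and the direction describes the sample relative to the reference:
    'tighter' when kd_sample < kd_reference, 'weaker' when larger, 'equal'
    otherwise.
    """
    if kd_reference <= 0 or kd_sample <= 0:
        raise ValueError("dissociation constants must be positive")
    ratio = max(kd_reference, kd_sample) / min(kd_reference, kd_sample)
    if kd_sample < kd_reference:
        direction = "tighter"
    elif kd_sample > kd_reference:
        direction = "weaker"
    else:
        direction = "equal"
    return ratio, direction


@dataclass
class StudyConfig:
    samples: list[dict]  # label, shifts, relaxation_t1/..., exchange_*, structure, chain
    reference_label: str
    out_dir: Path
    seed: int = 0
    field_context: rx.FieldContext = field(default_factory=rx.FieldContext)
    subdomains: dict = field(default_factory=lambda: dict(DEFAULT_SUBDOMAIN_RANGES))
    kd_molar: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("empty sample list")
        labels = [s.get("label") for s in self.samples]
        if None in labels:
            raise ValueError("every sample needs a label")
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate sample labels: {labels}")
        if self.reference_label not in labels:
            raise ValueError(f"reference sample {self.reference_label!r} not in manifest")
        for sample in self.samples:
            for key, value in sample.items():
                if key.endswith(("shifts", "t1", "t1rho", "cleanex", "reference", "structure")):
                    if value and not Path(value).exists():
                        raise ValueError(f"sample {sample['label']!r}: missing file {value}")


def load_config(path: str | Path) -> StudyConfig:
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
    fc_raw = raw.get("field", {})
    fc = rx.FieldContext(
        h_freq_mhz=fc_raw.get("h_freq_mhz", 800.0),
        b1_khz=fc_raw.get("b1_khz", 1.56),
        carrier_ppm=fc_raw.get("carrier_ppm", 117.074),
    )
    subdomains = {
        name: [tuple(r) for r in ranges]
        for name, ranges in raw.get("subdomains", DEFAULT_SUBDOMAIN_RANGES).items()
    }
    return StudyConfig(
        samples=raw["samples"],
        reference_label=raw["reference"],
        out_dir=Path(raw.get("out_dir", "study_out")),
        seed=int(raw.get("seed", 0)),
        field_context=fc,
        subdomains=subdomains,
        kd_molar=raw.get("kd_molar", {}),
    )


@dataclass
class ComparisonReport:
    csp: pd.DataFrame | None = None  # per sample: csp_max, threshold, n residues
    tau_c: pd.DataFrame | None = None  # per sample x subdomain: mean, sd
    exchange_counts: pd.DataFrame | None = None  # per sample: class counts
    superposition: pd.DataFrame | None = None  # Table-2-style rmsd rows
    fold_changes: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sections = {
            "csp_summary.tsv": self.csp,
            "tau_c_summary.tsv": self.tau_c,
            "exchange_counts.tsv": self.exchange_counts,
            "superposition.tsv": self.superposition,
            "fold_changes.tsv": self.fold_changes,
        }
        written = []
        for name, df in sections.items():
            if df is not None:
                df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6g")
                written.append(name)
        summary = ["study report", "============", f"sections: {', '.join(written) or 'none'}"]
        if self.warnings:
            summary.append("warnings:")
            summary.extend(f"  - {w}" for w in self.warnings)
        for name, df in sections.items():
            if df is not None:
                summary.append("")
                summary.append(f"## {name}")
                summary.append(df.to_string(index=False))
        (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
        return out_dir / "summary.txt"


def _sample_tau_c(sample: dict, config: StudyConfig) -> dict[int, float | None]:
    t1_series = rx.read_series_tsv(sample["relaxation_t1"], "T1")
    t1rho_series = rx.read_series_tsv(sample["relaxation_t1rho"], "T1rho")
    t1 = {s.residue: rx.fit_decay(s).time_ms for s in t1_series}
    t1rho = {s.residue: rx.fit_decay(s).time_ms for s in t1rho_series}
    shifts = sample.get("residue_shifts_ppm", {})
    tau: dict[int, float | None] = {}
    for res in sorted(set(t1) & set(t1rho)):
        t1rho_val = t1rho[res]
        if res in shifts:
            corrected = rx.correct_t1rho(t1rho_val, t1[res], shifts[res], config.field_context)
            if corrected is None:
                tau[res] = None
                continue
            t1rho_val = corrected
        tau[res] = rx.estimate_tau_c(t1[res], t1rho_val, config.field_context)
    return tau


def _sample_exchange(sample: dict) -> list[ex.ExchangeRecord]:
    cleanex = _read_intensity_tsv(sample["exchange_cleanex"])
    reference = _read_intensity_tsv(sample["exchange_reference"])
    factor = ex.cleanex_factor(cleanex, reference)
    cleanex = ex.normalise_cleanex(cleanex, factor)
    realtime = {
        float(h): _read_intensity_tsv(path)
        for h, path in sample.get("exchange_realtime", {}).items()
    }
    residues = set(cleanex) | set(reference)
    for table in realtime.values():
        residues |= set(table)
    noise = float(sample.get("exchange_noise", 0.0))
    records = []
    for res in sorted(residues):
        records.append(
            ex.ExchangeRecord(
                residue=res,
                cleanex=cleanex.get(res),
                reference=reference.get(res),
                i3=realtime.get(3.0, {}).get(res),
                i12=realtime.get(12.0, {}).get(res),
                i39=realtime.get(39.0, {}).get(res),
                noise=noise,
            )
        )
    return records


def _read_intensity_tsv(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "residue" not in df.columns or "intensity" not in df.columns:
        raise ValueError(f"{path}: expected columns residue, intensity")
    return {int(r): float(v) for r, v in zip(df["residue"], df["intensity"])}


def run_study(config: StudyConfig) -> ComparisonReport:
    """Run every configured stage for every sample; deterministic in inputs."""
    report = ComparisonReport()
    by_label = {s["label"]: s for s in config.samples}
    ref_sample = by_label[config.reference_label]

    # --- CSP stage ---------------------------------------------------------
    profiles: list[tuple[str, sa.CSPProfile]] = []
    if "shifts" in ref_sample:
        ref_table = sa.read_shift_table(
            ref_sample["shifts"], ref_sample.get("shifts_dialect", "tsv"),
            label=config.reference_label,
        )
        for sample in config.samples:
            label = sample["label"]
            if label == config.reference_label or "shifts" not in sample:
                continue
            try:
                table = sa.read_shift_table(
                    sample["shifts"], sample.get("shifts_dialect", "tsv"), label=label
                )
                profiles.append((label, sa.compute_csp(ref_table, table)))
            except Exception as exc:  # stage isolation: log, flag, continue
                logger.warning("CSP stage failed for %s: %s", label, exc)
                report.warnings.append(f"csp[{label}]: {exc}")
        if profiles:
            sa.normalise_profiles([p for _, p in profiles])
            report.csp = pd.DataFrame(
                [
                    {
                        "sample": label,
                        "n_csp": int(np.isfinite(p.data["csp"]).sum()),
                        "csp_max_sample": float(np.nanmax(p.data["csp"].to_numpy())),
                        "csp_max_global": p.csp_max,
                        "threshold": p.threshold,
                    }
                    for label, p in profiles
                ]
            )

    # --- relaxation stage --------------------------------------------------
    tau_rows = []
    for sample in config.samples:
        if "relaxation_t1" not in sample:
            continue
        label = sample["label"]
        try:
            tau = _sample_tau_c(sample, config)
            summary = rx.subdomain_summary(tau, config.subdomains)
            for _, row in summary.iterrows():
                tau_rows.append({"sample": label, **row.to_dict()})
            undefined = sum(1 for v in tau.values() if v is None)
            if undefined:
                report.warnings.append(f"tau_c[{label}]: {undefined} residues undefined")
        except Exception as exc:
            logger.warning("relaxation stage failed for %s: %s", label, exc)
            report.warnings.append(f"relaxation[{label}]: {exc}")
    if tau_rows:
        report.tau_c = pd.DataFrame(tau_rows)

    # --- exchange stage ----------------------------------------------------
    count_rows = []
    for sample in config.samples:
        if "exchange_cleanex" not in sample:
            continue
        label = sample["label"]
        try:
            records = _sample_exchange(sample)
            table = ex.class_table(records)
            counts = table["class"].value_counts().to_dict()
            count_rows.append({"sample": label, **{c: counts.get(c, 0) for c in ex.CLASS_SPEED_ORDER}})
        except Exception as exc:
            logger.warning("exchange stage failed for %s: %s", label, exc)
            report.warnings.append(f"exchange[{label}]: {exc}")
    if count_rows:
        report.exchange_counts = pd.DataFrame(count_rows)

    # --- superposition stage ----------------------------------------------
    if "structure" in ref_sample:
        try:
            ref_model = sm.read_structure(ref_sample["structure"])
            others = []
            for sample in config.samples:
                if sample["label"] == config.reference_label or "structure" not in sample:
                    continue
                others.append((sm.read_structure(sample["structure"]), sample.get("chain", "A")))
            if others:
                rows = sm.superposition_report(
                    ref_model, others, chain_ref=ref_sample.get("chain", "A")
                )
                report.superposition = pd.DataFrame(rows)
        except Exception as exc:
            logger.warning("superposition stage failed: %s", exc)
            report.warnings.append(f"superposition: {exc}")

    # --- affinity fold changes --------------------------------------------
    kd = config.kd_molar or {}
    if kd:
        ref_kd = kd.get(config.reference_label) or kd.get("free")
        if ref_kd:
            rows = []
            for label, value in sorted(kd.items()):
                if value == ref_kd and label in (config.reference_label, "free"):
                    continue
                ratio, direction = fold_change(ref_kd, value)
                rows.append({"sample": label, "kd_molar": value, "fold_change": ratio,
                             "direction": direction})
            if rows:
                report.fold_changes = pd.DataFrame(rows)

    report.write(config.out_dir)
    return report
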