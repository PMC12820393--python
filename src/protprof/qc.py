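"""Intrinsic-fluorescence quality control.

Stool extracts can fluoresce on their own (soluble fluorophores — e.g.
incompletely absorbed mesalazine — that survive centrifugation and
filtration).  Each extract therefore gets a substrate-free intrinsic well
per plate; its mean fluorescence is the sample's intrinsic baseline.

Two decisions are made from these baselines:

* extracts whose baseline is *excessively* high are excluded from enzymatic
  analysis entirely (their signal is dominated by the contaminant);
* every remaining digestion curve has its extract's intrinsic trace
  subtracted point-by-point before slope estimation.

"Excessively high" is a policy, not a constant: either an absolute RFU
threshold, or an adaptive threshold referenced to the plate's empty wells
(mean + k * SD of all empty-well reads, default k = 10).  Each flag records
the threshold that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import AlignmentError, ConfigError, InputError, PairingError
from .plates import KineticTrace, PlateRun, WellRole

__all__ = [
    "IntrinsicBaseline",
    "QcFlag",
    "AbsolutePolicy",
    "AdaptivePolicy",
    "intrinsic_baseline",
    "collect_intrinsic_baselines",
    "flag_high_background",
    "subtract_intrinsic",
    "qc_report",
]


@dataclass(frozen=True)
class IntrinsicBaseline:
    """Per-(sample, plate) summary of the substrate-free intrinsic trace."""

    sample_id: str
    plate_id: str
    baseline_rfu: float
    baseline_sd_rfu: float
    n_reads: int


@dataclass(frozen=True)
class QcFlag:
    sample_id: str
    excluded: bool
    reason: str  # high_intrinsic_fluorescence | incomplete_trace | none
    threshold_used: float

    def __post_init__(self) -> None:
        if self.excluded != (self.reason != "none"):
            raise InputError("excluded flag and reason are inconsistent")


@dataclass(frozen=True)
class AbsolutePolicy:
    """Exclude samples whose mean intrinsic baseline exceeds a fixed RFU."""

    threshold_rfu: float


@dataclass(frozen=True)
class AdaptivePolicy:
    """Exclude relative to plate background: mean(empty) + k * SD(empty)."""

    k: float = 10.0


def intrinsic_baseline(trace: KineticTrace) -> IntrinsicBaseline:
    """Summarize one intrinsic well as mean +/- SD over its reads."""
    if trace.role is not WellRole.INTRINSIC:
        raise InputError(
            f"intrinsic_baseline needs an intrinsic well, got role {trace.role.value!r}"
        )
    rfu = trace.rfu
    sd = float(np.std(rfu, ddof=1)) if len(rfu) > 1 else 0.0
    return IntrinsicBaseline(
        sample_id=trace.sample_id,
        plate_id=trace.plate_id,
        baseline_rfu=float(np.mean(rfu)),
        baseline_sd_rfu=sd,
        n_reads=len(rfu),
    )


def collect_intrinsic_baselines(runs: list[PlateRun]) -> list[IntrinsicBaseline]:
    """Baselines for every intrinsic well across a set of plates."""
    return [
        intrinsic_baseline(t)
        for run in runs
        for t in run.wells(WellRole.INTRINSIC)
    ]


def _empty_well_threshold(runs: list[PlateRun], k: float) -> float:
    reads = np.concatenate(
        [t.rfu for run in runs for t in run.empty_wells()]
        or [np.array([])]
    )
    if reads.size == 0:
        raise ConfigError("adaptive QC policy needs at least one empty well")
    sd = float(np.std(reads, ddof=1)) if reads.size > 1 else 0.0
    return float(np.mean(reads)) + k * sd


def flag_high_background(
    baselines: list[IntrinsicBaseline],
    plate_runs: list[PlateRun] | None = None,
    policy: AbsolutePolicy | AdaptivePolicy = AdaptivePolicy(),
) -> list[QcFlag]:
    """One exclusion flag per sample.

    A sample's score is the mean of its per-plate intrinsic baselines (the
    contaminant is a property of the extract, so it shows on every plate).
    Deterministic given inputs; the threshold applied is recorded on every
    flag.
    """
    if isinstance(policy, AbsolutePolicy):
        threshold = float(policy.threshold_rfu)
    elif isinstance(policy, AdaptivePolicy):
        if not plate_runs:
            raise ConfigError("adaptive QC policy needs plate runs with empty wells")
        threshold = _empty_well_threshold(plate_runs, policy.k)
    else:
        raise ConfigError(f"unknown QC policy: {policy!r}")

    per_sample: dict[str, list[float]] = {}
    for b in baselines:
        per_sample.setdefault(b.sample_id, []).append(b.baseline_rfu)
    flags = []
    for sample_id in sorted(per_sample):
        level = float(np.mean(per_sample[sample_id]))
        excluded = level > threshold
        flags.append(
            QcFlag(
                sample_id=sample_id,
                excluded=excluded,
                reason="high_intrinsic_fluorescence" if excluded else "none",
                threshold_used=threshold,
            )
        )
    return flags


def subtract_intrinsic(
    digestion: KineticTrace, intrinsic: KineticTrace
) -> KineticTrace:
    """Subtract an extract's intrinsic trace from its digestion curve.

    The corrected curve may contain negative values (read noise); they are
    kept as-is because downstream slope fitting is offset-invariant.
    """
    if digestion.sample_id != intrinsic.sample_id:
        raise PairingError(
            f"cannot subtract intrinsic of {intrinsic.sample_id!r} from "
            f"digestion of {digestion.sample_id!r}"
        )
    if len(digestion.timepoints) != len(intrinsic.timepoints) or not np.allclose(
        digestion.timepoints, intrinsic.timepoints
    ):
        raise AlignmentError(
            f"sample {digestion.sample_id}: digestion and intrinsic traces "
            "are on different timepoint grids"
        )
    return digestion.with_rfu(
        digestion.rfu - intrinsic.rfu,
        intrinsic_subtracted=True,
        intrinsic_well=f"{intrinsic.plate_id}/{intrinsic.well_id}",
    )


def qc_report(
    baselines: list[IntrinsicBaseline], flags: list[QcFlag]
) -> pd.DataFrame:
    """Tabular QC report: one row per sample."""
    per_sample: dict[str, list[IntrinsicBaseline]] = {}
    for b in baselines:
        per_sample.setdefault(b.sample_id, []).append(b)
    by_flag = {f.sample_id: f for f in flags}
    rows = []
    for sample_id in sorted(per_sample):
        f = by_flag.get(sample_id)
        rows.append(
            {
                "sample_id": sample_id,
                "baseline_rfu": float(
                    np.mean([b.baseline_rfu for b in per_sample[sample_id]])
                ),
                "n_intrinsic_wells": len(per_sample[sample_id]),
                "threshold_used": f.threshold_used if f else np.nan,
                "excluded": bool(f.excluded) if f else False,
                "reason": f.reason if f else "none",
            }
        )
    return pd.DataFrame(rows)
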