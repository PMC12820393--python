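"""Rate estimation from corrected progress curves.

The chain per plate is fixed: (1) divide every read on the plate by the
plate's normalization factor, (2) subtract each extract's (normalized)
intrinsic trace from its digestion curves, (3) detect the linear phase of
the corrected curve, (4) ordinary least squares over the window; the fitted
slope is the activity in RFU/min.  Steps 1 and 2 commute within a plate,
and because OLS slopes are offset- and scale-consistent, normalizing raw
traces is equivalent to normalizing fitted slopes.

Plate normalization
-------------------
Plate-to-plate gain differences are corrected with the factor::

    factor(plate x) = mean empty-well fluorescence of plate x / reference value

where the reference value is the same quantity on a designated reference
plate.  Multiplying every well of a plate by k multiplies its factor by k,
so normalized data — and every downstream activity — are unchanged.

Linear-phase detection
----------------------
The early portion of a progress curve (typically within the first ~20
minutes) is linear before substrate depletion bends it over.  The detector
enumerates contiguous read windows inside ``[0, t_max_window]``, longest
first and earliest start first among equal lengths, and accepts the first
window whose maximum absolute deviation from its own least-squares line is
within ``linearity_tol * (RFU span of the window) + 3 * noise_estimate``,
the noise estimate being the SD of first differences over the trace tail.
Near-flat traces (full-window slope below ``activity_floor_rfu_per_min``)
skip the search and report the default window with ``low_activity=True`` —
a linearity criterion is meaningless when there is nothing but noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import FormatError, InputError, LayoutError
from .plates import KineticTrace, PlateRun, WellRole
from .qc import QcFlag, subtract_intrinsic

__all__ = [
    "NormalizationFactor",
    "LinearWindow",
    "LinearPhaseOptions",
    "ActivityRecord",
    "plate_normalization_factor",
    "normalize_plate",
    "detect_linear_phase",
    "fit_slope",
    "aggregate_replicates",
    "estimate_activities",
    "activity_table",
    "read_activity_table",
]


@dataclass(frozen=True)
class NormalizationFactor:
    plate_id: str
    factor: float
    reference_value: float
    empty_well_mean: float
    n_empty_wells: int


@dataclass(frozen=True)
class LinearWindow:
    """A contiguous time window judged linear, in absolute minutes."""

    t_start: float
    t_end: float
    n_points: int
    r_squared: float  # NaN for flat windows, where r^2 is undefined
    low_activity: bool = False


@dataclass(frozen=True)
class LinearPhaseOptions:
    t_min_window: float = 5.0
    t_max_window: float = 20.0
    min_points: int = 4
    linearity_tol: float = 0.02
    activity_floor_rfu_per_min: float = 1.0


@dataclass
class ActivityRecord:
    """Replicate-aggregated activity for one (sample, substrate, pH)."""

    sample_id: str
    substrate_id: str
    ph: float
    rate_rfu_per_min: float
    rate_sd: float  # NaN when only one replicate
    n_replicates: int
    windows: tuple[tuple[float, float], ...] = ()
    low_activity: bool = False
    qc_excluded: bool = False
    normalization_factor: float = 1.0


def empty_well_mean(plate: PlateRun) -> float:
    """Mean over all reads of all empty wells of a plate."""
    empties = plate.empty_wells()
    if not empties:
        raise LayoutError(f"plate {plate.plate_id} has no empty wells")
    return float(np.mean(np.concatenate([t.rfu for t in empties])))


def plate_normalization_factor(
    plate: PlateRun, reference_value: float
) -> NormalizationFactor:
    if reference_value <= 0:
        raise InputError("reference value must be > 0")
    mean = empty_well_mean(plate)
    factor = mean / reference_value
    if factor <= 0:
        raise InputError(
            f"plate {plate.plate_id}: non-positive normalization factor {factor}"
        )
    return NormalizationFactor(
        plate_id=plate.plate_id,
        factor=factor,
        reference_value=float(reference_value),
        empty_well_mean=mean,
        n_empty_wells=len(plate.empty_wells()),
    )


def normalize_plate(
    plate: PlateRun, factor: NormalizationFactor | float
) -> PlateRun:
    """Divide every read of every trace by the plate's factor."""
    f = factor.factor if isinstance(factor, NormalizationFactor) else float(factor)
    if f <= 0:
        raise InputError("normalization factor must be > 0")
    return plate.map_rfu(lambda r: r / f, normalization_factor=f)


def _ols(t: np.ndarray, y: np.ndarray):
    """Slope, intercept, stderr, r^2 with flat-trace handling."""
    if np.ptp(t) == 0:
        raise InputError("degenerate window: all reads share one timepoint")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0, math.nan
    res = sps.linregress(t, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.stderr),
        float(res.rvalue**2),
    )


def _tail_noise_estimate(trace: KineticTrace, t_max_window: float) -> float:
    """SD of first differences over the trace tail (reads past the window)."""
    tail = trace.rfu[trace.timepoints > t_max_window]
    if len(tail) < 3:
        tail = trace.rfu[len(trace.rfu) // 2 :]
    if len(tail) < 3:
        return 0.0
    return float(np.std(np.diff(tail), ddof=1))


def candidate_windows(
    t: np.ndarray, options: LinearPhaseOptions
) -> list[tuple[int, int]]:
    """Index ranges (i, j) of admissible windows, in acceptance order.

    Admissible: inside ``[0, t_max_window]``, at least ``min_points`` reads,
    spanning at least ``t_min_window`` minutes.  Ordered by decreasing
    length, then earliest start.
    """
    in_bound = np.flatnonzero(t <= options.t_max_window + 1e-9)
    if len(in_bound) < options.min_points:
        in_bound = np.arange(min(len(t), options.min_points))
    idx = in_bound
    out = []
    for n in range(len(idx), options.min_points - 1, -1):
        for s in range(0, len(idx) - n + 1):
            i, j = idx[s], idx[s + n - 1]
            if t[j] - t[i] >= options.t_min_window - 1e-9:
                out.append((int(i), int(j)))
    return out


def window_accepted(
    trace: KineticTrace, i: int, j: int, noise: float, options: LinearPhaseOptions
) -> bool:
    """The linearity acceptance rule for the window spanning reads i..j."""
    t = trace.timepoints[i : j + 1]
    y = trace.rfu[i : j + 1]
    if np.ptp(y) == 0:
        return True  # perfectly flat is perfectly linear
    slope, intercept, _, _ = _ols(t, y)
    max_dev = float(np.max(np.abs(y - (slope * t + intercept))))
    return max_dev <= options.linearity_tol * float(np.ptp(y)) + 3.0 * noise


def detect_linear_phase(
    trace: KineticTrace, options: LinearPhaseOptions | None = None
) -> LinearWindow:
    """Find the early linear phase of a corrected progress curve.

    Deterministic.  If no admissible window satisfies the acceptance rule,
    the window with the smallest deviation relative to its allowance is
    returned (the least-bent choice).
    """
    options = options or LinearPhaseOptions()
    t, y = trace.timepoints, trace.rfu
    if len(t) < options.min_points:
        raise InputError(
            f"trace has {len(t)} reads; need at least {options.min_points}"
        )
    cands = candidate_windows(t, options)
    if not cands:
        raise InputError("no admissible window; check window options")
    noise = _tail_noise_estimate(trace, options.t_max_window)

    default_i, default_j = cands[0]  # the full in-bound window
    full_t = t[default_i : default_j + 1]
    full_y = y[default_i : default_j + 1]
    if np.ptp(full_y) == 0:
        full_slope = 0.0
    else:
        full_slope, _, _, _ = _ols(full_t, full_y)
    if abs(full_slope) < options.activity_floor_rfu_per_min:
        return LinearWindow(
            t_start=float(t[default_i]),
            t_end=float(t[default_j]),
            n_points=default_j - default_i + 1,
            r_squared=math.nan if np.ptp(full_y) == 0 else _ols(full_t, full_y)[3],
            low_activity=True,
        )

    best = None  # (relative deviation, i, j) fallback
    for i, j in cands:
        tw, yw = t[i : j + 1], y[i : j + 1]
        if np.ptp(yw) == 0:
            max_dev, allowance = 0.0, max(3.0 * noise, 1e-300)
        else:
            slope, intercept, _, _ = _ols(tw, yw)
            max_dev = float(np.max(np.abs(yw - (slope * tw + intercept))))
            allowance = options.linearity_tol * float(np.ptp(yw)) + 3.0 * noise
        if max_dev <= allowance:
            r2 = math.nan if np.ptp(yw) == 0 else _ols(tw, yw)[3]
            return LinearWindow(
                t_start=float(t[i]),
                t_end=float(t[j]),
                n_points=j - i + 1,
                r_squared=r2,
            )
        ratio = max_dev / allowance if allowance > 0 else math.inf
        if best is None or ratio < best[0]:
            best = (ratio, i, j)
    _, i, j = best
    r2 = math.nan if np.ptp(y[i : j + 1]) == 0 else _ols(t[i : j + 1], y[i : j + 1])[3]
    return LinearWindow(
        t_start=float(t[i]), t_end=float(t[j]), n_points=j - i + 1, r_squared=r2
    )


def fit_slope(
    trace: KineticTrace, window: LinearWindow
) -> tuple[float, float, float]:
    """OLS slope over the reads inside a window.

    Returns ``(rate_rfu_per_min, stderr, r_squared)``; the intercept is
    discarded (it is the residual baseline, not activity).
    """
    mask = (trace.timepoints >= window.t_start - 1e-9) & (
        trace.timepoints <= window.t_end + 1e-9
    )
    t, y = trace.timepoints[mask], trace.rfu[mask]
    if len(t) < 3:
        raise InputError("slope window must contain at least 3 reads")
    slope, _, stderr, r2 = _ols(t, y)
    return slope, stderr, r2


def aggregate_replicates(slopes: list[float]) -> tuple[float, float, int]:
    """Mean, sample SD (n-1) and count over replicate rates.

    A single replicate reports SD as NaN (missing), not zero: one well
    carries no spread information.
    """
    if len(slopes) == 0:
        raise InputError("no replicate slopes to aggregate")
    arr = np.asarray(slopes, dtype=float)
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else math.nan
    return mean, sd, len(arr)


def estimate_activities(
    runs: list[PlateRun],
    qc_flags: list[QcFlag] | None = None,
    reference_plate_id: str | None = None,
    options: LinearPhaseOptions | None = None,
    reference_value: float | None = None,
) -> list[ActivityRecord]:
    """Full kinetics chain over a set of plates.

    The reference plate is ``reference_plate_id`` if given, else the run
    flagged ``is_reference_plate``, else the first run; alternatively an
    explicit ``reference_value`` (mean empty-well RFU, e.g. from a plate not
    in ``runs``) overrides both.  QC-excluded samples are processed and
    flagged, never silently dropped, so audit tables stay complete;
    downstream assembly decides whether to drop them.
    """
    if not runs:
        raise InputError("no plate runs given")
    options = options or LinearPhaseOptions()
    if reference_value is None:
        if reference_plate_id is None:
            flagged = [r for r in runs if r.is_reference_plate]
            reference = flagged[0] if flagged else runs[0]
        else:
            by_id = {r.plate_id: r for r in runs}
            if reference_plate_id not in by_id:
                raise InputError(f"reference plate {reference_plate_id!r} not found")
            reference = by_id[reference_plate_id]
        reference_value = empty_well_mean(reference)
    excluded = {f.sample_id for f in (qc_flags or []) if f.excluded}

    per_condition: dict[tuple[str, str, float], dict] = {}
    for run in runs:
        nf = plate_normalization_factor(run, reference_value)
        norm = normalize_plate(run, nf)
        for trace in norm.wells(WellRole.DIGESTION):
            intrinsic = norm.intrinsic_well(trace.sample_id)
            corrected = (
                subtract_intrinsic(trace, intrinsic) if intrinsic is not None else trace
            )
            window = detect_linear_phase(corrected, options)
            slope, _, _ = fit_slope(corrected, window)
            key = (trace.sample_id, trace.substrate_id, float(trace.ph))
            bucket = per_condition.setdefault(
                key,
                {"slopes": [], "windows": [], "low": False, "factor": nf.factor},
            )
            bucket["slopes"].append(slope)
            bucket["windows"].append((window.t_start, window.t_end))
            bucket["low"] = bucket["low"] or window.low_activity

    records = []
    for (sample_id, substrate_id, ph), bucket in sorted(per_condition.items()):
        mean, sd, n = aggregate_replicates(bucket["slopes"])
        records.append(
            ActivityRecord(
                sample_id=sample_id,
                substrate_id=substrate_id,
                ph=ph,
                rate_rfu_per_min=mean,
                rate_sd=sd,
                n_replicates=n,
                windows=tuple(bucket["windows"]),
                low_activity=bucket["low"],
                qc_excluded=sample_id in excluded,
                normalization_factor=bucket["factor"],
            )
        )
    return records


def activity_table(
    records: list[ActivityRecord], sheet: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flat activity table, one row per (sample, substrate, pH)."""
    cohort_of = (
        dict(zip(sheet["sample_id"], sheet["cohort"])) if sheet is not None else {}
    )
    rows = []
    for r in records:
        starts = [w[0] for w in r.windows]
        ends = [w[1] for w in r.windows]
        rows.append(
            {
                "sample_id": r.sample_id,
                "cohort": cohort_of.get(r.sample_id, ""),
                "substrate_id": r.substrate_id,
                "ph": r.ph,
                "rate_rfu_per_min": r.rate_rfu_per_min,
                "rate_sd": r.rate_sd,
                "n_replicates": r.n_replicates,
                "window_start": min(starts) if starts else math.nan,
                "window_end": max(ends) if ends else math.nan,
                "low_activity": r.low_activity,
                "qc_excluded": r.qc_excluded,
                "normalization_factor": r.normalization_factor,
            }
        )
    return pd.DataFrame(rows)


def read_activity_table(source) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Inverse of :func:`activity_table` (windows reduced to their span)."""
    df = pd.read_csv(source)
    needed = {"sample_id", "substrate_id", "ph", "rate_rfu_per_min"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"activity table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        windows = ()
        if not (pd.isna(d.get("window_start")) or pd.isna(d.get("window_end"))):
            windows = ((float(d["window_start"]), float(d["window_end"])),)
        records.append(
            ActivityRecord(
                sample_id=str(d["sample_id"]),
                substrate_id=str(d["substrate_id"]),
                ph=float(d["ph"]),
                rate_rfu_per_min=float(d["rate_rfu_per_min"]),
                rate_sd=float(d.get("rate_sd", math.nan)),
                n_replicates=int(d.get("n_replicates", 1)),
                windows=windows,
                low_activity=bool(d.get("low_activity", False)),
                qc_excluded=bool(d.get("qc_excluded", False)),
                normalization_factor=float(d.get("normalization_factor", 1.0)),
            )
        )
    sheet = (
        df[["sample_id", "cohort"]].drop_duplicates().reset_index(drop=True)
        if "cohort" in df.columns
        else pd.DataFrame(columns=["sample_id", "cohort"])
    )
    sheet["phase"] = "none"
    sheet["notes"] = ""
    return records, sheet
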