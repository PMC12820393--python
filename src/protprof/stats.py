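"""Group comparisons, ROC discrimination and inhibition summaries.

Group tests follow the study design they support: two-sided Student's
t-tests with pooled variance (the equal-SD assumption; Welch available
behind a flag) for independent cohorts, and paired t-tests for matched
phases of the same patients.  No multiple-testing correction is applied by
default across the substrate x pH grid; Benjamini–Hochberg is available as
an option and recorded when used.

Degenerate-variance conventions (documented, deterministic): when both
groups have zero variance, equal means give statistic 0 / p = 1 and unequal
means give an infinite statistic / p = 0.

ROC analysis scores a single (substrate, pH) activity as a classifier
between two cohorts.  The AUC is the Mann–Whitney probability that a
random positive outscores a random negative, ties counting one half, and
equals the trapezoidal area under the empirical curve built from every
distinct score threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

from ._errors import InputError, PairingError

__all__ = [
    "TestResult",
    "RocResult",
    "InhibitionResult",
    "unpaired_t_test",
    "paired_t_test",
    "roc_curve_auc",
    "percent_inhibition",
    "inhibition_summary",
    "analyze_inhibition",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    ci95: tuple[float, float]
    n_a: int
    n_b: int
    test_kind: str  # unpaired_equal_var | unpaired_welch | paired


@dataclass(frozen=True)
class RocResult:
    auc: float
    positive_label: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class InhibitionResult:
    mean_percent_inhibition: float
    percent_inhibition: np.ndarray  # per sample, NaN where control <= 0
    sample_ids: tuple[str, ...]
    test: TestResult  # paired test, control vs inhibited rates


def _degenerate_result(
    mean_diff: float, df: int, n_a: int, n_b: int, kind: str
) -> TestResult:
    if mean_diff == 0:
        return TestResult(0.0, df, 1.0, (0.0, 0.0), n_a, n_b, kind)
    stat = math.inf if mean_diff > 0 else -math.inf
    return TestResult(stat, df, 0.0, (mean_diff, mean_diff), n_a, n_b, kind)


def unpaired_t_test(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided independent-samples t-test with 95% CI of the mean difference.

    Pooled-variance (Student) by default; ``equal_var=False`` switches to
    Welch with Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("both groups need at least 2 observations")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise InputError("group values must be finite")
    n_a, n_b = len(a), len(b)
    kind = "unpaired_equal_var" if equal_var else "unpaired_welch"
    mean_diff = float(np.mean(a) - np.mean(b))
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return _degenerate_result(mean_diff, n_a + n_b - 2, n_a, n_b, kind)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=int(round(float(res.df))),
        p_value=float(res.pvalue),
        ci95=(float(ci.low), float(ci.high)),
        n_a=n_a,
        n_b=n_b,
        test_kind=kind,
    )


def paired_t_test(x, y) -> TestResult:
    """Two-sided paired t-test (one-sample t on within-pair differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise PairingError(f"paired groups differ in length: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise InputError("paired test needs at least 2 pairs")
    d = x - y
    n = len(d)
    if np.var(d, ddof=1) == 0:
        return _degenerate_result(float(np.mean(d)), n - 1, n, n, "paired")
    res = sps.ttest_1samp(d, 0.0)
    ci = res.confidence_interval(0.95)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=n - 1,
        p_value=float(res.pvalue),
        ci95=(float(ci.low), float(ci.high)),
        n_a=n,
        n_b=n,
        test_kind="paired",
    )


def roc_curve_auc(scores, labels, positive_label) -> RocResult:
    """ROC curve and AUC for one continuous score against binary labels.

    The curve is thresholded at every distinct score, so it starts at
    (0, 0), ends at (1, 1) and its trapezoidal area equals the tie-aware
    Mann–Whitney AUC exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise InputError("scores and labels must have equal length")
    if np.any(~np.isfinite(scores)):
        raise InputError("scores must be finite")
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InputError(
            f"need both classes present; got {n_pos} positives, {n_neg} negatives"
        )
    fpr, tpr, thresholds = skm.roc_curve(
        pos.astype(int), scores, drop_intermediate=False
    )
    auc = float(skm.auc(fpr, tpr))
    return RocResult(
        auc=auc,
        positive_label=str(positive_label),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def percent_inhibition(control_rate: float, inhibited_rate: float) -> float:
    """100 * (1 - inhibited/control); NaN when the control rate is not positive.

    Negative values (apparent activation) are reported as-is.
    """
    if control_rate <= 0:
        return math.nan
    return 100.0 * (1.0 - inhibited_rate / control_rate)


def inhibition_summary(
    control_rates, inhibited_rates, sample_ids
) -> InhibitionResult:
    """Per-sample percent inhibition plus a paired control-vs-inhibitor test."""
    control = np.asarray(control_rates, dtype=float)
    inhibited = np.asarray(inhibited_rates, dtype=float)
    ids = tuple(str(s) for s in sample_ids)
    if not (len(control) == len(inhibited) == len(ids)):
        raise PairingError("control, inhibited and sample_ids must align")
    percents = np.array(
        [percent_inhibition(c, i) for c, i in zip(control, inhibited)]
    )
    return InhibitionResult(
        mean_percent_inhibition=float(np.nanmean(percents)),
        percent_inhibition=percents,
        sample_ids=ids,
        test=paired_t_test(control, inhibited),
    )


def analyze_inhibition(control_run, inhibited_run, options=None) -> InhibitionResult:
    """Percent inhibition from paired control/inhibitor plates.

    Both plates are normalized against the *control* plate's empty-well mean
    (a shared reference), so plate-gain differences between the two runs
    cancel before rates are compared sample by sample.
    """
    from .kinetics import empty_well_mean, estimate_activities

    reference = empty_well_mean(control_run)
    control = {
        r.sample_id: r.rate_rfu_per_min
        for r in estimate_activities([control_run], options=options,
                                     reference_value=reference)
    }
    inhibited = {
        r.sample_id: r.rate_rfu_per_min
        for r in estimate_activities([inhibited_run], options=options,
                                     reference_value=reference)
    }
    if set(control) != set(inhibited):
        raise PairingError(
            "control and inhibitor plates do not measure the same samples"
        )
    ids = sorted(control)
    return inhibition_summary(
        [control[s] for s in ids], [inhibited[s] for s in ids], ids
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional across the substrate x pH grid)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
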