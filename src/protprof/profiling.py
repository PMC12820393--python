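"""Activity matrices, cohort profiles and class contributions.

The per-sample rates are assembled into a samples x (substrate, pH) matrix;
cohort-level mean profiles summarize group trends (the heatmap view), and
normalized contributions express each substrate's — or each protease
class's — share of a cohort's total activity, either separately per pH
(default) or pooled across pH.

Fractions are computed from cohort *means* (matching the mean-based heatmap
representation), with negative means clamped to zero first: a share of
total activity cannot be negative, though raw means are always reported
unclamped.  Clipping for heatmap display is cosmetic and never alters
stored values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._errors import InputError, IntegrityError, PairingError
from .kinetics import ActivityRecord
from .panel import SubstratePanel

__all__ = [
    "ActivityMatrix",
    "CohortProfile",
    "ContributionTable",
    "build_activity_matrix",
    "cohort_mean_profile",
    "normalized_contributions",
    "plot_profile_heatmap",
]


class ActivityMatrix:
    """Samples x (substrate, pH) rate matrix with cohort annotations."""

    def __init__(self, data: pd.DataFrame, sample_info: pd.DataFrame):
        self.data = data  # index: sample_id; columns: MultiIndex (substrate_id, ph)
        self.sample_info = sample_info.set_index("sample_id") if (
            "sample_id" in sample_info.columns
        ) else sample_info

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[tuple[str, float]]:
        return list(self.data.columns)

    def cohort_of(self, sample_id: str) -> str:
        return str(self.sample_info.loc[sample_id, "cohort"])

    def column(self, substrate_id: str, ph: float) -> pd.Series:
        return self.data[(substrate_id, float(ph))]


class CohortProfile:
    """Mean rate per (cohort, substrate, pH) with contributing-sample counts."""

    def __init__(self, means: pd.DataFrame, counts: pd.DataFrame,
                 clip_range: tuple[float, float] | None = None):
        self.means = means  # index: cohort; columns: (substrate_id, ph)
        self.counts = counts
        self.clip_range = clip_range

    @property
    def cohorts(self) -> list[str]:
        return list(self.means.index)

    def to_frame(self) -> pd.DataFrame:
        long = self.means.stack(future_stack=True).stack(future_stack=True)
        long.index.names = ["cohort", "ph", "substrate_id"]
        out = long.rename("mean_rate").reset_index()
        n = self.counts.stack(future_stack=True).stack(future_stack=True)
        n.index.names = ["cohort", "ph", "substrate_id"]
        out["n"] = n.reset_index(drop=True)
        return out[["cohort", "substrate_id", "ph", "mean_rate", "n"]]


class ContributionTable:
    """Normalized activity shares; every positive-denominator block sums to 1."""

    def __init__(self, table: pd.DataFrame, level: str, scope: str):
        self.table = table  # cohort, ph, unit, level, fraction, denominator
        self.level = level
        self.scope = scope

    def fraction(self, cohort: str, ph, unit: str) -> float:
        t = self.table
        hit = t[(t["cohort"] == cohort) & (t["ph"] == ph) & (t["unit"] == unit)]
        if hit.empty:
            raise InputError(f"no contribution cell ({cohort}, {ph}, {unit})")
        return float(hit["fraction"].iloc[0])


def build_activity_matrix(
    records: list[ActivityRecord],
    sheet: pd.DataFrame,
    drop_excluded: bool = True,
) -> ActivityMatrix:
    """Pivot activity records into the samples x conditions matrix.

    QC-excluded samples are either dropped entirely (``drop_excluded=True``)
    or kept as all-missing rows so the matrix still documents them.
    """
    known = set(sheet["sample_id"])
    cells: dict[tuple[str, tuple[str, float]], float] = {}
    excluded_samples = set()
    for r in records:
        if r.sample_id not in known:
            raise PairingError(f"sample {r.sample_id!r} is not in the sample sheet")
        key = (r.sample_id, (r.substrate_id, float(r.ph)))
        if key in cells:
            raise IntegrityError(
                f"duplicate activity record for {r.sample_id}/"
                f"{r.substrate_id}/pH {r.ph}"
            )
        if r.qc_excluded:
            excluded_samples.add(r.sample_id)
            cells[key] = np.nan
        else:
            cells[key] = r.rate_rfu_per_min

    sample_order = [s for s in sheet["sample_id"] if any(k[0] == s for k in cells)]
    col_order: list[tuple[str, float]] = []
    for r in records:
        c = (r.substrate_id, float(r.ph))
        if c not in col_order:
            col_order.append(c)
    data = pd.DataFrame(
        index=pd.Index(sample_order, name="sample_id"),
        columns=pd.MultiIndex.from_tuples(col_order, names=["substrate_id", "ph"]),
        dtype=float,
    )
    for (sample, cond), value in cells.items():
        data.loc[sample, cond] = value
    if drop_excluded:
        data = data.drop(index=[s for s in excluded_samples if s in data.index])
    return ActivityMatrix(data=data, sample_info=sheet.copy())


def cohort_mean_profile(
    matrix: ActivityMatrix, clip_range: tuple[float, float] | None = None
) -> CohortProfile:
    """Arithmetic mean per (cohort, substrate, pH) over non-missing samples.

    Cohorts present in the sample sheet but empty in the matrix produce a
    warning and an all-missing row rather than an exception.
    """
    cohorts = list(dict.fromkeys(matrix.sample_info["cohort"]))
    rows_means, rows_counts = [], []
    for cohort in cohorts:
        members = [
            s for s in matrix.samples if matrix.cohort_of(s) == cohort
        ]
        if not members:
            warnings.warn(f"cohort {cohort!r} has no usable samples", stacklevel=2)
            rows_means.append(pd.Series(np.nan, index=matrix.data.columns, name=cohort))
            rows_counts.append(pd.Series(0, index=matrix.data.columns, name=cohort))
            continue
        block = matrix.data.loc[members]
        rows_means.append(block.mean(axis=0, skipna=True).rename(cohort))
        rows_counts.append(block.notna().sum(axis=0).rename(cohort))
    means = pd.DataFrame(rows_means)
    counts = pd.DataFrame(rows_counts)
    means.index.name = counts.index.name = "cohort"
    return CohortProfile(means=means, counts=counts, clip_range=clip_range)


def normalized_contributions(
    profile: CohortProfile,
    panel: SubstratePanel,
    level: str = "class",
    scope: str = "per_ph",
) -> ContributionTable:
    """Share of total activity per substrate or per protease class.

    ``scope='per_ph'`` normalizes within each (cohort, pH) block;
    ``scope='across_ph'`` pools all pH conditions per cohort (the pooled
    rows carry ``ph='all'``).  Blocks whose clamped total is zero yield
    missing fractions, flagged by a NaN denominator share.
    """
    if level not in ("substrate", "class"):
        raise InputError(f"unknown contribution level {level!r}")
    if scope not in ("per_ph", "across_ph"):
        raise InputError(f"unknown contribution scope {scope!r}")
    means = profile.means
    for substrate_id, _ in means.columns:
        panel.entry(substrate_id)  # raises on substrates absent from the panel

    clamped = means.clip(lower=0.0)

    def unit_of(substrate_id: str) -> str:
        return substrate_id if level == "substrate" else panel.class_of(substrate_id)

    rows = []
    for cohort in clamped.index:
        series = clamped.loc[cohort]
        if scope == "per_ph":
            ph_values = sorted({ph for _, ph in means.columns})
            blocks = [
                (ph, series[[c for c in means.columns if c[1] == ph]]) for ph in ph_values
            ]
        else:
            blocks = [("all", series)]
        for ph, block in blocks:
            totals: dict[str, float] = {}
            for (substrate_id, _), value in block.items():
                if np.isnan(value):
                    continue
                unit = unit_of(substrate_id)
                totals[unit] = totals.get(unit, 0.0) + float(value)
            denom = sum(totals.values())
            units = (
                sorted(totals)
                if level == "substrate"
                else [c for c in ("serine", "cysteine") if c in totals]
            )
            for unit in units:
                rows.append(
                    {
                        "cohort": cohort,
                        "ph": ph,
                        "unit": unit,
                        "level": level,
                        "fraction": (totals[unit] / denom) if denom > 0 else np.nan,
                        "denominator": denom,
                    }
                )
    return ContributionTable(pd.DataFrame(rows), level=level, scope=scope)


def plot_profile_heatmap(
    profile: CohortProfile,
    clip_range: tuple[float, float] = (0.0, 600.0),
    path=None,
):
    """Render the cohort-mean heatmap (substrates x cohort/pH columns).

    Purely cosmetic: display values are clipped to ``clip_range`` but the
    profile itself is untouched.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = profile.means.T  # rows: (substrate, ph); columns: cohort
    frame = frame.sort_index(level=[1, 0])
    values = frame.to_numpy(dtype=float)
    values = np.clip(values, clip_range[0], clip_range[1])
    fig, ax = plt.subplots(
        figsize=(2 + 1.2 * frame.shape[1], 1 + 0.25 * frame.shape[0])
    )
    im = ax.imshow(values, aspect="auto", cmap="inferno",
                   vmin=clip_range[0], vmax=clip_range[1])
    ax.set_xticks(range(frame.shape[1]), frame.columns)
    ax.set_yticks(
        range(frame.shape[0]),
        [f"{s} @ pH {ph}" for s, ph in frame.index],
        fontsize=6,
    )
    fig.colorbar(im, ax=ax, label="mean activity (RFU/min)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
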