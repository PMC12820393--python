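"""End-to-end orchestration: data (or simulation) -> QC -> rates -> profiles -> stats.

A run is described by a :class:`RunConfig` (usually loaded from YAML) with
exactly one data source — either paths to a kinetics table + sample sheet,
or a simulation block.  ``run_pipeline`` executes the fixed chain and
writes a report bundle:

* ``qc_report.csv`` — per-sample intrinsic baselines, threshold, exclusions
* ``activity_table.csv`` — per (sample, substrate, pH) rates with windows
* ``cohort_profile.csv`` — cohort-mean rates per condition
* ``contributions.csv`` — normalized substrate/class activity shares
* ``stats_report.csv`` — cohort comparisons per (substrate, pH)
* ``roc_curves.csv`` + ``roc_summary.json`` — requested discriminations
* ``manifest.json`` — config hash, seed, thresholds, warnings

Identical config and seed give a byte-identical bundle; every policy and
threshold that affects a number is recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigError, ReportError
from .kinetics import (
    LinearPhaseOptions,
    activity_table,
    estimate_activities,
)
from .panel import load_substrate_panel
from .plate_io import (
    read_kinetic_table,
    read_sample_sheet,
    validate_layout,
    write_kinetic_table,
    write_sample_sheet,
)
from .profiling import build_activity_matrix, cohort_mean_profile, normalized_contributions
from .qc import (
    AbsolutePolicy,
    AdaptivePolicy,
    collect_intrinsic_baselines,
    flag_high_background,
    qc_report,
)
from .simulate import SimulationConfig, simulate_study
from .stats import benjamini_hochberg, roc_curve_auc, unpaired_t_test

log = logging.getLogger("protprof")

BUNDLE_MEMBERS = [
    "qc_report.csv",
    "activity_table.csv",
    "cohort_profile.csv",
    "contributions.csv",
    "stats_report.csv",
    "roc_curves.csv",
    "roc_summary.json",
    "manifest.json",
]


@dataclass
class RocSpec:
    positive: str
    negative: str
    substrate: str
    ph: float


@dataclass
class RunConfig:
    simulation: SimulationConfig | None = None
    kinetics_path: str | None = None
    samples_path: str | None = None
    qc_policy: AbsolutePolicy | AdaptivePolicy = field(default_factory=AdaptivePolicy)
    kinetics_options: LinearPhaseOptions = field(default_factory=LinearPhaseOptions)
    reference_plate: str | None = None
    contribution_level: str = "class"
    contribution_scope: str = "per_ph"
    comparisons: tuple[tuple[str, str], ...] = ()
    roc: tuple[RocSpec, ...] = ()
    bh_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.kinetics_path is not None or self.samples_path is not None
        if has_files and (self.kinetics_path is None or self.samples_path is None):
            raise ConfigError("file input needs both kinetics and samples paths")
        if (self.simulation is not None) and has_files:
            raise ConfigError("config must give either input files or a simulation, not both")
        if (self.simulation is None) and not has_files:
            raise ConfigError("config must give input files or a simulation block")

    def describe(self) -> dict:
        """JSON-serializable summary used for hashing and the manifest."""
        d = {
            "seed": self.seed,
            "qc_policy": (
                {"kind": "absolute", "threshold_rfu": self.qc_policy.threshold_rfu}
                if isinstance(self.qc_policy, AbsolutePolicy)
                else {"kind": "adaptive", "k": self.qc_policy.k}
            ),
            "kinetics_options": {
                "t_min_window": self.kinetics_options.t_min_window,
                "t_max_window": self.kinetics_options.t_max_window,
                "min_points": self.kinetics_options.min_points,
                "linearity_tol": self.kinetics_options.linearity_tol,
                "activity_floor_rfu_per_min": self.kinetics_options.activity_floor_rfu_per_min,
            },
            "reference_plate": self.reference_plate,
            "contribution_level": self.contribution_level,
            "contribution_scope": self.contribution_scope,
            "comparisons": [list(c) for c in self.comparisons],
            "roc": [
                {"positive": r.positive, "negative": r.negative,
                 "substrate": r.substrate, "ph": r.ph}
                for r in self.roc
            ],
            "bh_correction": self.bh_correction,
        }
        if self.simulation is not None:
            sim = self.simulation
            d["simulation"] = {
                "cohorts": [list(c) for c in sim.cohorts],
                "ph_levels": list(sim.ph_levels),
                "substrates": list(sim.substrate_ids),
                "cv_log": sim.cv_log,
                "depletion_timescale_min": (
                    "inf" if math.isinf(sim.depletion_timescale_min)
                    else sim.depletion_timescale_min
                ),
                "noise_sd_rfu": sim.noise_sd_rfu,
                "background_mean_rfu": sim.background_mean_rfu,
                "background_sd_rfu": sim.background_sd_rfu,
                "high_background_fraction": sim.high_background_fraction,
                "high_background_multiplier": sim.high_background_multiplier,
                "plate_gain_sd": sim.plate_gain_sd,
                "replicates": sim.replicates,
                "timepoints_min": list(sim.timepoints_min),
                "seed": sim.seed,
            }
        else:
            d["inputs"] = {"kinetics": str(self.kinetics_path),
                           "samples": str(self.samples_path)}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.describe(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _simulation_from_dict(d: dict, seed: int | None) -> SimulationConfig:
    d = dict(d)
    cohorts = d.pop("cohorts", None)
    if cohorts is None:
        raise ConfigError("simulation block needs 'cohorts'")
    if isinstance(cohorts, dict):
        cohorts = tuple(cohorts.items())
    else:
        cohorts = tuple((c[0], c[1]) for c in cohorts)
    effect = d.pop("effect_matrix", "default")
    panel = load_substrate_panel(d.pop("panel", None))
    ph_levels = tuple(float(p) for p in d.pop("ph_levels", (5.5, 6.5, 7.5, 8.0)))
    if isinstance(effect, str) and effect == "default":
        effect_df = None
    elif isinstance(effect, str):
        effect_df = pd.read_csv(effect)
    else:
        raise ConfigError("effect_matrix must be 'default' or a CSV path")
    tau = d.pop("depletion_timescale_min", 40.0)
    if isinstance(tau, str):
        if tau not in ("inf", "infinite", ".inf"):
            raise ConfigError(f"bad depletion_timescale_min: {tau!r}")
        tau = math.inf
    if seed is not None:
        d["seed"] = int(seed)
    known = {
        "cv_log", "noise_sd_rfu", "background_mean_rfu", "background_sd_rfu",
        "high_background_fraction", "high_background_multiplier", "plate_gain_sd",
        "replicates", "timepoints_min", "empty_well_rfu", "substrate_only_rfu",
        "n_empty_wells", "n_substrate_only_wells", "seed", "substrates",
    }
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    if "timepoints_min" in d:
        d["timepoints_min"] = tuple(float(t) for t in d["timepoints_min"])
    if "substrates" in d and d["substrates"] is not None:
        d["substrates"] = tuple(d["substrates"])
    return SimulationConfig(
        cohorts=cohorts, effect_matrix=effect_df, ph_levels=ph_levels,
        depletion_timescale_min=float(tau), panel=panel, **d,
    )


def config_from_yaml(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a run configuration; ``seed`` (if given) overrides the file's."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    sim = None
    kinetics_path = samples_path = None
    if "simulation" in raw and "inputs" in raw:
        raise ConfigError("config must give either 'simulation' or 'inputs', not both")
    if "simulation" in raw:
        sim = _simulation_from_dict(raw["simulation"], seed)
    elif "inputs" in raw:
        inputs = raw["inputs"]
        kinetics_path = inputs.get("kinetics")
        samples_path = inputs.get("samples")
    qc_raw = raw.get("qc", {}) or {}
    if qc_raw.get("policy", "adaptive") == "absolute":
        if "threshold_rfu" not in qc_raw:
            raise ConfigError("absolute QC policy needs 'threshold_rfu'")
        policy = AbsolutePolicy(float(qc_raw["threshold_rfu"]))
    else:
        policy = AdaptivePolicy(float(qc_raw.get("k", 10.0)))
    kin_raw = raw.get("kinetics", {}) or {}
    options = LinearPhaseOptions(
        t_min_window=float(kin_raw.get("t_min_window", 5.0)),
        t_max_window=float(kin_raw.get("t_max_window", 20.0)),
        min_points=int(kin_raw.get("min_points", 4)),
        linearity_tol=float(kin_raw.get("linearity_tol", 0.02)),
        activity_floor_rfu_per_min=float(kin_raw.get("activity_floor_rfu_per_min", 1.0)),
    )
    prof_raw = raw.get("profiling", {}) or {}
    stats_raw = raw.get("stats", {}) or {}
    comparisons = tuple(
        (str(a), str(b)) for a, b in stats_raw.get("comparisons", [])
    )
    roc = tuple(
        RocSpec(
            positive=str(r["positive"]), negative=str(r["negative"]),
            substrate=str(r["substrate"]), ph=float(r["ph"]),
        )
        for r in stats_raw.get("roc", [])
    )
    cfg_seed = raw.get("seed", 0) if seed is None else seed
    return RunConfig(
        simulation=sim,
        kinetics_path=kinetics_path,
        samples_path=samples_path,
        qc_policy=policy,
        kinetics_options=options,
        reference_plate=kin_raw.get("reference_plate"),
        contribution_level=str(prof_raw.get("level", "class")),
        contribution_scope=str(prof_raw.get("scope", "per_ph")),
        comparisons=comparisons,
        roc=roc,
        bh_correction=bool(stats_raw.get("bh_correction", False)),
        seed=int(cfg_seed),
    )


@dataclass
class RunBundle:
    out_dir: Path
    paths: dict[str, Path]
    manifest: dict


def _plate_factors(runs, reference_plate_id: str | None) -> dict[str, float]:
    from .kinetics import empty_well_mean, plate_normalization_factor

    if reference_plate_id is not None:
        reference = next(r for r in runs if r.plate_id == reference_plate_id)
    else:
        flagged = [r for r in runs if r.is_reference_plate]
        reference = flagged[0] if flagged else runs[0]
    ref_value = empty_well_mean(reference)
    return {
        r.plate_id: plate_normalization_factor(r, ref_value).factor for r in runs
    }


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunBundle:
    """Execute the full analysis chain and write the report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    panel = load_substrate_panel()

    if config.simulation is not None:
        runs, sheet, truth = simulate_study(config.simulation)
        write_kinetic_table(runs, out_dir / "kinetics.csv")
        write_sample_sheet(sheet, out_dir / "samples.csv")
        truth.write(
            out_dir / "truth_rates.csv",
            out_dir / "truth_samples.csv",
            out_dir / "truth_plates.csv",
        )
    else:
        runs = read_kinetic_table(config.kinetics_path)
        sheet = read_sample_sheet(config.samples_path)

    issues = validate_layout(runs, sheet, panel)
    for issue in issues:
        warnings_log.append(f"layout: {issue.message}")
        log.warning("layout issue: %s", issue.message)

    baselines = collect_intrinsic_baselines(runs)
    flags = flag_high_background(baselines, runs, config.qc_policy)
    qc_df = qc_report(baselines, flags)
    _write_csv(qc_df, out_dir / "qc_report.csv")

    records = estimate_activities(
        runs,
        qc_flags=flags,
        reference_plate_id=config.reference_plate,
        options=config.kinetics_options,
    )
    act_df = activity_table(records, sheet)
    _write_csv(act_df, out_dir / "activity_table.csv")

    matrix = build_activity_matrix(records, sheet, drop_excluded=True)
    profile = cohort_mean_profile(matrix)
    _write_csv(profile.to_frame(), out_dir / "cohort_profile.csv")
    contributions = normalized_contributions(
        profile,
        panel,
        level=config.contribution_level,
        scope=config.contribution_scope,
    )
    _write_csv(contributions.table, out_dir / "contributions.csv")

    cohort_of = dict(zip(sheet["sample_id"], sheet["cohort"]))
    stat_rows = []
    for cohort_a, cohort_b in config.comparisons:
        for substrate_id, ph in matrix.conditions:
            col = matrix.column(substrate_id, ph)
            a = col[[s for s in col.index if cohort_of.get(s) == cohort_a]].dropna()
            b = col[[s for s in col.index if cohort_of.get(s) == cohort_b]].dropna()
            if len(a) < 2 or len(b) < 2:
                warnings_log.append(
                    f"comparison {cohort_a} vs {cohort_b} skipped for "
                    f"{substrate_id}/pH {ph}: fewer than 2 samples per group"
                )
                continue
            res = unpaired_t_test(a.to_numpy(), b.to_numpy())
            stat_rows.append(
                {
                    "comparison": f"{cohort_a}_vs_{cohort_b}",
                    "substrate_id": substrate_id,
                    "ph": ph,
                    "test_kind": res.test_kind,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "statistic": res.statistic,
                    "df": res.degrees_of_freedom,
                    "p_value": res.p_value,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                }
            )
    stats_df = pd.DataFrame(
        stat_rows,
        columns=["comparison", "substrate_id", "ph", "test_kind", "n_a", "n_b",
                 "statistic", "df", "p_value", "ci_low", "ci_high"],
    )
    if config.bh_correction and not stats_df.empty:
        stats_df["p_adjusted_bh"] = benjamini_hochberg(stats_df["p_value"])
    _write_csv(stats_df, out_dir / "stats_report.csv")

    roc_rows = []
    roc_summary = {}
    for spec in config.roc:
        cond = (spec.substrate, float(spec.ph))
        if cond not in matrix.conditions:
            warnings_log.append(
                f"ROC {spec.positive} vs {spec.negative} skipped: condition "
                f"{spec.substrate}/pH {spec.ph} absent"
            )
            continue
        col = matrix.column(*cond)
        keep = [
            s for s in col.index
            if cohort_of.get(s) in (spec.positive, spec.negative)
            and not np.isnan(col[s])
        ]
        labels = [cohort_of[s] for s in keep]
        if labels.count(spec.positive) == 0 or labels.count(spec.negative) == 0:
            warnings_log.append(
                f"ROC {spec.positive} vs {spec.negative} on {spec.substrate}/"
                f"pH {spec.ph} skipped: a class has no usable samples"
            )
            continue
        roc = roc_curve_auc(col[keep].to_numpy(), np.array(labels), spec.positive)
        key = f"{spec.positive}_vs_{spec.negative}:{spec.substrate}:pH{spec.ph}"
        roc_summary[key] = {
            "auc": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg,
            "positive_label": roc.positive_label,
        }
        for f, t, th in zip(roc.fpr, roc.tpr, roc.thresholds):
            roc_rows.append(
                {"comparison": key, "fpr": float(f), "tpr": float(t),
                 "threshold": float(th)}
            )
    _write_csv(
        pd.DataFrame(roc_rows, columns=["comparison", "fpr", "tpr", "threshold"]),
        out_dir / "roc_curves.csv",
    )
    (out_dir / "roc_summary.json").write_text(
        json.dumps(roc_summary, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )

    manifest = {
        "package_version": __version__,
        "config": config.describe(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_plates": len(runs),
        "n_samples": int(sheet["sample_id"].nunique()),
        "n_excluded": int(qc_df["excluded"].sum()) if not qc_df.empty else 0,
        "qc_threshold_rfu": (
            float(qc_df["threshold_used"].iloc[0]) if not qc_df.empty else None
        ),
        "normalization_factors": _plate_factors(runs, config.reference_plate),
        "warnings": warnings_log,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    paths = {name: out_dir / name for name in BUNDLE_MEMBERS}
    return RunBundle(out_dir=out_dir, paths=paths, manifest=manifest)


def render_report(bundle: RunBundle | str | Path) -> str:
    """Plain-text summary of a report bundle (deterministic)."""
    out_dir = bundle.out_dir if isinstance(bundle, RunBundle) else Path(bundle)
    for name in BUNDLE_MEMBERS:
        if not (out_dir / name).exists():
            raise ReportError(f"bundle member missing: {name}")
    manifest = json.loads((out_dir / "manifest.json").read_text())
    qc_df = pd.read_csv(out_dir / "qc_report.csv")
    act = pd.read_csv(out_dir / "activity_table.csv")
    contrib = pd.read_csv(out_dir / "contributions.csv")
    stats_df = pd.read_csv(out_dir / "stats_report.csv")
    roc_summary = json.loads((out_dir / "roc_summary.json").read_text())

    lines = [
        "protease activity profiling report",
        "==================================",
        f"config hash: {manifest['config_hash'][:12]}  seed: {manifest['seed']}",
        f"{manifest['n_samples']} samples on {manifest['n_plates']} plates; "
        f"{manifest['n_excluded']} samples excluded "
        f"(QC threshold {manifest['qc_threshold_rfu']:.1f} RFU)"
        if manifest["qc_threshold_rfu"] is not None
        else f"{manifest['n_samples']} samples on {manifest['n_plates']} plates",
        "",
        "cohorts:",
    ]
    usable = act[~act["qc_excluded"]] if not act.empty else act
    for cohort in sorted(set(act["cohort"].dropna()) - {""}):
        block = usable[usable["cohort"] == cohort]
        if block.empty:
            lines.append(f"  {cohort}: no usable samples")
            continue
        top = block.groupby("substrate_id")["rate_rfu_per_min"].mean().idxmax()
        lines.append(
            f"  {cohort}: {block['sample_id'].nunique()} samples; "
            f"most active substrate {top}"
        )
    class_rows = contrib[contrib["level"] == "class"] if not contrib.empty else contrib
    if not class_rows.empty:
        lines.append("")
        lines.append("cysteine-class share of total activity:")
        for _, row in class_rows[class_rows["unit"] == "cysteine"].iterrows():
            lines.append(
                f"  {row['cohort']} pH {row['ph']}: {100 * row['fraction']:.1f}%"
            )
    if not stats_df.empty:
        sig = stats_df[stats_df["p_value"] < 0.05]
        lines.append("")
        lines.append(
            f"cohort comparisons: {len(stats_df)} tests, {len(sig)} with p < 0.05"
        )
    if roc_summary:
        lines.append("")
        lines.append("ROC discriminations:")
        for key in sorted(roc_summary):
            lines.append(f"  {key}: AUC = {roc_summary[key]['auc']:.3f}")
    if manifest["warnings"]:
        lines.append("")
        lines.append(f"warnings ({len(manifest['warnings'])}):")
        lines.extend(f"  - {w}" for w in manifest["warnings"])
    else:
        lines.append("")
        lines.append("warnings (0)")
    return "\n".join(lines) + "\n"
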