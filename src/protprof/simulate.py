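"""Synthetic plate-reader datasets with known ground truth.

The generator emulates the statistical structure of a multi-substrate,
multi-pH fecal protease assay so every downstream stage (QC, normalization,
slope estimation, profiling, statistics) can be exercised against known
truth without any measured data.

Generative model
----------------
A digestion well for sample *i* on plate *p* follows a single-exponential
product-formation curve with additive Gaussian read noise::

    RFU(t) = g_p * (B_i + v * tau * (1 - exp(-t / tau))) + eps,   eps ~ N(0, sd^2)

where ``v`` is the sample's true cleavage rate (RFU/min), ``B_i`` its
constant intrinsic baseline, ``g_p`` the plate gain and ``tau`` the
substrate-depletion timescale.  In the limit ``tau -> inf`` the curve is
exactly affine, ``RFU(t) = g_p * (B_i + v t) + eps``, which is the regime
the linear-phase slope estimator assumes at early times.

True rates are cohort-structured with lognormal inter-individual spread::

    v[i, s, ph] = mu[cohort(i), s, ph] * exp(N(0, sigma^2)),
    sigma^2 = ln(1 + cv_log^2)

drawn independently per (sample, substrate, pH) condition.  A configurable
fraction of samples is a high-background subpopulation (emulating soluble
fluorophores such as incompletely absorbed mesalazine) whose intrinsic
baseline is inflated by a large multiplier.

Reproducibility
---------------
All randomness derives from one integer seed through five fixed,
documented substreams (high-background indicators; baselines; lognormal
rate multipliers; plate gains; read noise), each a
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` stream.  The same seed
therefore yields a bit-identical dataset, and any single substream can be
re-drawn in isolation (e.g. to recount the high-background Bernoulli draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ConfigError, InputError
from .panel import SubstratePanel, load_substrate_panel
from .plates import KineticTrace, PlateRun, WellRole

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "InhibitionDataset",
    "default_effect_matrix",
    "simulate_kinetic_trace",
    "simulate_study",
    "simulate_inhibition_experiment",
    "substream",
]

DEFAULT_PH_LEVELS = (5.5, 6.5, 7.5, 8.0)
DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(0, 80, 5))  # 0..75 min, 5-min reads

# Substream tags (spawn keys) of the dataset-level RNG.
STREAM_HIGH_BACKGROUND = 0
STREAM_BASELINES = 1
STREAM_RATE_MULTIPLIERS = 2
STREAM_PLATE_GAINS = 3
STREAM_NOISE = 4


def substream(seed: int, tag: int) -> np.random.Generator:
    """Generator for one documented substream of a dataset seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tag,)))


def default_effect_matrix(
    panel: SubstratePanel | None = None,
    ph_levels: tuple[float, ...] = DEFAULT_PH_LEVELS,
    cohorts: tuple[str, ...] = ("HC", "CD", "UC", "IBS"),
) -> pd.DataFrame:
    """Illustrative cohort-level mean rates mu[cohort, substrate, pH].

    These values are NOT measurements; they are a synthetic effect matrix
    that qualitatively mirrors the group-level trends the analysis is
    designed to resolve: healthy controls near-silent everywhere; CD and UC
    broadly elevated with UC relatively richer in cathepsin-like (cysteine)
    activity; IBS dominated by furin-like serine activity with a dip at
    pH 7.5; the short furin-motif substrate Ac-PHLVRQKR-AMC a poor substrate
    everywhere; and the cathepsin substrate Ac-RSVL-AMC separating UC from
    CD at pH 5.5.  Rates are in RFU/min.
    """
    if panel is None:
        panel = load_substrate_panel()
    base = {
        # (cohort, subclass) -> mean rate inside the substrate's pH optimum
        ("HC", "elastase-like"): 3.0,
        ("HC", "furin-like"): 6.0,
        ("HC", "SKI-1/S1P-like"): 5.0,
        ("HC", "trypsin-like"): 6.0,
        ("HC", "cathepsin-like"): 5.0,
        ("CD", "elastase-like"): 20.0,
        ("CD", "furin-like"): 300.0,
        ("CD", "SKI-1/S1P-like"): 220.0,
        ("CD", "trypsin-like"): 200.0,
        ("CD", "cathepsin-like"): 180.0,
        ("UC", "elastase-like"): 20.0,
        ("UC", "furin-like"): 250.0,
        ("UC", "SKI-1/S1P-like"): 180.0,
        ("UC", "trypsin-like"): 180.0,
        ("UC", "cathepsin-like"): 260.0,
        ("IBS", "elastase-like"): 8.0,
        ("IBS", "furin-like"): 400.0,
        ("IBS", "SKI-1/S1P-like"): 60.0,
        ("IBS", "trypsin-like"): 80.0,
        ("IBS", "cathepsin-like"): 40.0,
    }
    rows = []
    for cohort in cohorts:
        for entry in panel:
            for ph in ph_levels:
                mu = base[(cohort, entry.subclass)]
                if not entry.ph_in_optimum(ph):
                    mu *= 0.25  # activity decays away from the optimum
                if entry.subclass == "cathepsin-like" and ph == 7.5 and cohort in ("CD", "UC"):
                    # inflamed-gut extracts keep cysteine-class activity just
                    # above neutral pH; UC markedly prefers these substrates
                    mu = {"CD": 200.0, "UC": 280.0}[cohort]
                if ph == 5.5:
                    mu *= 0.5  # globally weakest condition
                if entry.substrate_id == "Ac-PHLVRQKR-AMC":
                    mu *= 0.05  # two residues shorter than its parent, barely cleaved
                if entry.substrate_id == "Ac-RSVL-AMC" and ph == 5.5:
                    mu = {"HC": 3.0, "CD": 45.0, "UC": 90.0, "IBS": 15.0}.get(cohort, mu)
                if cohort == "IBS" and entry.subclass == "furin-like" and ph == 7.5:
                    mu *= 0.5  # non-monotonic pH profile of furin-motif cleavage
                rows.append((cohort, entry.substrate_id, float(ph), float(mu)))
    return pd.DataFrame(rows, columns=["cohort", "substrate_id", "ph", "rate"])


@dataclass
class SimulationConfig:
    """Parameters of a synthetic assay campaign.

    Defaults correspond to the study design being emulated: four cohorts
    (12 HC, 12 CD, 11 UC, 4 IBS), the full 14-substrate panel at four pH
    levels, triplicate digestion wells, 5-minute reads over 75 minutes, and
    roughly one in five samples carrying a strongly elevated intrinsic
    baseline.
    """

    cohorts: tuple[tuple[str, int], ...] = (("HC", 12), ("CD", 12), ("UC", 11), ("IBS", 4))
    effect_matrix: pd.DataFrame | None = None  # defaults to default_effect_matrix()
    ph_levels: tuple[float, ...] = DEFAULT_PH_LEVELS
    substrates: tuple[str, ...] | None = None  # None = full panel
    cv_log: float = 0.6
    depletion_timescale_min: float = 40.0  # math.inf = ideal linear traces
    noise_sd_rfu: float = 15.0
    background_mean_rfu: float = 20.0
    background_sd_rfu: float = 5.0
    high_background_fraction: float = 0.2
    high_background_multiplier: float = 50.0
    plate_gain_sd: float = 0.05
    replicates: int = 3
    timepoints_min: tuple[float, ...] = DEFAULT_TIMEPOINTS
    empty_well_rfu: float = 50.0
    substrate_only_rfu: float = 30.0
    n_empty_wells: int = 3
    n_substrate_only_wells: int = 3
    seed: int = 0
    panel: SubstratePanel = field(default_factory=load_substrate_panel, repr=False)

    def __post_init__(self) -> None:
        self.cohorts = tuple((str(c), int(n)) for c, n in
                             (self.cohorts.items() if isinstance(self.cohorts, dict)
                              else self.cohorts))
        if not self.cohorts or any(n < 1 for _, n in self.cohorts):
            raise ConfigError("every cohort needs n_samples >= 1")
        if len({c for c, _ in self.cohorts}) != len(self.cohorts):
            raise ConfigError("cohort labels must be unique")
        if self.cv_log < 0:
            raise ConfigError("cv_log must be >= 0")
        if not self.depletion_timescale_min > 0:
            raise ConfigError("depletion timescale must be > 0 (use inf for linear)")
        if self.noise_sd_rfu < 0:
            raise ConfigError("noise_sd_rfu must be >= 0")
        if not 0 <= self.high_background_fraction <= 1:
            raise ConfigError("high_background_fraction must be in [0, 1]")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        tp = np.asarray(self.timepoints_min, dtype=float)
        if len(tp) < 4 or np.any(np.diff(tp) <= 0):
            raise ConfigError("timepoints must be strictly increasing with >= 4 points")
        self.timepoints_min = tuple(float(t) for t in tp)
        if self.substrates is not None:
            self.substrates = tuple(self.substrates)
            for s in self.substrates:
                self.panel.entry(s)  # raises if unknown
        if self.effect_matrix is None:
            self.effect_matrix = default_effect_matrix(
                self.panel, self.ph_levels, tuple(c for c, _ in self.cohorts)
            )

    @property
    def substrate_ids(self) -> tuple[str, ...]:
        return self.substrates if self.substrates is not None else tuple(self.panel.ids)

    @property
    def sigma_log(self) -> float:
        """Lognormal sigma implied by the inter-individual CV."""
        return math.sqrt(math.log(1.0 + self.cv_log**2))

    def sample_ids(self) -> list[tuple[str, str]]:
        """[(sample_id, cohort)] in the fixed generation order."""
        out = []
        for cohort, n in self.cohorts:
            for i in range(1, n + 1):
                out.append((f"{cohort}{i:03d}", cohort))
        return out

    def mean_rate(self, cohort: str, substrate_id: str, ph: float) -> float:
        em = self.effect_matrix
        hit = em[
            (em["cohort"] == cohort)
            & (em["substrate_id"] == substrate_id)
            & (np.isclose(em["ph"].astype(float), ph))
        ]
        if len(hit) == 0:
            raise ConfigError(
                f"effect matrix has no cell for ({cohort}, {substrate_id}, pH {ph})"
            )
        if len(hit) > 1:
            raise ConfigError(
                f"effect matrix has duplicate cells for ({cohort}, {substrate_id}, pH {ph})"
            )
        mu = float(hit["rate"].iloc[0])
        if mu < 0:
            raise ConfigError("mean rates must be >= 0")
        return mu


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a synthetic dataset.

    ``rates`` has one row per (sample, substrate, pH) with the true cleavage
    rate; ``samples`` one row per sample with its intrinsic baseline and
    high-background indicator; ``plates`` one row per plate with its gain.
    """

    rates: pd.DataFrame  # sample_id, cohort, substrate_id, ph, rate_rfu_per_min
    samples: pd.DataFrame  # sample_id, cohort, baseline_rfu, high_background
    plates: pd.DataFrame  # plate_id, gain
    seed: int

    def write(self, rates_csv, samples_csv, plates_csv) -> None:
        self.rates.to_csv(rates_csv, index=False, lineterminator="\n")
        self.samples.to_csv(samples_csv, index=False, lineterminator="\n")
        self.plates.to_csv(plates_csv, index=False, lineterminator="\n")


def _product_curve(rate: float, tau: float, t: np.ndarray) -> np.ndarray:
    if math.isinf(tau):
        return rate * t
    return rate * tau * (1.0 - np.exp(-t / tau))


def simulate_kinetic_trace(
    rate: float,
    baseline: float,
    gain: float = 1.0,
    depletion_timescale: float = math.inf,
    noise_sd: float = 0.0,
    timepoints=DEFAULT_TIMEPOINTS,
    rng: np.random.Generator | int | None = None,
    *,
    plate_id: str = "sim",
    well_id: str = "A1",
    sample_id: str | None = "sim-sample",
    substrate_id: str | None = "sim-substrate",
    ph: float = 7.5,
    role: WellRole = WellRole.DIGESTION,
    replicate_index: int = 1,
) -> KineticTrace:
    """Simulate one well's progress curve from the generative model.

    With ``noise_sd = 0`` and an infinite depletion timescale the trace is
    exactly affine: ``RFU(t) = gain * (baseline + rate * t)``.
    """
    if rate < 0 or baseline < 0:
        raise InputError("rate and baseline must be >= 0")
    if gain <= 0:
        raise InputError("gain must be > 0")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    if not depletion_timescale > 0:
        raise InputError("depletion timescale must be > 0")
    t = np.asarray(timepoints, dtype=float)
    if len(t) < 4 or np.any(np.diff(t) <= 0):
        raise InputError("timepoints must be strictly increasing with >= 4 points")
    signal = gain * (baseline + _product_curve(rate, depletion_timescale, t))
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        signal = signal + rng.normal(0.0, noise_sd, size=len(t))
    return KineticTrace(
        plate_id=plate_id,
        well_id=well_id,
        sample_id=sample_id,
        substrate_id=substrate_id,
        ph=ph,
        role=role,
        replicate_index=replicate_index,
        timepoints=t,
        rfu=signal,
        meta={
            "sim": {
                "rate": float(rate),
                "baseline": float(baseline),
                "gain": float(gain),
                "depletion_timescale_min": float(depletion_timescale),
                "noise_sd_rfu": float(noise_sd),
            }
        },
    )


def _well_name(index: int, ncols: int = 12) -> str:
    """Row-major well label (A1..A12, B1.., then AA1.. past 26 rows)."""
    row, col = divmod(index, ncols)
    letters = ""
    row += 1
    while row > 0:
        row, rem = divmod(row - 1, 26)
        letters = chr(65 + rem) + letters
    return f"{letters}{col + 1}"


def _draw_sample_attributes(config: SimulationConfig, seed: int):
    """High-background flags, baselines and rate multipliers, per substream."""
    samples = config.sample_ids()
    n = len(samples)
    rng_hb = substream(seed, STREAM_HIGH_BACKGROUND)
    high_bg = rng_hb.random(n) < config.high_background_fraction
    rng_base = substream(seed, STREAM_BASELINES)
    baselines = np.clip(
        rng_base.normal(config.background_mean_rfu, config.background_sd_rfu, size=n),
        0.0,
        None,
    )
    baselines = np.where(high_bg, baselines * config.high_background_multiplier, baselines)
    subs = config.substrate_ids
    phs = config.ph_levels
    rng_mult = substream(seed, STREAM_RATE_MULTIPLIERS)
    mult = np.exp(
        rng_mult.normal(0.0, config.sigma_log, size=(n, len(subs), len(phs)))
    )
    return samples, high_bg, baselines, mult


def simulate_study(config: SimulationConfig):
    """Simulate a full assay campaign.

    One plate is generated per (substrate, pH) condition.  Each plate holds
    the configured empty and substrate-only control wells, then — per sample
    — ``replicates`` digestion wells and one intrinsic (extract-only) well.
    The first plate is flagged as the normalization reference.

    Returns
    -------
    (runs, sheet, truth)
        ``runs`` — list of :class:`PlateRun`; ``sheet`` — sample-sheet
        DataFrame; ``truth`` — :class:`SimulationTruth`.
    """
    seed = config.seed
    samples, high_bg, baselines, mult = _draw_sample_attributes(config, seed)
    subs = config.substrate_ids
    phs = config.ph_levels
    t = np.asarray(config.timepoints_min)
    tau = config.depletion_timescale_min

    n_plates = len(subs) * len(phs)
    rng_gain = substream(seed, STREAM_PLATE_GAINS)
    gains = np.exp(rng_gain.normal(0.0, config.plate_gain_sd, size=n_plates))
    rng_noise = substream(seed, STREAM_NOISE)

    def noisy(signal: np.ndarray) -> np.ndarray:
        if config.noise_sd_rfu > 0:
            return signal + rng_noise.normal(0.0, config.noise_sd_rfu, size=len(signal))
        return signal

    runs: list[PlateRun] = []
    rate_rows = []
    plate_rows = []
    plate_idx = 0
    for si, substrate in enumerate(subs):
        for pi, ph in enumerate(phs):
            gain = float(gains[plate_idx])
            plate_id = f"{substrate}_pH{ph}"
            plate_rows.append((plate_id, gain))
            traces: list[KineticTrace] = []
            widx = 0
            for _ in range(config.n_empty_wells):
                traces.append(
                    KineticTrace(
                        plate_id=plate_id,
                        well_id=_well_name(widx),
                        ph=ph,
                        role=WellRole.EMPTY,
                        timepoints=t,
                        rfu=noisy(np.full(len(t), gain * config.empty_well_rfu)),
                    )
                )
                widx += 1
            for _ in range(config.n_substrate_only_wells):
                traces.append(
                    KineticTrace(
                        plate_id=plate_id,
                        well_id=_well_name(widx),
                        ph=ph,
                        role=WellRole.SUBSTRATE_ONLY,
                        substrate_id=substrate,
                        timepoints=t,
                        rfu=noisy(np.full(len(t), gain * config.substrate_only_rfu)),
                    )
                )
                widx += 1
            for j, (sample_id, cohort) in enumerate(samples):
                mu = config.mean_rate(cohort, substrate, ph)
                v = mu * float(mult[j, si, pi])
                rate_rows.append((sample_id, cohort, substrate, float(ph), v))
                b = float(baselines[j])
                signal = gain * (b + _product_curve(v, tau, t))
                for rep in range(1, config.replicates + 1):
                    traces.append(
                        KineticTrace(
                            plate_id=plate_id,
                            well_id=_well_name(widx),
                            sample_id=sample_id,
                            substrate_id=substrate,
                            ph=ph,
                            role=WellRole.DIGESTION,
                            replicate_index=rep,
                            timepoints=t,
                            rfu=noisy(signal),
                            meta={"sim": {"rate": v, "baseline": b, "gain": gain}},
                        )
                    )
                    widx += 1
                traces.append(
                    KineticTrace(
                        plate_id=plate_id,
                        well_id=_well_name(widx),
                        sample_id=sample_id,
                        ph=ph,
                        role=WellRole.INTRINSIC,
                        timepoints=t,
                        rfu=noisy(np.full(len(t), gain * b)),
                    )
                )
                widx += 1
            runs.append(
                PlateRun(
                    plate_id=plate_id,
                    traces=traces,
                    is_reference_plate=(plate_idx == 0),
                )
            )
            plate_idx += 1

    sheet = pd.DataFrame(
        {
            "sample_id": [s for s, _ in samples],
            "cohort": [c for _, c in samples],
            "phase": "none",
            "notes": "",
        }
    )
    truth = SimulationTruth(
        rates=pd.DataFrame(
            rate_rows,
            columns=["sample_id", "cohort", "substrate_id", "ph", "rate_rfu_per_min"],
        ),
        samples=pd.DataFrame(
            {
                "sample_id": [s for s, _ in samples],
                "cohort": [c for _, c in samples],
                "baseline_rfu": baselines,
                "high_background": high_bg,
            }
        ),
        plates=pd.DataFrame(plate_rows, columns=["plate_id", "gain"]),
        seed=seed,
    )
    return runs, sheet, truth


@dataclass
class InhibitionDataset:
    """Paired control/inhibitor plates for one substrate and pH."""

    control: PlateRun
    inhibited: PlateRun
    sheet: pd.DataFrame
    truth: pd.DataFrame  # sample_id, cohort, control_rate, inhibited_rate
    substrate_id: str
    ph: float


def simulate_inhibition_experiment(
    config: SimulationConfig,
    furin_fraction: float,
    inhibitor_efficiency: float,
    rng_seed: int | None = None,
    substrate_id: str = "Pyr-RTKR-AMC",
    ph: float = 7.5,
) -> InhibitionDataset:
    """Simulate a paired inhibitor experiment (e.g. CMK vs. DMSO control).

    Each sample's control wells carry its true rate ``v``; the paired
    inhibitor wells carry ``v * (1 - furin_fraction * inhibitor_efficiency)``,
    i.e. only the furin-attributable share of activity is suppressed, in
    proportion to how completely the inhibitor blocks it.  Paired wells share
    sample identity, plate position and baseline, differing only in condition
    and rate.
    """
    if not 0 <= furin_fraction <= 1:
        raise InputError("furin_fraction must be in [0, 1]")
    if not 0 <= inhibitor_efficiency <= 1:
        raise InputError("inhibitor_efficiency must be in [0, 1]")
    seed = config.seed if rng_seed is None else int(rng_seed)
    single = replace(
        config,
        substrates=(substrate_id,),
        ph_levels=(ph,),
        seed=seed,
        panel=config.panel,
        effect_matrix=config.effect_matrix,
    )
    samples, high_bg, baselines, mult = _draw_sample_attributes(single, seed)
    t = np.asarray(single.timepoints_min)
    tau = single.depletion_timescale_min
    rng_gain = substream(seed, STREAM_PLATE_GAINS)
    gains = np.exp(rng_gain.normal(0.0, single.plate_gain_sd, size=2))
    rng_noise = substream(seed, STREAM_NOISE)
    reduction = 1.0 - furin_fraction * inhibitor_efficiency

    def build_plate(plate_id, gain, rate_for):
        traces = []
        widx = 0
        for _ in range(single.n_empty_wells):
            sig = np.full(len(t), gain * single.empty_well_rfu)
            if single.noise_sd_rfu > 0:
                sig = sig + rng_noise.normal(0, single.noise_sd_rfu, len(t))
            traces.append(
                KineticTrace(plate_id=plate_id, well_id=_well_name(widx), ph=ph,
                             role=WellRole.EMPTY, timepoints=t, rfu=sig)
            )
            widx += 1
        for j, (sample_id, cohort) in enumerate(samples):
            v = rate_for(j)
            b = float(baselines[j])
            sig = gain * (b + _product_curve(v, tau, t))
            for rep in range(1, single.replicates + 1):
                y = sig
                if single.noise_sd_rfu > 0:
                    y = sig + rng_noise.normal(0, single.noise_sd_rfu, len(t))
                traces.append(
                    KineticTrace(
                        plate_id=plate_id, well_id=_well_name(widx),
                        sample_id=sample_id, substrate_id=substrate_id, ph=ph,
                        role=WellRole.DIGESTION, replicate_index=rep,
                        timepoints=t, rfu=y,
                        meta={"condition": plate_id, "sim": {"rate": v}},
                    )
                )
                widx += 1
            y = np.full(len(t), gain * b)
            if single.noise_sd_rfu > 0:
                y = y + rng_noise.normal(0, single.noise_sd_rfu, len(t))
            traces.append(
                KineticTrace(plate_id=plate_id, well_id=_well_name(widx),
                             sample_id=sample_id, ph=ph, role=WellRole.INTRINSIC,
                             timepoints=t, rfu=y)
            )
            widx += 1
        return PlateRun(plate_id=plate_id, traces=traces)

    control_rates = np.array(
        [single.mean_rate(c, substrate_id, ph) * float(mult[j, 0, 0])
         for j, (_, c) in enumerate(samples)]
    )
    control = build_plate("control_DMSO", float(gains[0]), lambda j: float(control_rates[j]))
    inhibited = build_plate(
        "inhibitor_CMK", float(gains[1]), lambda j: float(control_rates[j] * reduction)
    )
    control.is_reference_plate = True
    sheet = pd.DataFrame(
        {
            "sample_id": [s for s, _ in samples],
            "cohort": [c for _, c in samples],
            "phase": "none",
            "notes": "",
        }
    )
    truth = pd.DataFrame(
        {
            "sample_id": [s for s, _ in samples],
            "cohort": [c for _, c in samples],
            "control_rate": control_rates,
            "inhibited_rate": control_rates * reduction,
        }
    )
    return InhibitionDataset(
        control=control, inhibited=inhibited, sheet=sheet, truth=truth,
        substrate_id=substrate_id, ph=ph,
    )
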