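"""Normalization, window detection, slope fitting and replicate aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protprof import InputError, LayoutError
from protprof.kinetics import (
    LinearPhaseOptions,
    LinearWindow,
    aggregate_replicates,
    detect_linear_phase,
    estimate_activities,
    fit_slope,
    normalize_plate,
    plate_normalization_factor,
)
from protprof.plates import PlateRun, WellRole
from protprof.simulate import SimulationConfig, simulate_kinetic_trace, simulate_study

from conftest import make_trace


class TestNormalizationFactor:
    def test_forced_arithmetic(self):
        empties = [
            make_trace(np.full(16, 200.0), role=WellRole.EMPTY, well_id="A1"),
        ]
        plate = PlateRun("P1", empties)
        nf = plate_normalization_factor(plate, 100.0)
        assert nf.factor == 2.0
        assert nf.empty_well_mean == 200.0

    def test_identity_when_equal_to_reference(self):
        plate = PlateRun(
            "P1", [make_trace(np.full(16, 123.0), role=WellRole.EMPTY)]
        )
        assert plate_normalization_factor(plate, 123.0).factor == 1.0

    def test_mean_over_multiple_empty_wells(self):
        empties = [
            make_trace(np.full(16, v), role=WellRole.EMPTY, well_id=f"A{i+1}")
            for i, v in enumerate((90.0, 110.0, 100.0))
        ]
        nf = plate_normalization_factor(PlateRun("P1", empties), 50.0)
        assert nf.factor == pytest.approx(2.0)
        assert nf.n_empty_wells == 3

    def test_no_empty_wells_is_layout_error(self):
        plate = PlateRun("P1", [make_trace(np.full(16, 1.0))])
        with pytest.raises(LayoutError):
            plate_normalization_factor(plate, 100.0)

    def test_nonpositive_reference_rejected(self, tiny_plate):
        with pytest.raises(InputError):
            plate_normalization_factor(tiny_plate, 0.0)


class TestNormalizePlate:
    def test_factor_one_is_identity(self, tiny_plate):
        out = normalize_plate(tiny_plate, 1.0)
        for a, b in zip(tiny_plate.traces, out.traces):
            np.testing.assert_array_equal(a.rfu, b.rfu)

    def test_factor_two_halves_reads(self, tiny_plate):
        out = normalize_plate(tiny_plate, 2.0)
        for a, b in zip(tiny_plate.traces, out.traces):
            np.testing.assert_allclose(b.rfu, a.rfu / 2.0)
            assert b.meta["normalization_factor"] == 2.0

    def test_scaling_commutes_with_factor(self, tiny_plate, rng):
        # normalize(scale(p, k), f*k) == normalize(p, f)
        for k in (0.5, 3.0, 10.0):
            f = float(rng.uniform(0.5, 2.0))
            lhs = normalize_plate(tiny_plate.scaled(k), f * k)
            rhs = normalize_plate(tiny_plate, f)
            for a, b in zip(lhs.traces, rhs.traces):
                np.testing.assert_allclose(a.rfu, b.rfu, rtol=1e-12)

    def test_nonpositive_factor_rejected(self, tiny_plate):
        with pytest.raises(InputError):
            normalize_plate(tiny_plate, -1.0)


def brute_force_window(trace, options):
    """Independent exhaustive search over admissible windows.

    Re-states the acceptance rule naively: all contiguous read windows inside
    [0, t_max_window] with >= min_points reads spanning >= t_min_window
    minutes, longest first then earliest start; accept the first whose max
    deviation from its own OLS line is within tol * span + 3 * tail-noise.
    """
    t, y = trace.timepoints, trace.rfu
    tail = y[t > options.t_max_window]
    if len(tail) < 3:
        tail = y[len(y) // 2:]
    noise = float(np.std(np.diff(tail), ddof=1)) if len(tail) >= 3 else 0.0
    idx = [i for i in range(len(t)) if t[i] <= options.t_max_window + 1e-9]
    if len(idx) < options.min_points:
        idx = list(range(min(len(t), options.min_points)))

    def ols_line(ti, yi):
        A = np.vstack([ti, np.ones_like(ti)]).T
        coef, *_ = np.linalg.lstsq(A, yi, rcond=None)
        return coef

    # full-window slope for the activity floor
    ti, yi = t[idx], y[idx]
    full_slope = 0.0 if np.ptp(yi) == 0 else ols_line(ti, yi)[0]
    if abs(full_slope) < options.activity_floor_rfu_per_min:
        return (float(t[idx[0]]), float(t[idx[-1]]), True)

    fallback, fallback_ratio = None, math.inf
    for n in range(len(idx), options.min_points - 1, -1):
        for s in range(len(idx) - n + 1):
            sel = idx[s: s + n]
            if t[sel[-1]] - t[sel[0]] < options.t_min_window - 1e-9:
                continue
            tw, yw = t[sel], y[sel]
            if np.ptp(yw) == 0:
                return (float(tw[0]), float(tw[-1]), False)
            slope, intercept = ols_line(tw, yw)
            dev = float(np.max(np.abs(yw - slope * tw - intercept)))
            allowance = options.linearity_tol * float(np.ptp(yw)) + 3 * noise
            if dev <= allowance:
                return (float(tw[0]), float(tw[-1]), False)
            ratio = dev / allowance if allowance > 0 else math.inf
            if ratio < fallback_ratio:
                fallback_ratio, fallback = ratio, (float(tw[0]), float(tw[-1]), False)
    return fallback


class TestDetectLinearPhase:
    def test_affine_trace_gets_full_window(self):
        t = np.arange(0, 80, 5, dtype=float)
        trace = make_trace(7 + 3 * t, t)
        w = detect_linear_phase(trace)
        assert (w.t_start, w.t_end) == (0.0, 20.0)
        assert not w.low_activity
        assert w.r_squared == pytest.approx(1.0)

    def test_flat_trace_low_activity_default_window(self):
        trace = make_trace(np.zeros(16))
        w = detect_linear_phase(trace)
        assert w.low_activity
        assert (w.t_start, w.t_end) == (0.0, 20.0)
        assert math.isnan(w.r_squared)

    def test_saturating_trace_matches_brute_force(self):
        t = np.arange(0, 80, 5, dtype=float)
        opts = LinearPhaseOptions()
        trace = simulate_kinetic_trace(50, 0, 1, 10.0, 0, t)
        w = detect_linear_phase(trace, opts)
        bf_start, bf_end, bf_low = brute_force_window(trace, opts)
        assert (w.t_start, w.t_end, w.low_activity) == (bf_start, bf_end, bf_low)
        # strong curvature: the full 0-20 window must have been rejected
        assert w.t_end - w.t_start < 20.0

    def test_random_traces_match_brute_force(self, rng):
        t = np.arange(0, 80, 5, dtype=float)
        opts = LinearPhaseOptions()
        for _ in range(150):
            tau = float(rng.choice([5.0, 10.0, 30.0, math.inf]))
            rate = float(rng.uniform(0, 100))
            noise = float(rng.uniform(0, 10))
            trace = simulate_kinetic_trace(rate, rng.uniform(0, 50), 1.0, tau,
                                           noise, t, rng)
            w = detect_linear_phase(trace, opts)
            assert (w.t_start, w.t_end, w.low_activity) == \
                brute_force_window(trace, opts)

    def test_too_few_reads_rejected(self):
        with pytest.raises(InputError):
            detect_linear_phase(make_trace([0, 1, 2], [0.0, 5.0, 10.0]))


class TestFitSlope:
    def test_exact_line(self):
        t = np.arange(0, 80, 5, dtype=float)
        trace = make_trace(10 + 3 * t, t)
        slope, stderr, r2 = fit_slope(trace, LinearWindow(0, 75, 16, 1.0))
        assert slope == pytest.approx(3.0, rel=1e-12)
        assert stderr == pytest.approx(0.0, abs=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_constant_trace_zero_slope(self):
        trace = make_trace(np.full(16, 42.0))
        slope, stderr, r2 = fit_slope(trace, LinearWindow(0, 75, 16, math.nan))
        assert slope == 0.0
        assert math.isnan(r2)

    def test_matches_independent_ols(self, rng):
        t = np.arange(0, 80, 5, dtype=float)
        y = 12 + 4.5 * t + rng.normal(0, 3, size=len(t))
        trace = make_trace(y, t)
        slope, stderr, _ = fit_slope(trace, LinearWindow(0, 75, 16, 1.0))
        # hand-coded OLS formulas
        tbar, ybar = t.mean(), y.mean()
        sxx = np.sum((t - tbar) ** 2)
        beta = np.sum((t - tbar) * (y - ybar)) / sxx
        resid = y - (ybar + beta * (t - tbar))
        se = math.sqrt(np.sum(resid**2) / (len(t) - 2) / sxx)
        assert slope == pytest.approx(beta, rel=1e-10)
        assert stderr == pytest.approx(se, rel=1e-10)

    def test_offset_invariance(self, rng):
        t = np.arange(0, 80, 5, dtype=float)
        y = rng.normal(50, 5, size=len(t))
        w = LinearWindow(0, 75, 16, 1.0)
        s1, _, _ = fit_slope(make_trace(y, t), w)
        s2, _, _ = fit_slope(make_trace(y + 1234.5, t), w)
        assert s2 == pytest.approx(s1, abs=1e-10)

    def test_degenerate_window_rejected(self):
        trace = make_trace(np.full(16, 1.0))
        with pytest.raises(InputError):
            fit_slope(trace, LinearWindow(0, 2, 1, 1.0))


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "slopes,expected",
        [
            ([3, 3, 3], (3.0, 0.0, 3)),
            ([2, 4], (3.0, math.sqrt(2), 2)),
        ],
    )
    def test_examples(self, slopes, expected):
        mean, sd, n = aggregate_replicates(slopes)
        assert (mean, n) == (expected[0], expected[2])
        assert sd == pytest.approx(expected[1])

    def test_single_value_has_missing_sd(self):
        mean, sd, n = aggregate_replicates([5.0])
        assert (mean, n) == (5.0, 1)
        assert math.isnan(sd)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            aggregate_replicates([])


class TestGainInvariance:
    def _records(self, runs):
        recs = estimate_activities(runs)
        return {
            (r.sample_id, r.substrate_id, r.ph): r.rate_rfu_per_min for r in recs
        }

    def test_scaling_one_plate_leaves_records_unchanged(self):
        cfg = SimulationConfig(
            cohorts=(("CD", 3),), substrates=("Ac-RSVL-AMC", "Pyr-RTKR-AMC"),
            ph_levels=(7.5,), seed=8,
        )
        runs, _, _ = simulate_study(cfg)
        base = self._records(runs)
        for k in (0.5, 2.0, 10.0):
            # scale a non-reference plate; its normalization factor absorbs k
            scaled = [runs[0], runs[1].scaled(k)]
            out = self._records(scaled)
            for key, value in base.items():
                assert out[key] == pytest.approx(value, rel=1e-10)

    @given(k=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_gain_invariance_property(self, k):
        cfg = SimulationConfig(
            cohorts=(("UC", 2),), substrates=("Ac-RRHL-AMC",), ph_levels=(6.5,),
            seed=21,
        )
        runs, _, _ = simulate_study(cfg)
        plate = runs[0]
        ref_value = 50.0
        from protprof.kinetics import plate_normalization_factor as pnf

        f1 = pnf(plate, ref_value).factor
        f2 = pnf(plate.scaled(k), ref_value).factor
        assert f2 == pytest.approx(k * f1, rel=1e-12)
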