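"""Fitting stages: parameter recovery, model selection, diagnostics."""

import numpy as np
import pytest

from slowbind import (
    ActivityTimeCourse,
    AssayConditions,
    BiphasicParams,
    FitError,
    KobsSeries,
    ProgressTrace,
    classify_inhibition,
    extract_initial_velocities,
    fit_biphasic,
    fit_kobs_secondary,
    fit_progress,
    fit_reactivation,
    kobs_type_b,
    progress_curve,
    reversible_rate,
    simulate_biphasic_inactivation,
    simulate_progress,
)
from slowbind.fitting import VelocityGrid

COND = AssayConditions(S=1e-4, Km=1e-4, I=1e-8, Vmax=2e-8)


def _trace(t, y, cond=COND):
    return ProgressTrace(times=t, signal=y, condition=cond, signal_units="product")


class TestFitProgress:
    def test_noiseless_exact_recovery(self):
        t = np.linspace(0, 60, 240)
        y = progress_curve(t, 1.0, 0.2, 0.4)
        f = fit_progress(_trace(t, y))
        assert not f.no_lag
        assert f.v_i == pytest.approx(1.0, rel=1e-3)
        assert f.v_ss == pytest.approx(0.2, rel=1e-3)
        assert f.k_obs == pytest.approx(0.4, rel=1e-3)

    def test_lag_time_is_reciprocal_kobs(self):
        t = np.linspace(0, 60, 240)
        f = fit_progress(_trace(t, progress_curve(t, 1.0, 0.2, 0.4)))
        assert f.lag_time == pytest.approx(1.0 / f.k_obs, rel=1e-12)

    def test_noisy_simulated_recovery(self, ref_spec, make_condition, times_60min):
        # 50 replicate noisy traces at 10 nM inhibitor: the median k_obs
        # error stays below 5%
        cond = make_condition(S=1e-4, I=1e-8)
        clean = simulate_progress(ref_spec, cond, times_60min)
        truth = kobs_type_b(cond.I, ref_spec.Ki, ref_spec.k_plus4,
                            ref_spec.k_minus4, S=cond.S, Km=cond.Km)
        sd = 0.003 * np.ptp(clean.signal)
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            tr = ProgressTrace(times=clean.times,
                               signal=clean.signal + rng.normal(0, sd, clean.signal.shape),
                               condition=cond)
            f = fit_progress(tr)
            if f.k_obs is not None:
                errs.append(abs(f.k_obs - truth) / truth)
        assert len(errs) >= 45
        assert np.median(errs) < 0.05

    def test_linear_trace_gives_no_lag(self):
        t = np.linspace(0, 60, 240)
        rng = np.random.default_rng(0)
        y = 0.01 * t + rng.normal(0, 1e-4, t.shape)
        f = fit_progress(_trace(t, y))
        assert f.no_lag
        assert f.k_obs is None
        assert f.v_i == pytest.approx(0.01, rel=0.01)

    @pytest.mark.parametrize("noise,max_median_err", [(0.0, 1e-5), (0.001, 0.01), (0.01, 0.1)])
    def test_bias_vanishes_as_noise_vanishes(self, noise, max_median_err):
        t = np.linspace(0, 60, 240)
        clean = progress_curve(t, 1.0, 0.2, 0.4)
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, noise * np.ptp(clean), t.shape) if noise else clean
            f = fit_progress(_trace(t, y))
            errs.append(abs(f.k_obs - 0.4) / 0.4)
        assert np.median(errs) < max_median_err

    def test_burst_trace_flagged_not_rejected(self):
        t = np.linspace(0, 60, 240)
        y = progress_curve(t, 0.2, 1.0, 0.3)  # v_ss > v_i
        f = fit_progress(_trace(t, y))
        assert any("burst" in w for w in f.warnings)


class TestExtractInitialVelocities:
    def _grid_traces(self, K_ci=5.15e-9, noise=0.0, seed=0, n=240):
        t = np.linspace(0, 60, n)
        rng = np.random.default_rng(seed)
        traces = []
        for S in (1e-4, 5e-4, 1e-3):
            for I in (0, 1e-9, 2e-9, 5e-9, 1e-8, 2e-8, 5e-8):
                cond = AssayConditions(S=S, Km=1e-4, I=I, Vmax=2e-8)
                v = reversible_rate(cond, K_ci=K_ci)
                y = v * t if I == 0 else progress_curve(t, v, 0.4 * v, 0.25)
                if noise:
                    y = y + rng.normal(0, noise * v * 60, t.shape)
                traces.append(_trace(t, y, cond))
        return traces

    def test_noiseless_grid_matches_rate_law(self):
        traces = self._grid_traces()
        grid = extract_initial_velocities(traces)
        for i, S in enumerate(grid.S_levels):
            for j, I in enumerate(grid.I_levels):
                cond = AssayConditions(S=S, Km=1e-4, I=I, Vmax=2e-8)
                expected = reversible_rate(cond, K_ci=5.15e-9)
                assert grid.v[i, j] == pytest.approx(expected, rel=2e-3)

    def test_uninhibited_column_is_michaelis_menten(self):
        grid = extract_initial_velocities(self._grid_traces())
        j0 = int(np.where(grid.I_levels == 0)[0][0])
        for i, S in enumerate(grid.S_levels):
            assert grid.v[i, j0] == pytest.approx(2e-8 * S / (1e-4 + S), rel=2e-3)

    def test_replicate_averaging_shrinks_se(self):
        t = np.linspace(0, 60, 240)
        cond = AssayConditions(S=1e-4, Km=1e-4, I=1e-8, Vmax=2e-8)
        v = reversible_rate(cond, K_ci=5.15e-9)
        clean = progress_curve(t, v, 0.4 * v, 0.25)

        def grid_with(n_reps):
            rng = np.random.default_rng(1)
            reps = [
                _trace(t, clean + rng.normal(0, 0.01 * v * 60, t.shape), cond)
                for _ in range(n_reps)
            ]
            return extract_initial_velocities(reps)

        se1 = grid_with(1).se[0, 0]
        se4 = grid_with(4).se[0, 0]
        assert se4 == pytest.approx(se1 / 2, rel=0.35)


def _velocity_grid(K_ci, K_ui, noise=0.0, seed=0, n_I=6):
    S_levels = np.array([1e-4, 5e-4, 1e-3])
    I_levels = np.concatenate([[0.0], np.geomspace(1e-9, 5e-8, n_I - 1)])
    rng = np.random.default_rng(seed)
    v = np.empty((S_levels.size, I_levels.size))
    for i, S in enumerate(S_levels):
        for j, I in enumerate(I_levels):
            cond = AssayConditions(S=S, Km=1e-4, I=I, Vmax=2e-8)
            v[i, j] = reversible_rate(cond, K_ci=K_ci, K_ui=K_ui)
    se = np.full_like(v, 0.01 * v.mean())
    if noise:
        v = v * (1 + rng.normal(0, noise, v.shape))
        se = noise * v
    return VelocityGrid(S_levels, I_levels, v, se)


class TestClassifyInhibition:
    def test_competitive_recovery_over_seeds(self):
        # 1% multiplicative noise, 20 seeds: the competitive mechanism is
        # selected in >=95% of runs and K_ci is recovered within 10% median
        calls, errs = [], []
        for seed in range(20):
            grid = _velocity_grid(5.15e-9, None, noise=0.01, seed=seed)
            d = classify_inhibition(grid)
            calls.append(d.mechanism)
            if d.K_ci is not None:
                errs.append(abs(d.K_ci - 5.15e-9) / 5.15e-9)
        assert calls.count("competitive") >= 19
        assert np.median(errs) < 0.10

    def test_noncompetitive_intersections_coincide(self):
        grid = _velocity_grid(8e-9, 8e-9)
        d = classify_inhibition(grid)
        assert d.mechanism == "noncompetitive"
        gx_d = d.graphical["dixon"]["intersection_x"]
        gx_c = d.graphical["cornish_bowden"]["intersection_x"]
        assert gx_d == pytest.approx(-8e-9, rel=1e-6)
        assert gx_c == pytest.approx(gx_d, rel=1e-6)

    def test_uncompetitive_geometry(self):
        grid = _velocity_grid(None, 8e-9)
        d = classify_inhibition(grid)
        assert d.mechanism == "uncompetitive"
        assert d.K_ci is None
        # Dixon lines parallel (equal slopes), Cornish-Bowden lines intersect
        assert d.graphical["dixon"]["parallel_p_min"] > 0.05
        assert d.graphical["cornish_bowden"]["parallel_p_min"] < 0.05

    def test_competitive_reports_absent_kui(self):
        d = classify_inhibition(_velocity_grid(5.15e-9, None))
        assert d.mechanism == "competitive"
        assert d.K_ui is None
        assert d.K_ci == pytest.approx(5.15e-9, rel=1e-4)

    def test_too_few_levels_rejected(self):
        grid = _velocity_grid(5e-9, None)
        small = VelocityGrid(grid.S_levels[:1], grid.I_levels,
                             grid.v[:1], grid.se[:1])
        with pytest.raises(ValueError):
            classify_inhibition(small)


def _kobs_series(noise=0.0, seed=0, Ki=5.15e-9, kp4=0.456, km4=0.054):
    rng = np.random.default_rng(seed)
    out = []
    I = np.array([0.1, 0.5, 1, 2, 5, 10, 20, 50]) * 1e-9
    for S in (1e-4, 5e-4, 1e-3):
        k = kobs_type_b(I, Ki, kp4, km4, S=S, Km=1e-4)
        se = np.full_like(k, max(noise, 1e-3) * k.mean())
        if noise:
            k = k * (1 + rng.normal(0, noise, k.shape))
        out.append(KobsSeries(I=I, k_obs=k, se=se, S=S, Km=1e-4))
    return out


class TestFitKobsSecondary:
    def test_noiseless_exact_recovery_and_type_b(self):
        fit = fit_kobs_secondary(_kobs_series())
        assert fit.sbi_type == "B"
        assert fit.pooled["k_minus4"] == pytest.approx(0.054, rel=1e-4)
        assert fit.pooled["k_plus4"] == pytest.approx(0.456, rel=1e-4)
        assert fit.pooled["Ki"] == pytest.approx(5.15e-9, rel=1e-3)
        for entry in fit.per_series:
            assert entry["aicc_B"] < entry["aicc_A"]

    def test_noisy_recovery_within_reported_uncertainty(self):
        # 5% noise on k_obs, 50 seeds: pooled constants fall within the
        # reference uncertainties (+-0.006 on k-4, +-0.095 on k+4) in at
        # least 68% of runs
        hit_km4 = hit_kp4 = 0
        n_seeds = 50
        for seed in range(n_seeds):
            fit = fit_kobs_secondary(_kobs_series(noise=0.05, seed=seed))
            hit_km4 += abs(fit.pooled["k_minus4"] - 0.054) <= 0.006
            hit_kp4 += abs(fit.pooled["k_plus4"] - 0.456) <= 0.095
        assert hit_km4 >= 0.68 * n_seeds
        assert hit_kp4 >= 0.68 * n_seeds

    def test_linear_series_selected_as_type_a(self):
        I = np.array([1, 2, 5, 10, 20]) * 1e-9
        series = [
            KobsSeries(I=I, k_obs=0.05 + 2e6 * I, se=np.full(I.size, 1e-4),
                       S=1e-4, Km=1e-4)
        ]
        fit = fit_kobs_secondary(series)
        assert fit.sbi_type == "A"
        assert any("undersampled" in w for w in fit.warnings)

    def test_type_a_never_called_b_noiseless(self):
        for slope in (1e6, 5e6, 2e7):
            I = np.array([0.5, 1, 2, 5, 10, 20, 50]) * 1e-9
            series = [
                KobsSeries(I=I, k_obs=0.054 + slope * I, se=None, S=S, Km=1e-4)
                for S in (1e-4, 1e-3)
            ]
            assert fit_kobs_secondary(series).sbi_type != "B"

    def test_flat_series_is_type_none(self):
        I = np.array([1, 2, 5, 10, 20]) * 1e-9
        rng = np.random.default_rng(3)
        series = [
            KobsSeries(I=I, k_obs=0.05 + rng.normal(0, 1e-4, I.size),
                       se=np.full(I.size, 1e-3), S=1e-4, Km=1e-4)
        ]
        assert fit_kobs_secondary(series).sbi_type == "none"

    def test_inconsistent_series_block_pooling(self):
        series = _kobs_series()
        shifted = _kobs_series(Ki=5.15e-9, km4=0.054 * 3)[0]
        series[0] = shifted
        fit = fit_kobs_secondary(series)
        assert fit.pooled["k_minus4_pooling_blocked"]
        assert any("pooling blocked" in w for w in fit.warnings)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_kobs_secondary(
                [KobsSeries(I=np.array([1e-9, 2e-9, 5e-9]),
                            k_obs=np.array([0.1, 0.15, 0.2]), se=None,
                            S=1e-4, Km=1e-4)]
            )


class TestFitBiphasic:
    PARAMS = BiphasicParams(E0_fast=0.5, E0_slow=0.5, kp_fast=0.2, kp_slow=0.02,
                            KI_fast=1e-7, KI_slow=1e-7)

    def test_single_exponential_selected_and_recovered(self):
        p = BiphasicParams(E0_fast=1.0, E0_slow=0.0, kp_fast=0.2, kp_slow=0.02,
                           KI_fast=1e-7, KI_slow=1e-7)
        t = np.linspace(0, 60, 31)
        tc = simulate_biphasic_inactivation(p, 1e-7, t)
        fit = fit_biphasic([tc])
        entry = fit.per_trace[0]
        assert not entry["biphasic"]
        assert entry["k_obs_fast"] == pytest.approx(0.1, rel=0.02)

    def test_two_phase_recovery_over_seeds(self):
        # rate ratio 10, equal amplitudes, 1% noise, 20 seeds: both rates
        # recovered within 15% median
        I = 1e-7
        kf_true, ks_true = 0.1, 0.01
        t = np.linspace(0, 200, 81)
        errs_f, errs_s = [], []
        for seed in range(20):
            tc = simulate_biphasic_inactivation(self.PARAMS, I, t,
                                                noise_sd=0.01, seed=seed)
            entry = fit_biphasic([tc]).per_trace[0]
            if entry["biphasic"]:
                errs_f.append(abs(entry["k_obs_fast"] - kf_true) / kf_true)
                errs_s.append(abs(entry["k_obs_slow"] - ks_true) / ks_true)
        assert len(errs_f) >= 15
        assert np.median(errs_f) < 0.15
        assert np.median(errs_s) < 0.15

    def test_rate_hyperbola_recovered_across_levels(self):
        t = np.linspace(0, 200, 81)
        levels = [2e-8, 5e-8, 1e-7, 2e-7, 5e-7]
        courses = [simulate_biphasic_inactivation(self.PARAMS, I, t) for I in levels]
        fit = fit_biphasic(courses)
        assert fit.pooled_fast["kp"] == pytest.approx(0.2, rel=0.05)
        assert fit.pooled_fast["KI"] == pytest.approx(1e-7, rel=0.10)
        assert fit.pooled_slow["kp"] == pytest.approx(0.02, rel=0.05)
        # saturation: k_obs approaches the plateau k_p at high [I]
        top = max(e["k_obs_fast"] for e in fit.per_trace)
        assert top < 0.2 and top > 0.8 * 0.2

    def test_amplitude_collapse_reported_monophasic(self):
        p = BiphasicParams(E0_fast=0.995, E0_slow=0.005, kp_fast=0.2, kp_slow=0.02,
                           KI_fast=1e-7, KI_slow=1e-7)
        t = np.linspace(0, 60, 31)
        tc = simulate_biphasic_inactivation(p, 1e-7, t, noise_sd=0.002, seed=1)
        fit = fit_biphasic([tc])
        assert not fit.per_trace[0]["biphasic"]


class TestFitReactivation:
    def _course(self, k=0.05, a0=0.03, a_inf=1.0, t_end=120, n=61, noise=0.0, seed=0):
        t = np.linspace(0, t_end, n)
        a = a_inf - (a_inf - a0) * np.exp(-k * t)
        if noise:
            a = a + np.random.default_rng(seed).normal(0, noise, t.shape)
        return ActivityTimeCourse(times=t, residual_activity=a)

    def test_estimators_agree_noiseless(self):
        fit = fit_reactivation(self._course())
        assert fit.k_react == pytest.approx(0.05, rel=1e-6)
        assert fit.k_react_logslope == pytest.approx(fit.k_react, rel=0.01)
        assert fit.t_half == pytest.approx(np.log(2) / 0.05, rel=1e-6)

    def test_fixed_vs_free_plateau_agree(self):
        tc = self._course(noise=0.005, seed=4)
        free = fit_reactivation(tc)
        fixed = fit_reactivation(tc, control_level=1.0, fix_a_inf=True)
        assert abs(free.k_react - fixed.k_react) < 2 * max(free.se_k_react,
                                                           fixed.se_k_react)

    def test_non_recovering_trace_raises(self):
        t = np.linspace(0, 60, 31)
        tc = ActivityTimeCourse(times=t, residual_activity=np.full(t.size, 0.03))
        with pytest.raises(FitError):
            fit_reactivation(tc)
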