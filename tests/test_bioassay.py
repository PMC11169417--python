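"""Imaging responder metrics, gating/dose-response fits, AUC, group stats."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scaffscreen import (
    BehaviorSeries,
    FixtureSpec,
    ImagingTrace,
    boltzmann_fit,
    conductance_transform,
    delta_f_over_f0,
    estimate_reversal,
    generate_dose_response,
    generate_ephys,
    group_stats,
    hill_fit,
    inhibition_rate,
    peak_current_density,
    sidak_adjust,
    trapezoid_auc,
)
from scaffscreen.bioassay import SweepProtocol, SweepSet


def make_trace(agonist_peak, f0=100.0, kcl_peak=None, trace_id="t"):
    time = np.arange(0.0, 330.0, 5.0)
    F = np.full(time.size, f0)
    F[(time >= 80) & (time < 200)] = agonist_peak
    if kcl_peak is not None:
        F[(time >= 280) & (time < 320)] = kcl_peak
    return ImagingTrace(time=time, F=F, baseline=(0, 60), agonist=(60, 240),
                        kcl=(270, 330), trace_id=trace_id)


class TestDeltaFOverF0:
    def test_fifty_percent_response_is_responder(self):
        res = delta_f_over_f0(make_trace(150.0, kcl_peak=200.0))
        assert res.dF_F0 == pytest.approx(0.5)
        assert res.responder and res.viable

    def test_nine_percent_is_below_the_responder_criterion(self):
        res = delta_f_over_f0(make_trace(109.0, kcl_peak=200.0))
        assert res.dF_F0 == pytest.approx(0.09)
        assert not res.responder

    def test_no_kcl_response_marks_trace_non_viable(self):
        res = delta_f_over_f0(make_trace(150.0, kcl_peak=100.0))
        assert res.responder and not res.viable

    def test_background_subtraction_before_f0(self):
        t = make_trace(150.0, kcl_peak=200.0)
        t.background = 50.0
        res = delta_f_over_f0(t)
        assert res.dF_F0 == pytest.approx(1.0)  # peak (150-50) over F0 (100-50)

    def test_scaling_f_and_background_together_is_invariant(self):
        t1 = make_trace(150.0, kcl_peak=200.0)
        t1.background = 20.0
        t2 = make_trace(150.0, kcl_peak=200.0)
        t2.F = t1.F * 3.0
        t2.background = 60.0
        assert delta_f_over_f0(t1).dF_F0 == pytest.approx(delta_f_over_f0(t2).dF_F0)

    def test_nonpositive_f0_rejected_with_reason(self):
        t = make_trace(150.0)
        t.background = 200.0
        res = delta_f_over_f0(t)
        assert res.status == "REJECTED:nonpositive_F0"


class TestInhibitionRate:
    def test_equal_groups_mean_zero_inhibition(self):
        group = [make_trace(150.0, kcl_peak=200.0, trace_id=f"c{i}") for i in range(4)]
        out = inhibition_rate(group, group)
        assert out["percent_of_control"] == pytest.approx(100.0)
        assert out["inhibition_pct"] == pytest.approx(0.0)
        assert not out["is_hit"]

    def test_abolished_response_is_full_inhibition(self):
        control = [make_trace(150.0, kcl_peak=200.0) for _ in range(4)]
        treated = [make_trace(100.0, kcl_peak=200.0) for _ in range(4)]
        out = inhibition_rate(treated, control)
        assert out["percent_of_control"] == pytest.approx(0.0)
        assert out["is_hit"]

    def test_two_thirds_remaining_response(self):
        control = [make_trace(160.0, kcl_peak=220.0) for _ in range(5)]
        treated = [make_trace(140.0, kcl_peak=220.0) for _ in range(5)]
        out = inhibition_rate(treated, control)
        assert out["percent_of_control"] == pytest.approx(100 * 0.4 / 0.6)

    def test_exclusion_accounting_reconciles(self):
        traces = [
            make_trace(150.0, kcl_peak=200.0, trace_id="resp"),
            make_trace(105.0, kcl_peak=200.0, trace_id="nonresp"),
            make_trace(150.0, kcl_peak=100.0, trace_id="nonviable"),
        ]
        bad = make_trace(150.0, kcl_peak=200.0, trace_id="rej")
        bad.background = 300.0
        traces.append(bad)
        control = [make_trace(150.0, kcl_peak=200.0) for _ in range(3)]
        out = inhibition_rate(traces, control)
        acct = out["accounting"]["treated"]
        assert acct["total"] == 4
        assert (acct["responders"] + acct["non_responders"]
                + acct["non_viable"] + acct["rejected"]) == acct["total"]

    def test_empty_control_group_errors(self):
        with pytest.raises(ValueError):
            inhibition_rate([make_trace(150.0, kcl_peak=200.0)], [])


def square_sweepset(peaks, capacitance=10.0, duration=200.0):
    protocol = SweepProtocol(-60.0, -70.0, -70.0 + 5.0 * (len(peaks) - 1), 5.0, duration)
    t = np.arange(0.0, duration + 0.1, 0.1)
    sweeps = {}
    for v, peak in zip(protocol.steps, peaks):
        trace = np.zeros(t.size)
        trace[(t >= 2.0) & (t <= 50.0)] = peak
        sweeps[float(v)] = trace
    return SweepSet(protocol=protocol, time_ms=t, sweeps=sweeps,
                    capacitance_pf=capacitance, cell_id="c")


class TestPeakCurrentDensity:
    def test_simple_density(self):
        iv = peak_current_density(square_sweepset([-1000.0]))
        assert iv.iloc[0].density_pa_pf == pytest.approx(-100.0)

    def test_all_zero_trace_gives_zero_density(self):
        iv = peak_current_density(square_sweepset([0.0]))
        assert iv.iloc[0].density_pa_pf == 0.0

    def test_signed_extremum_keeps_inward_negative(self):
        iv = peak_current_density(square_sweepset([-500.0, 300.0]))
        assert iv.iloc[0].peak_pa == -500.0
        assert iv.iloc[1].peak_pa == 300.0

    def test_missing_sweep_flagged(self):
        ss = square_sweepset([-100.0, -200.0])
        del ss.sweeps[-65.0]
        iv = peak_current_density(ss)
        assert list(iv.status) == ["OK", "MISSING"]

    def test_zero_capacitance_rejected(self):
        with pytest.raises(ValueError):
            square_sweepset([-100.0], capacitance=0.0)


class TestBoltzmannFit:
    def test_noiseless_recovery_is_exact(self):
        v = np.arange(-70.0, 61.0, 5.0)
        for kind, vh, k in [("activation", -20.0, 6.0), ("inactivation", -65.0, 7.0)]:
            if kind == "activation":
                y = 1 / (1 + np.exp((vh - v) / k))
            else:
                y = 1 / (1 + np.exp((v - vh) / k))
            fit = boltzmann_fit(v, y, kind)
            assert fit.converged
            assert abs(fit.V_half - vh) < 1e-6
            assert abs(fit.k - k) < 1e-6

    def test_monte_carlo_bias_small_at_sigma_003(self, rng):
        v = np.arange(-70.0, 61.0, 5.0)
        truth_vh, truth_k = -20.0, 6.0
        y0 = 1 / (1 + np.exp((truth_vh - v) / truth_k))
        estimates = []
        for _ in range(200):
            fit = boltzmann_fit(v, y0 + rng.normal(0, 0.03, v.size), "activation")
            if fit.converged:
                estimates.append(fit.V_half)
        assert abs(np.mean(estimates) - truth_vh) < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_fit(np.array([0.0, 1, 2, 3]), np.array([0.0, 0.3, 0.7, 1]))


class TestConductanceTransform:
    def test_ohmic_iv_gives_constant_conductance(self):
        v = np.arange(-70.0, 41.0, 10.0)
        iv = pd.DataFrame({"voltage_mv": v, "density_pa_pf": 2.0 * (v - 60.0)})
        g = conductance_transform(iv, 60.0)
        np.testing.assert_allclose(g.g_norm, 1.0)

    def test_inverts_the_boltzmann_generator(self):
        v = np.arange(-70.0, 41.0, 5.0)
        m = 1 / (1 + np.exp((-20.0 - v) / 6.0))
        iv = pd.DataFrame({"voltage_mv": v, "density_pa_pf": 30.0 * m * (v - 60.0)})
        g = conductance_transform(iv, 60.0)
        recovered = g.g_norm.to_numpy()
        expected = m / m.max()
        assert np.sqrt(np.mean((recovered - expected) ** 2)) < 1e-6

    def test_point_at_reversal_is_dropped(self):
        v = np.arange(0.0, 101.0, 10.0)
        iv = pd.DataFrame({"voltage_mv": v, "density_pa_pf": v - 60.0})
        g = conductance_transform(iv, 60.0)
        assert len(g) == len(v) - 1
        assert 60.0 not in set(g.voltage_mv)

    def test_normalized_max_is_exactly_one(self):
        v = np.arange(-70.0, 41.0, 5.0)
        m = 1 / (1 + np.exp((-20.0 - v) / 6.0))
        iv = pd.DataFrame({"voltage_mv": v, "density_pa_pf": 30.0 * m * (v - 60.0)})
        g = conductance_transform(iv, 60.0)
        assert g.g_norm.max() == 1.0

    def test_reversal_estimated_from_positive_limb(self):
        cells, truth = generate_ephys(
            FixtureSpec(seed=0, scenario="ephys",
                        parameters={"n_cells": 1, "noise_sd": 0.0}),
            np.random.default_rng(0))
        iv = peak_current_density(cells[0])
        vrev = estimate_reversal(iv)
        assert abs(vrev - truth["cells"][0]["V_rev"]) < 1.0


class TestHillFit:
    def test_noiseless_recovery_is_exact(self):
        c = np.array([0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        y = 1 / (1 + (1.0 / c) ** 1.0)
        fit = hill_fit(c, y)
        assert abs(fit.IC50 - 1.0) < 1e-6
        assert abs(fit.hill - 1.0) < 1e-6
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)

    def test_matches_dense_grid_search_oracle(self, rng):
        c = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        log_grid = np.exp(np.linspace(np.log(0.05), np.log(60), 2000))
        hill_grid = np.linspace(0.5, 2.5, 401)
        # dense curve bank: (ic50, hill, conc)
        curves = 1 / (1 + (log_grid[:, None, None] / c) ** hill_grid[None, :, None])
        for _ in range(20):
            ic50 = float(rng.uniform(0.3, 10.0))
            hill = float(rng.uniform(0.7, 2.0))
            y = 1 / (1 + (ic50 / c) ** hill)
            fit = hill_fit(c, y)
            sse = ((curves - y) ** 2).sum(axis=2)
            gi, _hi = np.unravel_index(np.argmin(sse), sse.shape)
            assert abs(fit.IC50 - log_grid[gi]) / log_grid[gi] < 0.01

    def test_nonmonotone_data_flagged(self):
        c = np.array([0.1, 1.0, 10.0, 100.0])
        y = np.array([0.1, 0.8, 0.3, 0.9])
        fit = hill_fit(c, y)
        assert fit.flagged_nonmonotone

    def test_dose_ladder_recovery_from_generator(self, rng):
        table, truth = generate_dose_response(
            FixtureSpec(seed=0, scenario="dose_response",
                        parameters={"IC50": 2.0, "noise_sd": 0.0}), rng)
        fit = hill_fit(table.concentration_um.to_numpy(), table.inhibition.to_numpy())
        assert abs(fit.IC50 - truth["IC50"]) < 1e-6

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            hill_fit(np.array([1.0, 2, 3]), np.array([0.1, 0.5, 0.9]))


class TestTrapezoidAuc:
    def test_constant_pwt_is_a_rectangle(self):
        series = BehaviorSeries(time_h=np.array([0.0, 1, 2, 3, 4]),
                                pwt_g={"a": np.full(5, 5.0)})
        out = trapezoid_auc(series)
        assert out["per_animal"]["a"] == pytest.approx(20.0)

    def test_unsorted_time_points_sorted_before_integration(self):
        t_sorted = np.array([0.0, 1, 2, 4])
        pwt_sorted = np.array([1.0, 3, 2, 5])
        perm = np.array([2, 0, 3, 1])
        a = trapezoid_auc(BehaviorSeries(time_h=t_sorted, pwt_g={"a": pwt_sorted}))
        b = trapezoid_auc(BehaviorSeries(time_h=t_sorted[perm], pwt_g={"a": pwt_sorted[perm]}))
        assert a["per_animal"]["a"] == pytest.approx(b["per_animal"]["a"])

    def test_auc_is_linear_in_pwt(self):
        t = np.array([0.0, 0.5, 1, 2, 3])
        pwt = np.array([2.0, 9, 7, 4, 2.5])
        a1 = trapezoid_auc(BehaviorSeries(time_h=t, pwt_g={"a": pwt}))
        a3 = trapezoid_auc(BehaviorSeries(time_h=t, pwt_g={"a": 3 * pwt}))
        assert a3["per_animal"]["a"] == pytest.approx(3 * a1["per_animal"]["a"])

    def test_group_mean_and_sem(self):
        series = BehaviorSeries(time_h=np.array([0.0, 1.0]),
                                pwt_g={"a": np.array([2.0, 2.0]),
                                       "b": np.array([4.0, 4.0])})
        out = trapezoid_auc(series)
        assert out["mean"] == pytest.approx(3.0)
        assert out["n"] == 2

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError):
            BehaviorSeries(time_h=np.array([1.0]), pwt_g={"a": np.array([2.0])})


class TestGroupStats:
    def test_identical_groups_give_t_zero_p_one(self):
        g = np.array([1.0, 2, 3, 4])
        out = group_stats({"a": g, "b": g.copy()}, design="t")
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_t_test_agrees_with_exhaustive_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.2, 1.0, 6)
        out = group_stats({"a": a, "b": b}, design="t")
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        count = 0
        combos = list(itertools.combinations(range(12), 6))
        for idx in combos:
            mask = np.zeros(12, bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            if diff >= observed - 1e-12:
                count += 1
        p_perm = count / len(combos)
        assert abs(out["p"] - p_perm) < 0.05

    def test_sidak_with_one_comparison_is_identity(self):
        assert sidak_adjust(0.0321, 1) == pytest.approx(0.0321)

    def test_anova_with_sidak_posthoc(self, rng):
        groups = {"ctrl": rng.normal(0, 1, 8), "lo": rng.normal(0.2, 1, 8),
                  "hi": rng.normal(2.0, 1, 8)}
        out = group_stats(groups, design="anova")
        assert out["test"] == "anova"
        for res in out["pairwise_vs_control"].values():
            assert res["p_sidak"] >= res["p_raw"] - 1e-12
            assert res["p_sidak"] == pytest.approx(
                1 - (1 - res["p_raw"]) ** 2)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            group_stats({"a": np.ones(3), "b": np.ones(3)}, design="t")
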