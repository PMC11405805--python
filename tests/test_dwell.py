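"""Dwell-time survival construction, exponential-mixture fits, model choice."""

import numpy as np
import pytest

from smtirf import (
    BindingModel,
    DwellSurvival,
    FitError,
    Trajectory,
    TrajectorySet,
    build_survival,
    classify_transient,
    compute_dwell_times,
    fit_survival,
    per_cell_summary,
    select_model,
    simulate_dwell_times,
)
from oracles import mle_exp_mixture


def _track(n_det, dt, tid=0):
    return Trajectory(tid, np.arange(5, 5 + n_det),
                      5.0 + 0.1 * np.arange(n_det), np.full(n_det, 5.0), dt)


class TestComputeDwellTimes:
    @pytest.mark.parametrize("n_det,dt,expected", [(5, 0.052, 0.208),
                                                   (3, 0.102, 0.204)])
    def test_detections_minus_one_times_interval(self, n_det, dt, expected):
        tset = TrajectorySet([_track(n_det, dt)], dt, 100)
        assert compute_dwell_times(tset)[0] == pytest.approx(expected)

    def test_single_detection_rejected(self):
        tset = TrajectorySet([_track(1, 0.052)], 0.052, 100)
        with pytest.raises(ValueError, match="single detection"):
            compute_dwell_times(tset)


class TestBuildSurvival:
    def test_small_sample_values(self):
        # dwells {1,1,2,2}: S(0)=1, S(1)=0.5, S(2)=0
        dwells = [1.0, 1.0, 2.0, 2.0] * 3  # replicated to pass the n>=10 gate
        curve = build_survival(dwells, 1.0)
        assert curve.survival[0] == pytest.approx(1.0)
        assert curve.log10_survival[0] == pytest.approx(0.0)
        assert curve.survival[1] == pytest.approx(0.5)
        assert np.log10(curve.survival[1]) == pytest.approx(-0.3010, abs=1e-4)
        assert curve.survival[2] == pytest.approx(0.0)

    def test_non_increasing_and_permutation_invariant(self, rng):
        dwells = rng.exponential(1.0, 500)
        a = build_survival(dwells, 0.05)
        b = build_survival(rng.permutation(dwells), 0.05)
        assert np.all(np.diff(a.survival) <= 1e-15)
        assert np.array_equal(a.survival, b.survival)
        assert np.array_equal(a.bin_edges, b.bin_edges)

    def test_log_slope_matches_minus_inverse_tau_ln10(self):
        # single exponential tau=1: d log10 S / dt = -1/ln(10)
        _, quant = simulate_dwell_times(
            100_000, BindingModel(tau_fast=1.0, tau_slow=1.0), 0.05, seed=3
        )
        curve = build_survival(quant, 0.05)
        t, logs = curve.log_curve()
        keep = t < 3.0  # well-populated region
        slope = np.polyfit(t[keep], logs[keep], 1)[0]
        assert slope == pytest.approx(-1 / np.log(10), rel=0.02)

    def test_all_identical_dwells_flagged_unfittable(self):
        with pytest.warns(UserWarning, match="unfittable"):
            curve = build_survival([0.5] * 20, 0.5)
        assert not curve.fittable


class TestFitSurvival:
    def test_exact_single_exponential_points(self):
        t = np.arange(0, 21) * 0.5
        curve = DwellSurvival(
            dwell_times=np.full(100, 2.0 * np.log(2)),
            frame_interval=0.5, bin_edges=t,
            survival=np.exp(-t / 2.0), n=100,
        )
        fit = fit_survival(curve, order=1)
        assert fit.tau1 == pytest.approx(2.0, abs=1e-6)

    def test_exact_two_exponential_points(self):
        t = np.arange(0, 60) * 0.2
        s = 0.7 * np.exp(-t / 0.5) + 0.3 * np.exp(-t / 3.0)
        curve = DwellSurvival(np.full(100, 0.8), 0.2, t, s, 100)
        fit = fit_survival(curve, order=2)
        assert fit.tau1 == pytest.approx(0.5, abs=1e-5)
        assert fit.tau2 == pytest.approx(3.0, abs=1e-5)
        assert fit.alpha == pytest.approx(0.7, abs=1e-5)

    def test_alpha_is_fast_fraction(self):
        # convention: tau1 <= tau2, alpha = fraction of the fast component
        _, quant = simulate_dwell_times(
            20_000, BindingModel(alpha_fast=0.3, tau_fast=0.3, tau_slow=3.0),
            0.052, seed=4,
        )
        fit = fit_survival(build_survival(quant, 0.052), order=2)
        assert fit.tau1 <= fit.tau2
        assert fit.alpha == pytest.approx(0.3, abs=0.05)

    def test_agrees_with_mle_oracle(self):
        # least squares on the quantized survival vs direct MLE of the
        # continuous sample: within 2 joint SE on every parameter
        model = BindingModel(alpha_fast=0.8, tau_fast=0.4, tau_slow=2.5)
        cont, quant = simulate_dwell_times(2000, model, 0.052, seed=5)
        fit = fit_survival(build_survival(quant, 0.052), order=2)
        (tau1, tau2, alpha), (se1, se2, sea) = mle_exp_mixture(cont, order=2)
        for a, b, se_a, se_b in [
            (fit.tau1, tau1, fit.tau1_se, se1),
            (fit.tau2, tau2, fit.tau2_se, se2),
            (fit.alpha, alpha, fit.alpha_se, sea),
        ]:
            joint = np.hypot(se_a, se_b)
            assert abs(a - b) < 2 * joint

    def test_too_few_points_raises(self):
        t = np.array([0.0, 0.5, 1.0])
        curve = DwellSurvival(np.full(20, 0.5), 0.5, t, np.exp(-t), 20)
        with pytest.raises(FitError):
            fit_survival(curve, order=2)

    def test_parameter_recovery_across_seeds(self):
        # median relative error <= 5% on tau, <= 0.02 absolute on alpha
        model = BindingModel(alpha_fast=0.9, tau_fast=0.5, tau_slow=2.5)
        errs_t1, errs_t2, errs_a = [], [], []
        for s in range(50):
            _, quant = simulate_dwell_times(15_000, model, 0.052, seed=100 + s)
            fit = fit_survival(build_survival(quant, 0.052), order=2)
            errs_t1.append(abs(fit.tau1 - 0.5) / 0.5)
            errs_t2.append(abs(fit.tau2 - 2.5) / 2.5)
            errs_a.append(abs(fit.alpha - 0.9))
        assert np.median(errs_t1) <= 0.05
        assert np.median(errs_t2) <= 0.05
        assert np.median(errs_a) <= 0.02

    def test_log_objective_also_recovers(self):
        _, quant = simulate_dwell_times(
            20_000, BindingModel(alpha_fast=0.95, tau_fast=0.8, tau_slow=3.0),
            0.052, seed=6,
        )
        fit = fit_survival(build_survival(quant, 0.052), order=2,
                           objective="log10")
        assert fit.tau1 == pytest.approx(0.8, rel=0.1)
        assert fit.tau2 == pytest.approx(3.0, rel=0.15)


class TestSelectModel:
    def test_pure_single_exponential_prefers_order_1(self):
        _, quant = simulate_dwell_times(
            10_000, BindingModel(tau_fast=1.0, tau_slow=1.0), 0.052, seed=7
        )
        order, fit = select_model(build_survival(quant, 0.052))
        assert order == 1 and fit.order == 1

    def test_clear_mixture_prefers_order_2(self):
        _, quant = simulate_dwell_times(
            10_000,
            BindingModel(alpha_fast=0.8, tau_fast=0.3, tau_slow=3.0),
            0.052, seed=8,
        )
        order, fit = select_model(build_survival(quant, 0.052))
        assert order == 2
        assert fit.tau2 / fit.tau1 >= 2

    def test_degenerate_two_component_rejected(self):
        # alpha == 1 exactly: any second component is spurious
        _, quant = simulate_dwell_times(
            10_000,
            BindingModel(alpha_fast=1.0, tau_fast=0.8, tau_slow=3.0),
            0.052, seed=9,
        )
        order, _ = select_model(build_survival(quant, 0.052))
        assert order == 1


class TestClassifyTransient:
    def test_none_below_threshold(self):
        assert classify_transient([0.2, 0.3, 0.5], threshold=0.104) == 0.0

    def test_closed_form_exponential_fraction(self):
        # P(T < 0.104) = 1 - exp(-0.104/0.289) = 0.302 for tau = 0.289 s
        tau, thr = 0.289, 0.104
        expected = 1 - np.exp(-thr / tau)
        fracs = []
        for s in range(20):
            cont, _ = simulate_dwell_times(
                50_000, BindingModel(tau_fast=tau, tau_slow=tau), 0.052,
                seed=200 + s,
            )
            fracs.append(classify_transient(cont, thr))
        # across-seed mean within 2 SE of the closed form
        se_mean = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 2 * se_mean


class TestPerCellSummary:
    @staticmethod
    def _cells(tau_by_cell, n_per_cell, dt=0.052, seed0=0):
        out = {}
        for i, (cell, tau) in enumerate(tau_by_cell.items()):
            _, quant = simulate_dwell_times(
                n_per_cell, BindingModel(tau_fast=tau, tau_slow=tau), dt,
                seed=seed0 + i,
            )
            out[cell] = quant
        return out

    def test_identical_groups_give_t0_p1(self):
        # same three dwell samples in both groups -> identical cell taus
        base = self._cells({"a": 0.4, "b": 0.5, "c": 0.6}, 2000)
        cells = {**base, **{k + "2": v for k, v in base.items()}}
        groups = {k: ("g1" if len(k) == 1 else "g2") for k in cells}
        res = per_cell_summary(cells, groups)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_t_statistic_matches_hand_formula(self):
        cells = self._cells(
            {"a": 0.3, "b": 0.4, "c": 0.5, "d": 0.6, "e": 0.8, "f": 1.0}, 3000
        )
        groups = {"a": "g1", "b": "g1", "c": "g1",
                  "d": "g2", "e": "g2", "f": "g2"}
        res = per_cell_summary(cells, groups)
        tau = dict(zip(res.table["cell"], res.table["tau1"]))
        x = np.array([tau["a"], tau["b"], tau["c"]])
        y = np.array([tau["d"], tau["e"], tau["f"]])
        # pooled-variance two-sample t computed from first principles
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert res.t_statistic == pytest.approx(t_hand, rel=1e-10)

    def test_group_means_recover_generating_taus(self):
        # 20 cells per group, ~800 molecules each, taus 0.353 vs 0.289 s
        cells = {}
        groups = {}
        for g, tau in (("wt", 0.353), ("mut", 0.289)):
            for i in range(20):
                cid = f"{g}{i}"
                _, quant = simulate_dwell_times(
                    800, BindingModel(tau_fast=tau, tau_slow=tau), 0.052,
                    seed=hash((g, i)) % 2**31,
                )
                cells[cid] = quant
                groups[cid] = g
        res = per_cell_summary(cells, groups)
        assert res.group_means["wt"] == pytest.approx(
            0.353, abs=max(res.group_sds["wt"], 0.02)
        )
        assert res.group_means["mut"] == pytest.approx(
            0.289, abs=max(res.group_sds["mut"], 0.02)
        )
        assert res.p_value < 0.01  # groups clearly separated
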