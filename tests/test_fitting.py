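"""Global-fit machinery: chi^2, runs test, multistarts, recovery,
model comparison, stability probing, single-cycle fitting."""

import numpy as np
import pytest
from statsmodels.sandbox.stats.runs import runstest_1samp

from sprkinetics import (
    BindingComponent,
    InjectionSchedule,
    KineticModel,
    ScheduleError,
    Sensorgram,
    simulate_response,
)
from sprkinetics.fitting import (
    FitOptions,
    FitProblem,
    chi_square,
    compare_models,
    fit_single_cycle,
    global_fit,
    multistart_seeds,
    perturb_and_refit,
    residual_runs_test,
    stability_suite,
    LOG_BOUNDS,
)

FAST_OPTS = FitOptions(n_starts=2, seed=0)


def make_series(model, concs, t_assoc=120.0, t_dissoc=300.0, hz=10.0, sigma=0.0, seed=0):
    """Small synthetic concentration series for fitting tests."""
    rng = np.random.default_rng(seed)
    curves = []
    for i, c in enumerate(concs):
        sched = InjectionSchedule.full_kinetics(c, t_assoc, t_dissoc)
        t = np.arange(sched.start_s, sched.end_s, 1.0 / hz)
        r = simulate_response(model, sched, t)
        if sigma:
            r = r + rng.normal(0, sigma, t.shape)
        curves.append(Sensorgram(t, r, sched, curve_id=f"c{i}", concentration_M=c))
    return curves


ONE_SITE = KineticModel((BindingComponent(ka=1e5, kd=1e-3, rmax=50.0),))
TWO_SITE = KineticModel(
    (BindingComponent(ka=1e5, kd=1e-2, rmax=30.0),
     BindingComponent(ka=2e5, kd=3e-1, rmax=60.0))
)


# ---------------------------------------------------------------------------
# chi^2
# ---------------------------------------------------------------------------


class TestChiSquare:
    def test_zero_residuals(self):
        assert chi_square(np.zeros(10), 3) == 0.0

    def test_hand_computation(self):
        assert chi_square(np.array([1.0, -1.0, 1.0, -1.0]), 0) == 1.0

    def test_zero_degrees_of_freedom_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.array([3.0]), 1)

    def test_accepts_per_curve_lists(self):
        assert chi_square([np.array([1.0, -1.0]), np.array([1.0, -1.0])], 0) == 1.0


# ---------------------------------------------------------------------------
# runs test
# ---------------------------------------------------------------------------


class TestRunsTest:
    def test_exact_lower_tail_by_enumeration(self):
        # +++--- : 2 runs among C(6,3)=20 equally likely arrangements;
        # arrangements with R<=2 are +++--- and ---+++ -> P = 2/20
        r = np.array([0.3, 1.0, 2.0, -1.0, -0.2, -3.0])
        assert residual_runs_test(r, alternative="less") == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "seq",
        [
            [1, 1, 1, 1, -1, -1, -1],  # 2 runs
            [1, -1, 1, -1, 1, -1, 1],  # 7 runs
            [1, 1, -1, -1, 1, 1, -1],  # 4 runs
            [-1, 1, 1, 1, -1, 1, -1],  # 5 runs
        ],
    )
    def test_exact_matches_brute_force_enumeration(self, seq):
        # enumerate all C(7,4) sign placements for n1=4, n2=3 and compare
        # the lower-tail probability with the closed-form runs distribution
        from itertools import combinations

        n1, n2 = 4, 3
        n = n1 + n2
        counts = {}
        for pos in combinations(range(n), n1):
            signs = np.full(n, -1.0)
            signs[list(pos)] = 1.0
            runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
            counts[runs] = counts.get(runs, 0) + 1
        total = sum(counts.values())
        seq = np.array(seq, dtype=float)
        r_obs = 1 + int(np.sum(np.sign(seq[1:]) != np.sign(seq[:-1])))
        brute = sum(v for k, v in counts.items() if k <= r_obs) / total
        assert residual_runs_test(seq, alternative="less") == pytest.approx(brute)

    def test_alternating_sequence_rejects(self):
        r = np.tile([1.0, -1.0], 50)
        assert residual_runs_test(r) < 1e-6

    def test_single_block_rejects(self):
        r = np.concatenate([np.ones(50), -np.ones(50)])
        assert residual_runs_test(r) < 1e-6

    def test_normal_approx_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        assert residual_runs_test(x) == pytest.approx(
            runstest_1samp(x, cutoff=0)[1], rel=1e-12
        )

    def test_type_one_error_calibration(self):
        """Empirical rejection rate at alpha=0.05 under white noise."""
        rng = np.random.default_rng(123)
        rej = sum(
            residual_runs_test(rng.normal(size=100)) < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07

    def test_degenerate_all_zero(self):
        with pytest.raises(ValueError):
            residual_runs_test(np.zeros(10))


# ---------------------------------------------------------------------------
# multistarts
# ---------------------------------------------------------------------------


class TestMultistart:
    def test_determinism(self):
        a = multistart_seeds(FitOptions(n_starts=1, seed=0), order=2)
        b = multistart_seeds(FitOptions(n_starts=1, seed=0), order=2)
        np.testing.assert_array_equal(a[0], b[0])

    def test_distinct_within_bounds(self):
        starts = multistart_seeds(FitOptions(n_starts=32, seed=1), order=2)
        assert len({s.tobytes() for s in starts}) == 32
        arr = np.array(starts)
        for j, key in enumerate(["ka", "kd", "rmax"] * 2):
            lo, hi = LOG_BOUNDS[key]
            assert np.all((arr[:, j] >= lo) & (arr[:, j] <= hi))

    def test_latin_hypercube_marginal_stratification(self):
        n = 16
        starts = np.array(multistart_seeds(FitOptions(n_starts=n, seed=3), order=1))
        for j, key in enumerate(["ka", "kd", "rmax"]):
            lo, hi = LOG_BOUNDS[key]
            bins = np.floor((starts[:, j] - lo) / (hi - lo) * n).astype(int)
            assert sorted(bins) == list(range(n))

    def test_rejects_zero_starts(self):
        with pytest.raises(ValueError):
            FitOptions(n_starts=0)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------


class TestGlobalFit:
    def test_noise_free_one_site_recovery(self):
        curves = make_series(ONE_SITE, [1e-8, 1e-7, 1e-6])
        res = global_fit(FitProblem(curves=curves, model_order=1), FAST_OPTS)
        comp = res.model.components[0]
        true = ONE_SITE.components[0]
        assert comp.ka == pytest.approx(true.ka, rel=1e-3)
        assert comp.kd == pytest.approx(true.kd, rel=1e-3)
        assert comp.rmax == pytest.approx(true.rmax, rel=1e-3)
        assert res.converged and res.chi2 < 1e-10

    def test_noise_free_two_site_recovery(self):
        curves = make_series(TWO_SITE, [1e-8, 1e-7, 1e-6], t_assoc=200.0)
        res = global_fit(FitProblem(curves=curves, model_order=2), FAST_OPTS)
        for fit_c, true_c in zip(res.model.components, TWO_SITE.components):
            assert fit_c.KD == pytest.approx(true_c.KD, rel=1e-4)

    def test_components_reported_in_canonical_order(self):
        curves = make_series(TWO_SITE, [1e-8, 1e-7, 1e-6], t_assoc=200.0)
        res = global_fit(FitProblem(curves=curves, model_order=2), FAST_OPTS)
        kds = [c.kd for c in res.model.components]
        assert kds == sorted(kds)

    def test_determinism_bit_identical(self):
        curves = make_series(ONE_SITE, [1e-7, 1e-6], sigma=0.5, seed=5)
        opts = FitOptions(n_starts=3, seed=9)
        a = global_fit(FitProblem(curves=curves, model_order=1), opts)
        b = global_fit(FitProblem(curves=curves, model_order=1), opts)
        np.testing.assert_array_equal(a.x, b.x)

    def test_nested_dominance_and_degeneracy_on_one_site_data(self):
        curves = make_series(ONE_SITE, [1e-8, 1e-7, 1e-6])
        r1 = global_fit(FitProblem(curves=curves, model_order=1), FAST_OPTS)
        r2 = global_fit(FitProblem(curves=curves, model_order=2), FAST_OPTS)
        # the order-2 fit reproduces the data at least as well ...
        assert r2.ssr <= r1.ssr + 1e-9
        # ... and is a perfect fit whose components jointly degenerate to
        # the generating single site (capacity-weighted behaviour matches)
        assert r2.chi2 < 1e-8
        total_rmax = sum(c.rmax for c in r2.model.components)
        assert total_rmax == pytest.approx(50.0, rel=1e-2)

    def test_identifiability_warning_single_concentration(self):
        curves = make_series(TWO_SITE, [1e-7])
        res = global_fit(FitProblem(curves=curves, model_order=2), FAST_OPTS)
        assert any("identifiable" in w for w in res.warnings)

    def test_bulk_ri_recovered_per_curve(self):
        model = KineticModel(ONE_SITE.components, bulk_ri_RU=8.0)
        curves = make_series(model, [1e-7, 1e-6])
        res = global_fit(
            FitProblem(curves=curves, model_order=1, fit_bulk_ri=True), FAST_OPTS
        )
        for v in res.bulk_ri_by_curve.values():
            assert v == pytest.approx(8.0, abs=0.05)

    def test_chi2_matches_residual_recomputation(self):
        curves = make_series(ONE_SITE, [1e-7], sigma=0.5, seed=2)
        res = global_fit(FitProblem(curves=curves, model_order=1), FAST_OPTS)
        assert res.chi2 == pytest.approx(
            chi_square(res.residuals_flat(), res.n_params)
        )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


class TestCompareModels:
    def test_selects_generating_order_two(self):
        curves = make_series(
            TWO_SITE, np.geomspace(1e-8, 1e-6, 5), t_assoc=300.0, sigma=0.5, seed=3
        )
        cmp = compare_models(curves, (1, 2, 3), FAST_OPTS)
        assert cmp.selected_order == 2
        assert 2 in cmp.results_by_order

    def test_selects_generating_order_one(self):
        curves = make_series(
            ONE_SITE, np.geomspace(1e-8, 1e-6, 5), sigma=0.5, seed=4
        )
        cmp = compare_models(curves, (1, 2, 3), FAST_OPTS)
        assert cmp.selected_order == 1

    def test_chi2_non_increasing_in_order(self):
        curves = make_series(
            TWO_SITE, np.geomspace(1e-8, 1e-6, 4), t_assoc=200.0, sigma=0.5, seed=8
        )
        cmp = compare_models(curves, (1, 2, 3), FitOptions(n_starts=4, seed=0))
        chis = [cmp.results_by_order[k].chi2 for k in sorted(cmp.results_by_order)]
        assert chis[0] >= chis[1] >= chis[2]

    def test_rationale_mentions_thresholds(self):
        curves = make_series(ONE_SITE, [1e-7, 1e-6], sigma=0.5, seed=4)
        cmp = compare_models(curves, (1, 2), FAST_OPTS)
        assert "chi2 ratio" in cmp.selection_rationale


# ---------------------------------------------------------------------------
# stability probing
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def reference_fit():
    curves = make_series(ONE_SITE, [1e-8, 1e-7, 1e-6])
    return global_fit(FitProblem(curves=curves, model_order=1), FAST_OPTS)


class TestStability:

    def test_well_conditioned_fit_reproduces(self, reference_fit):
        for name in ("ka1", "kd1", "rmax1"):
            rep = perturb_and_refit(reference_fit, name, factor=10.0)
            assert rep.reproduced, f"{name}: dlog={rep.max_abs_dlog10}"

    def test_identity_perturbation_trivially_reproduces(self, reference_fit):
        rep = perturb_and_refit(reference_fit, "ka1", factor=1.0)
        assert rep.reproduced and rep.max_abs_dlog10 < 1e-9

    def test_suite_flags_well(self, reference_fit):
        reports, flag = stability_suite(reference_fit)
        assert flag == "well"
        assert reference_fit.condition_flag == "well"

    def test_overparameterized_fit_flags_ill(self):
        """An order-3 fit to noisy order-2 data often lands in a different
        minimum after a single-parameter perturbation (low resistance to
        initial-value changes)."""
        curves = make_series(
            TWO_SITE, np.geomspace(1e-8, 1e-6, 5), t_assoc=300.0, sigma=0.5, seed=7
        )
        fit3 = global_fit(FitProblem(curves=curves, model_order=3), FAST_OPTS)
        reports, flag = stability_suite(fit3, options=FAST_OPTS)
        assert flag == "ill"
        assert any(not r.reproduced for r in reports)

    def test_unknown_parameter_rejected(self, reference_fit):
        with pytest.raises(KeyError):
            perturb_and_refit(reference_fit, "ka9")

    def test_factor_below_one_rejected(self, reference_fit):
        with pytest.raises(ValueError):
            perturb_and_refit(reference_fit, "ka1", factor=0.5)


# ---------------------------------------------------------------------------
# single-cycle kinetics
# ---------------------------------------------------------------------------


SLOW_SITE = KineticModel((BindingComponent(ka=1.2e2, kd=1.67e-5, rmax=641.0),))


def make_single_cycle(model, concs, t_inject=600.0, t_dissoc=600.0, hz=10.0):
    sched = InjectionSchedule.single_cycle(list(concs), t_inject, t_dissoc)
    t = np.arange(sched.start_s, sched.end_s, 1.0 / hz)
    r = simulate_response(model, sched, t)
    return [Sensorgram(t, r, sched, curve_id="sc")]


class TestSingleCycle:
    def test_six_injections_rejected(self):
        with pytest.raises(ScheduleError):
            InjectionSchedule.single_cycle([1e-8] * 6, 60.0)

    def test_full_kinetics_schedule_rejected(self):
        curves = make_series(ONE_SITE, [1e-7])
        with pytest.raises(ScheduleError):
            fit_single_cycle(FitProblem(curves=curves, model_order=1))

    def test_slow_dissociation_kd_recovery(self):
        """kd recovered within 1% from a single-cycle titration even though
        the surface never fully dissociates between injections."""
        kd_true = SLOW_SITE.components[0].kd
        concs = np.geomspace(1.39e-8, 1.39e-6, 5)  # KD/10 .. 10*KD
        curves = make_single_cycle(SLOW_SITE, concs)
        res = fit_single_cycle(
            FitProblem(curves=curves, model_order=1), FAST_OPTS
        )
        assert res.model.components[0].kd == pytest.approx(kd_true, rel=0.01)

    def test_cross_protocol_consistency(self):
        """Single-cycle and full-kinetics fits of the same noise-free model
        agree in ka and kd within 0.5%."""
        model = KineticModel((BindingComponent(ka=1e4, kd=5e-4, rmax=100.0),))
        concs = np.geomspace(5e-9, 5e-7, 5)
        sc = fit_single_cycle(
            FitProblem(curves=make_single_cycle(model, concs, t_inject=300.0),
                       model_order=1),
            FAST_OPTS,
        )
        fk = global_fit(
            FitProblem(curves=make_series(model, concs, t_assoc=300.0, t_dissoc=600.0),
                       model_order=1),
            FAST_OPTS,
        )
        a, b = sc.model.components[0], fk.model.components[0]
        assert a.ka == pytest.approx(b.ka, rel=5e-3)
        assert a.kd == pytest.approx(b.kd, rel=5e-3)
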