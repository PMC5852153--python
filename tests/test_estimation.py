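import numpy as np
import pytest

from clampkinetics.data import SubjectRecord
from clampkinetics.estimation import (
    EstimationConfig,
    NormalizationMeans,
    ParamRestriction,
    SubjectObjective,
    cohort_means,
    evolutionary_search,
    fit_subject,
    refine_local,
    rss,
)


@pytest.fixture(scope="module")
def light_config():
    """Reduced search for unit-level checks (the recovery benchmarks at the
    standard test-scale settings live in the acceptance suite)."""
    return EstimationConfig(n_parents=60, n_generations=200, n_restarts=2, rng_seed=3)


class TestRss:
    def test_perfect_fit_is_zero(self):
        means = NormalizationMeans(300.0, 1500.0)
        I = np.array([100.0, 200.0])
        CP = np.array([500.0, 700.0])
        assert rss(I, CP, I, CP, means) == 0.0

    def test_unit_residuals_count_points(self):
        means = NormalizationMeans(300.0, 1500.0)
        I = np.array([100.0, 200.0])
        sim_I = I - 300.0  # each insulin residual equals I_mean
        CP = np.array([500.0, 700.0])
        assert rss(I, CP, sim_I, CP, means) == pytest.approx(2.0)

    def test_doubling_means_quarters_rss(self):
        m1 = NormalizationMeans(300.0, 1500.0)
        m2 = NormalizationMeans(600.0, 3000.0)
        I, CP = np.array([100.0]), np.array([500.0])
        sI, sCP = np.array([130.0]), np.array([560.0])
        assert rss(I, CP, sI, sCP, m2) == pytest.approx(rss(I, CP, sI, sCP, m1) / 4)

    def test_length_mismatch(self):
        means = NormalizationMeans(300.0, 1500.0)
        with pytest.raises(ValueError):
            rss([1.0, 2.0], [1.0], [1.0], [1.0], means)


class TestCohortMeans:
    def test_single_subject_mean(self, noiseless_cohort):
        r = noiseless_cohort.records[0]
        m = cohort_means([r])
        assert m.I_mean == pytest.approx(r.insulin.mean())

    def test_pooled_not_mean_of_means(self):
        r1, r2 = [self._record(f"s{i}", vals) for i, vals in
                  enumerate([[300.0, 306.0], [400.0]])]
        m = cohort_means([r1, r2])
        # pooled: (300 + 306 + 400) / 3, not mean of subject means
        assert m.I_mean == pytest.approx(1006.0 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_means([])

    @staticmethod
    def _record(sid, insulin):
        from clampkinetics.data import SubjectMeta

        t = np.arange(5.0, 5.0 * (len(insulin) + 1) - 1e-9, 5.0)
        meta = SubjectMeta(sid, "male", 70.0, 170.0, "NGT", 5.0, 40.0, 400.0)
        return SubjectRecord(meta, t, np.asarray(insulin, float),
                             np.full(len(insulin), 1000.0), t, np.full(len(insulin), 5.0))


class TestEvolutionarySearch:
    BOUNDS = (np.full(8, -5.0), np.full(8, 5.0))

    @staticmethod
    def sphere(x):
        return np.sum(np.atleast_2d(x) ** 2, axis=1)

    def test_sphere_benchmark(self):
        rng = np.random.default_rng(0)
        _, best = evolutionary_search(self.sphere, self.BOUNDS, 50, 200, rng)
        assert best < 1e-3

    def test_zero_generations_returns_initial_best(self):
        rng = np.random.default_rng(1)
        x0 = np.random.default_rng(1).random((50, 8)) * 10 - 5
        _, best = evolutionary_search(self.sphere, self.BOUNDS, 50, 0, rng)
        assert best == pytest.approx(self.sphere(x0).min())

    def test_deterministic_given_seed(self):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            runs.append(evolutionary_search(self.sphere, self.BOUNDS, 30, 50, rng))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_nonfinite_objective_aborts(self):
        def bad(x):
            return np.full(np.atleast_2d(x).shape[0], np.nan)

        with pytest.raises(RuntimeError):
            evolutionary_search(bad, self.BOUNDS, 20, 5, np.random.default_rng(0))


@pytest.fixture(scope="module")
def objective(noiseless_cohort):
    """Objective whose optimum is exactly the true parameters: the
    observations are produced by the same forward map the residual uses."""
    cohort = noiseless_cohort
    s = cohort.subjects[0]
    cfg = EstimationConfig()
    means = cohort_means(cohort.records)
    obj = SubjectObjective(s.record, s.G, s.f, means, cfg)
    x_true = np.log10(s.true_params.as_array())
    I, CP = obj._simulate(x_true, cfg.refine_dt)
    rec = SubjectRecord(
        meta=s.record.meta,
        sample_times=s.record.sample_times,
        insulin=I[0],
        cpeptide=CP[0],
        glucose_times=s.record.glucose_times,
        glucose_values=s.record.glucose_values,
    )
    obj_sc = SubjectObjective(rec, s.G, s.f, means, cfg)
    return obj_sc, x_true, cfg


class TestRefineLocal:
    def test_truth_is_fixed_point(self, objective):
        obj, x_true, cfg = objective
        bounds = cfg.log_bounds(ParamRestriction.full())
        _, rss_out, _ = refine_local(x_true, obj.residual, bounds,
                                     h_index=2, h_edges=obj.h_edges)
        assert rss_out < 1e-10

    def test_recovers_from_smooth_perturbation(self, objective):
        # h held at truth: the secretion switch makes the objective only
        # piecewise-smooth in h, so the gradient stage owns the other seven
        obj, x_true, cfg = objective
        bounds = cfg.log_bounds(ParamRestriction.full())
        rng = np.random.default_rng(5)
        x0 = x_true + 0.02 * rng.standard_normal(8)
        x0[2] = x_true[2]
        x, rss_out, _ = refine_local(x0, obj.residual, bounds,
                                     h_index=2, h_edges=obj.h_edges, max_nfev=2000)
        assert rss_out < 1e-8
        for k in (5, 6):  # k_ratio, k_Iout
            assert abs(10 ** (x[k] - x_true[k]) - 1) < 1e-4

    def test_never_worse_than_start(self, objective):
        obj, x_true, cfg = objective
        bounds = cfg.log_bounds(ParamRestriction.full())
        x0 = np.clip(x_true + 1.5, *bounds)
        rss0 = obj.rss_at(x0)
        _, rss_out, _ = refine_local(x0, obj.residual, bounds, max_nfev=20)
        assert rss_out <= rss0


class TestFitSubject:
    def test_light_recovery_single_subject(self, noiseless_cohort, light_config):
        cohort = noiseless_cohort
        s = cohort.subjects[3]
        means = cohort_means(cohort.records)
        fr = fit_subject(s.record, s.G, s.f, light_config, means=means)
        assert fr.rss < 1e-4
        for name in ("k_ratio", "k_Iout", "h", "k_CPout"):
            est, true = getattr(fr.params, name), getattr(s.true_params, name)
            assert abs(est / true - 1) < 0.10

    def test_results_within_bounds(self, noiseless_cohort, light_config):
        s = noiseless_cohort.subjects[2]
        fr = fit_subject(s.record, s.G, s.f, light_config)
        theta = fr.params.as_array()
        assert np.all(theta >= 1e-6) and np.all(theta <= 1e4)
        assert fr.params.k_ratio <= 1.0

    def test_deterministic_and_independent_of_cohort_order(
        self, noiseless_cohort, light_config
    ):
        s = noiseless_cohort.subjects[1]
        f1 = fit_subject(s.record, s.G, s.f, light_config)
        f2 = fit_subject(s.record, s.G, s.f, light_config)
        assert f1.rss == f2.rss
        assert np.array_equal(f1.params.as_array(), f2.params.as_array())

    def test_sampling_order_invariance(self, noiseless_cohort, light_config):
        s = noiseless_cohort.subjects[1]
        rec = s.record
        perm = np.random.default_rng(0).permutation(rec.sample_times.size)
        shuffled = SubjectRecord(
            meta=rec.meta,
            sample_times=rec.sample_times[perm],
            insulin=rec.insulin[perm],
            cpeptide=rec.cpeptide[perm],
            glucose_times=rec.glucose_times,
            glucose_values=rec.glucose_values,
        )
        f1 = fit_subject(rec, s.G, s.f, light_config)
        f2 = fit_subject(shuffled, s.G, s.f, light_config)
        assert f1.rss == f2.rss
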