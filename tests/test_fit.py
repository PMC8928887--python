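import numpy as np
import pytest
from scipy import stats

from adbm import (
    ABCConfig,
    ADBMParams,
    AcceptanceExhaustedError,
    PredationMatrix,
    PriorSpec,
    distance,
    elicit_a_lower_bound,
    generate_community,
    generate_truth,
    kernel_weight,
    posterior_predictive,
    predict_web,
    rejection_abc,
    sample_prior,
    select_threshold,
    summarize_posterior,
)

TRUE_PARAMS = ADBMParams(a=1e-3, ai=0.5, aj=0.5, b=0.1)
GRID = np.round(np.arange(0.1, 1.55, 0.1), 10)


@pytest.fixture(scope="module")
def instance():
    comm = generate_community(15, (-4, 2), 21)
    return comm, generate_truth(comm, TRUE_PARAMS)


class TestPrior:
    def test_degenerate_intervals_give_point_mass(self):
        prior = PriorSpec(
            log10_a_bounds=(-3, -3), ai_bounds=(0.5, 0.5), aj_bounds=(0.5, 0.5),
            log10_b_bounds=(-1, -1),
        )
        p = sample_prior(prior, np.random.default_rng(0))
        assert (p.log10_a, p.ai, p.aj, p.log10_b) == (-3, 0.5, 0.5, -1)

    def test_draws_respect_bounds_and_are_uniform(self):
        prior = PriorSpec(log10_a_bounds=(-12, 10))
        rng = np.random.default_rng(1)
        draws = [sample_prior(prior, rng) for _ in range(10_000)]
        ai = np.array([d.ai for d in draws])
        log10_b = np.array([d.log10_b for d in draws])
        assert ai.min() >= -1.5 and ai.max() <= 1.5
        assert log10_b.min() >= -15 and log10_b.max() <= 15
        assert all(-12 <= d.log10_a <= 10 for d in draws)
        assert stats.kstest(ai, stats.uniform(-1.5, 3.0).cdf).pvalue > 1e-3

    def test_same_seed_reproduces_draws(self):
        prior = PriorSpec(log10_a_bounds=(-12, 10))
        d1 = [sample_prior(prior, np.random.default_rng(9)) for _ in range(5)]
        d2 = [sample_prior(prior, np.random.default_rng(9)) for _ in range(5)]
        assert d1 == d2


class TestKernelWeight:
    @pytest.mark.parametrize(
        "d,tol,expected",
        [(0.0, 0.5, 1.0), (0.5, 0.5, 0.0), (0.7, 0.5, 0.0), (0.25, 0.5, 0.75)],
    )
    def test_epanechnikov_values(self, d, tol, expected):
        assert kernel_weight(d, tol) == pytest.approx(expected)

    def test_decreasing_in_distance(self):
        w = [kernel_weight(d, 1.0) for d in np.linspace(0, 1, 20)]
        assert np.all(np.diff(w) < 0)


class TestRejectionABC:
    def test_point_mass_prior_self_fit(self, instance):
        comm, truth = instance
        prior = PriorSpec(
            log10_a_bounds=(-3, -3), ai_bounds=(0.5, 0.5), aj_bounds=(0.5, 0.5),
            log10_b_bounds=(-1, -1),
        )
        post = rejection_abc(truth, comm, prior, ABCConfig(tol=0.5, n_accept=20, seed=0))
        assert len(post) == 20
        assert post.attempts_used == 20  # distance 0 means weight 1: no rejections
        assert all(s.distance == 0.0 and s.params == TRUE_PARAMS for s in post.samples)

    def test_unreachable_tolerance_reports_best_distance(self, instance):
        comm, truth = instance
        # a web with a hole in an otherwise contiguous diet cannot be matched exactly
        gappy = truth.links.copy()
        on = np.argwhere(gappy == 1)
        gappy[tuple(on[len(on) // 2])] = 0
        observed = PredationMatrix(comm, gappy)
        prior = PriorSpec(log10_a_bounds=(-8, 2))
        with pytest.raises(AcceptanceExhaustedError) as err:
            rejection_abc(
                observed, comm, prior,
                ABCConfig(tol=1e-6, n_accept=5, seed=1, max_attempts=500),
            )
        assert err.value.best_distance > 0
        assert err.value.attempts == 500

    def test_accepted_samples_regenerate_exactly(self, instance):
        comm, truth = instance
        prior = PriorSpec(log10_a_bounds=(-8, 2))
        scan = select_threshold(truth, comm, prior, GRID, seed=2, n_reference=1000)
        post = rejection_abc(
            truth, comm, prior, ABCConfig(tol=scan.tol, n_accept=50, seed=3)
        )
        assert len(post) == 50
        for s in post.samples:
            assert s.distance < scan.tol
            assert s.tss == 1.0 - s.distance
            # the model is deterministic: stored distance must regenerate bitwise
            assert distance(truth, predict_web(comm, s.params)) == s.distance

    def test_same_seed_bitwise_reproducible(self, instance):
        comm, truth = instance
        prior = PriorSpec(log10_a_bounds=(-8, 2))
        cfg = ABCConfig(tol=0.8, n_accept=25, seed=11)
        p1 = rejection_abc(truth, comm, prior, cfg)
        p2 = rejection_abc(truth, comm, prior, cfg)
        assert p1.to_frame().equals(p2.to_frame())


class TestSelectThreshold:
    def test_first_grid_hit_is_returned(self, instance):
        comm, truth = instance
        prior = PriorSpec(log10_a_bounds=(-8, 2))
        scan = select_threshold(truth, comm, prior, GRID, seed=4, n_reference=2000)
        t = scan.table
        first = t.loc[t["contains_observed"], "tol"].iloc[0]
        assert scan.tol == first
        # self-generated data: some tolerance must admit the observed connectance
        assert t["contains_observed"].any()

    def test_interval_width_grows_with_tolerance(self, instance):
        comm, truth = instance
        prior = PriorSpec(log10_a_bounds=(-8, 2))
        scan = select_threshold(truth, comm, prior, GRID, seed=5, n_reference=4000)
        widths = (scan.table["upper"] - scan.table["lower"]).dropna().to_numpy()
        assert widths[-1] > widths[0]
        assert np.all(np.diff(widths) > -0.05)  # small sampling-noise slack


class TestElicitABound:
    def test_constant_tss_returns_grid_maximum(self, instance):
        comm, truth = instance
        prior = PriorSpec(log10_a_bounds=(-12, 10))
        # far below saturation the predicted web no longer depends on a
        scan = elicit_a_lower_bound(
            truth, comm, prior, [-11.0, -10.0, -9.0], n_probe=64, seed=6
        )
        assert scan.bound == -9.0

    def test_coarse_bound_not_above_dense_bound(self, instance):
        comm, truth = instance
        prior = PriorSpec(log10_a_bounds=(-12, 10))
        coarse_grid = np.arange(-12.0, 6.1, 2.0)
        dense_grid = np.arange(-12.0, 6.1, 0.5)
        coarse = elicit_a_lower_bound(truth, comm, prior, coarse_grid, n_probe=128, seed=7)
        dense = elicit_a_lower_bound(truth, comm, prior, dense_grid, n_probe=128, seed=7)
        assert coarse.bound <= dense.bound + 2.0
        assert dense.table["best_tss"].max() > 0.5

    def test_wide_mass_range_yields_finite_interior_bound(self):
        # a community spanning 14 orders of magnitude still yields a usable bound
        comm = generate_community(30, (-8, 6), 30)
        truth = generate_truth(comm, ADBMParams(a=1e-5, ai=0.5, aj=0.5, b=0.05))
        prior = PriorSpec(log10_a_bounds=(-14, 10))
        scan = elicit_a_lower_bound(
            truth, comm, prior, np.arange(-14.0, 10.1, 2.0), n_probe=64, seed=8
        )
        assert np.isfinite(scan.bound)
        assert scan.bound > -14.0


@pytest.fixture(scope="module")
def posterior(instance):
    comm, truth = instance
    prior = PriorSpec(log10_a_bounds=(-8, 2))
    return comm, truth, rejection_abc(
        truth, comm, prior, ABCConfig(tol=0.6, n_accept=100, seed=13)
    )


class TestPosteriorSummaries:

    def test_posterior_predictive_recount(self, posterior):
        comm, _, post = posterior
        pp = posterior_predictive(post, comm)
        recount = np.zeros((comm.size, comm.size), dtype=int)
        for s in post.samples:
            recount += predict_web(comm, s.params).links
        assert np.array_equal(pp.link_frequency.counts, recount)
        assert pp.link_frequency.n_webs == len(post)
        assert pp.histogram.sum() == comm.size**2
        assert pp.n_never_predicted == int((recount == 0).sum())
        assert pp.link_frequency.proportions.min() >= 0
        assert pp.link_frequency.proportions.max() <= 1

    def test_identical_params_give_all_or_nothing_counts(self, instance):
        comm, truth = instance
        prior = PriorSpec(
            log10_a_bounds=(-3, -3), ai_bounds=(0.5, 0.5), aj_bounds=(0.5, 0.5),
            log10_b_bounds=(-1, -1),
        )
        post = rejection_abc(truth, comm, prior, ABCConfig(tol=0.5, n_accept=10, seed=0))
        pp = posterior_predictive(post, comm)
        assert set(np.unique(pp.link_frequency.counts)) <= {0, 10}

    def test_quantiles_match_sort_oracle(self, posterior):
        _, _, post = posterior
        summary = summarize_posterior(post, level=0.9)
        tss = np.sort(post.to_frame()["tss"].to_numpy())
        lo, hi = np.quantile(tss, [0.05, 0.95])
        assert summary.loc["tss", "lower"] == pytest.approx(lo)
        assert summary.loc["tss", "upper"] == pytest.approx(hi)
        assert summary.loc["tss", "mean"] == pytest.approx(tss.mean())

    def test_level_one_gives_min_max_range(self, posterior):
        _, _, post = posterior
        summary = summarize_posterior(post, level=1.0)
        frame = post.to_frame()
        assert summary.loc["connectance", "lower"] == frame["connectance"].min()
        assert summary.loc["connectance", "upper"] == frame["connectance"].max()

    def test_constant_samples_have_zero_width_intervals(self, instance):
        comm, truth = instance
        prior = PriorSpec(
            log10_a_bounds=(-3, -3), ai_bounds=(0.5, 0.5), aj_bounds=(0.5, 0.5),
            log10_b_bounds=(-1, -1),
        )
        post = rejection_abc(truth, comm, prior, ABCConfig(tol=0.5, n_accept=10, seed=0))
        summary = summarize_posterior(post)
        assert summary.loc["log10_b", "lower"] == summary.loc["log10_b", "upper"] == -1.0
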