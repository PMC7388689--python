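"""Wakefield ABFs, regional Bayes factors, EM priors and posteriors."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

import pleiokit as pk


class TestWakefieldAbf:
    def test_null_z_reduces_to_shrinkage_factor(self):
        cfg = pk.AbfConfig(prior_variances=(0.1,))
        labf = pk.wakefield_log_abf(np.array([0.0]), np.array([0.1]), cfg)
        assert np.exp(labf[0]) == pytest.approx(np.sqrt(0.01 / 0.11))

    def test_vanishing_prior_gives_unit_bayes_factor(self):
        cfg = pk.AbfConfig(prior_variances=(1e-12,))
        labf = pk.wakefield_log_abf(np.array([0.3]), np.array([0.1]), cfg)
        assert np.exp(labf[0]) == pytest.approx(1.0, abs=1e-4)

    def test_closed_form_at_z_two_equal_variances(self):
        # V = W: ABF = sqrt(1/2) * exp(z^2/4) with z = 2
        cfg = pk.AbfConfig(prior_variances=(0.01,))
        labf = pk.wakefield_log_abf(np.array([0.2]), np.array([0.1]), cfg)
        assert np.exp(labf[0]) == pytest.approx(np.sqrt(0.5) * np.e, rel=1e-6)

    def test_stable_for_extreme_z(self):
        labf = pk.wakefield_log_abf(np.array([5.0]), np.array([0.1]))  # z = 50
        assert np.isfinite(labf).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pk.wakefield_log_abf(np.array([np.nan]), np.array([0.1]))
        with pytest.raises(ValueError):
            pk.wakefield_log_abf(np.array([0.1]), np.array([0.0]))


def brute_force_rbfs(abf1, abf2):
    """Double-loop oracle on the natural scale."""
    k = len(abf1)
    rbf1 = np.mean(abf1)
    rbf2 = np.mean(abf2)
    rbf3 = np.mean(abf1 * abf2)
    tot = 0.0
    for i in range(k):
        for j in range(k):
            if i != j:
                tot += abf1[i] * abf2[j]
    rbf4 = tot / (k * (k - 1)) if k > 1 else 0.0
    return np.array([rbf1, rbf2, rbf3, rbf4])


class TestRegionalBfs:
    def test_two_snp_hand_example(self):
        lr = pk.regional_log_bfs(np.log([10.0, 1.0]), np.log([8.0, 1.0]))
        assert np.exp(lr) == pytest.approx([5.5, 4.5, 40.5, 9.0], rel=1e-12)

    def test_uninformative_region(self):
        lr = pk.regional_log_bfs(np.zeros(5), np.zeros(5))
        assert np.exp(lr) == pytest.approx([1, 1, 1, 1])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert np.allclose(pk.regional_log_bfs(a, b),
                           pk.regional_log_bfs(a[perm], b[perm]))

    def test_single_snp_region_excludes_model_four(self):
        lr = pk.regional_log_bfs(np.array([2.0]), np.array([1.0]))
        assert lr[3] == -np.inf
        assert np.isfinite(lr[:3]).all()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = rng.integers(2, 40)
            labf1 = rng.normal(0, 3, size=k)
            labf2 = rng.normal(0, 3, size=k)
            got = np.exp(pk.regional_log_bfs(labf1, labf2))
            want = brute_force_rbfs(np.exp(labf1), np.exp(labf2))
            assert np.allclose(got, want, rtol=1e-10)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            pk.regional_log_bfs(np.array([]), np.array([]))


def grid_search_priors(log_rbfs, dirichlet_alpha=1.1):
    """Coarse-to-fine grid maximization of the penalized EM objective.

    Refines down to a 0.001 step, providing an independent optimum for the
    EM estimator to match.
    """
    R = log_rbfs.shape[0]
    lB5 = np.column_stack([np.zeros(R), log_rbfs])
    a = dirichlet_alpha - 1.0

    def objective(pi):
        with np.errstate(divide="ignore"):
            lw = np.log(pi)[None, :] + lB5
        return logsumexp(lw, axis=1).sum() + a * np.sum(np.log(np.maximum(pi, 1e-300)))

    def grid(step, center=None, radius=None):
        n = round(1.0 / step)
        best, best_obj = None, -np.inf
        rng4 = []
        for d in range(4):
            if center is None:
                rng4.append(range(n + 1))
            else:
                c = round(center[d] / step)
                r = round(radius / step)
                rng4.append(range(max(0, c - r), min(n, c + r) + 1))
        for idx in itertools.product(*rng4):
            if sum(idx) > n:
                continue
            pi = np.array([n - sum(idx), *idx]) * step
            obj = objective(np.maximum(pi, 1e-12))
            if obj > best_obj:
                best, best_obj = pi, obj
        return best

    pi = grid(0.02)
    pi = grid(0.005, center=pi[1:], radius=0.02)
    pi = grid(0.001, center=pi[1:], radius=0.005)
    return pi


class TestPriors:
    def test_null_data_pushes_weight_to_model_zero(self):
        lr = np.full((50, 4), -20.0)
        priors, _ = pk.estimate_priors(lr)
        assert priors.pi[0] > 0.95
        assert priors.pi[1:].min() > 0  # smoothing keeps weights off boundary

    def test_em_matches_grid_search_on_toy_problem(self):
        lr = np.log(np.array([[2.0, 0.5, 8.0, 1.0],
                              [0.3, 4.0, 0.5, 6.0]]))
        em, _ = pk.estimate_priors(lr)
        grid = grid_search_priors(lr)
        assert np.abs(em.pi - grid).max() < 0.005

    def test_penalized_objective_nondecreasing(self):
        rng = np.random.default_rng(2)
        lr = rng.normal(0, 2, size=(200, 4))
        _, trace = pk.estimate_priors(lr)
        assert (np.diff(trace) >= -1e-9).all()

    def test_recovers_mixture_proportions(self):
        df, models = pk.simulate_regions(1000, 30, seed=9)
        res = pk.ColocModel(df).fit()
        freq = np.bincount(models, minlength=5) / len(models)
        assert np.abs(res.priors.pi - freq).max() < 0.05


class TestPosteriors:
    def test_hand_example_flat_priors(self):
        lr = np.log([5.5, 4.5, 40.5, 9.0])
        pp = pk.region_posteriors(lr, pk.ModelPriors.flat())
        assert pp[3] == pytest.approx(40.5 / (1 + 5.5 + 4.5 + 40.5 + 9), rel=1e-9)
        assert pp[3] == pytest.approx(0.6694, abs=5e-4)

    def test_uninformative_region_flat(self):
        pp = pk.region_posteriors(np.zeros(4), pk.ModelPriors.flat())
        assert np.allclose(pp, 0.2)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(3)
        pp = pk.region_posteriors(rng.normal(0, 5, size=(50, 4)),
                                  pk.ModelPriors(np.array([.5, .1, .1, .2, .1])))
        assert np.allclose(pp.sum(axis=1), 1.0, atol=1e-9)


class TestTopSnp:
    def test_shared_model_product_weights(self):
        # ABF products (80, 1) -> first SNP, posterior 80/81
        sid, post = pk.top_snp(np.log([10.0, 1.0]), np.log([8.0, 1.0]), 3,
                               ["s1", "s2"])
        assert sid == "s1"
        assert post == pytest.approx(80 / 81)

    def test_single_snp_region(self):
        sid, post = pk.top_snp(np.array([1.0]), np.array([1.0]), 1, ["only"])
        assert sid == "only" and post == pytest.approx(1.0)

    def test_selection_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(size=10)
        ids = [f"s{i}" for i in range(10)]
        sid, _ = pk.top_snp(a, b, 3, ids)
        perm = rng.permutation(10)
        sid_p, _ = pk.top_snp(a[perm], b[perm], 3, [ids[i] for i in perm])
        assert sid == sid_p

    def test_no_single_snp_for_models_zero_and_four(self):
        assert pk.top_snp(np.zeros(3), np.zeros(3), 0, ["a", "b", "c"]) is None
        assert pk.top_snp(np.zeros(3), np.zeros(3), 4, ["a", "b", "c"]) is None


class TestClassify:
    def test_threshold_is_strict(self):
        pp = np.array([[0.02, 0.01, 0.01, 0.95, 0.01],
                       [0.04, 0.02, 0.02, 0.90, 0.02]])
        assigned = pk.classify_regions(pp, 0.9)
        assert list(assigned) == [3, -1]

    def test_results_classify_counts(self):
        df, models = pk.simulate_regions(300, 30, seed=10)
        res = pk.ColocModel(df).fit()
        lists = res.classify(0.9)
        total = sum(len(v) for v in lists.values())
        assert total <= len(res.regions)
        assert "model 3" in res.summary()
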