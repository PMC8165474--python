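import itertools

import numpy as np
import pytest
from scipy.stats import norm

from grsleak import (
    DVector, EMConfig, SEMConfig, accuracy, baseline_most_common, build_K,
    call_genotypes, em_attack, em_single, estimate_K, fit_grs, gibbs_conditional,
    sem_attack, sem_multiple, SimConfig, make_split,
)

from conftest import refit_with_added

FAST_SEM = dict(max_iter=400, burn_in=100, averaging_window=300)


@pytest.fixture(scope="module")
def em_inputs(small_split):
    old = fit_grs(small_split.private_base, small_split.private_phenotypes)
    K = build_K(small_split.private_base)
    K_hat = estimate_K(small_split.public, small_split.private_base.snp_ids)
    alphas = small_split.public.values.mean(axis=0)
    return small_split, old, K, K_hat, alphas


class TestEmSingle:
    @pytest.mark.parametrize("init", ["prior_probs", "zeros"])
    def test_exact_K_noiseless_limit_recovers_truth(self, em_inputs, init):
        split, old, K, _, alphas = em_inputs
        new, G_add = refit_with_added(split, [0])
        res = em_attack(K, old, new, alphas, EMConfig(init_mode=init))
        assert accuracy(res.genotypes, G_add) == 1.0
        assert res.diagnostics["at_sigma2_floor"]

    def test_estimated_K_beats_baseline_on_average(self, em_inputs):
        split, old, _, K_hat, alphas = em_inputs
        base = baseline_most_common(split.public, split.private_base.snp_ids)
        em_accs, base_accs = [], []
        for t in range(10):
            new, G_add = refit_with_added(split, [t])
            res = em_attack(K_hat, old, new, alphas)
            em_accs.append(accuracy(res.genotypes, G_add))
            base_accs.append(accuracy(base[None, :], G_add.values))
        assert np.mean(em_accs) > np.mean(base_accs)

    def test_monotone_observed_loglik(self, em_inputs):
        split, old, _, K_hat, alphas = em_inputs
        new, _ = refit_with_added(split, [2])
        res = em_attack(K_hat, old, new, alphas)
        trace = np.array(res.diagnostics["loglik_trace"])
        assert np.all(np.diff(trace) >= -1e-10)

    def test_planted_parameter_recovery(self):
        """x ~ N(C*phi0, s2 I) with known C: EM recovers C within 3 MC SE."""
        C_true, sigma, N = 0.4, 0.05, 150
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(60):
            phi0 = np.append((rng.random(N) < 0.5).astype(float), 1.0)
            x = C_true * phi0 + rng.normal(0, sigma, N + 1)
            d = DVector(x, 1, [f"s{i}" for i in range(N)])
            res = em_single(d, np.full(N, 0.5))
            estimates.append(res.C.C_values[0])
        err = np.mean(estimates) - C_true
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(err) <= 3 * mc_se

    def test_posterior_finite_and_normalized(self, em_inputs):
        split, old, _, K_hat, alphas = em_inputs
        new, _ = refit_with_added(split, [1])
        res = em_attack(K_hat, old, new, alphas)
        pi = res.posteriors
        assert np.all(np.isfinite(pi)) and np.all((pi >= 0) & (pi <= 1))
        assert pi[-1, 0] == 1.0   # intercept prior is 1


class TestGibbsConditional:
    def test_m1_reduces_to_em_responsibility(self):
        x_i, alpha, C, s2 = 0.33, 0.6, np.array([0.4]), 0.01
        p = gibbs_conditional(x_i, alpha, C, np.zeros(1), 0, s2)
        num = alpha * norm.pdf(x_i, C[0], np.sqrt(s2))
        den = num + (1 - alpha) * norm.pdf(x_i, 0.0, np.sqrt(s2))
        assert np.isclose(p, num / den, atol=1e-12)

    @pytest.mark.parametrize("alpha,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_priors(self, alpha, expected):
        assert gibbs_conditional(0.2, alpha, np.array([0.4]), np.zeros(1), 0, 0.01) == expected

    def test_agrees_with_exhaustive_joint_posterior_m3(self):
        """Enumerate all 2^3 states at one site; the conditional from the joint
        posterior must match the closed form to 1e-10."""
        rng = np.random.default_rng(5)
        C = np.array([0.2, 0.5, 0.9])
        alphas = np.array([0.3, 0.6, 0.45])
        s2 = 0.02
        x_i = 0.77
        states = np.array(list(itertools.product((0, 1), repeat=3)), dtype=float)
        prior = np.prod(np.where(states == 1, alphas, 1 - alphas), axis=1)
        lik = norm.pdf(x_i, states @ C, np.sqrt(s2))
        joint = prior * lik
        for j in range(3):
            for z_fixed in itertools.product((0, 1), repeat=2):
                z = np.zeros(3)
                others = [k for k in range(3) if k != j]
                z[others] = z_fixed
                # conditional from the enumerated joint
                sel1 = np.all(states[:, others] == z_fixed, axis=1) & (states[:, j] == 1)
                sel0 = np.all(states[:, others] == z_fixed, axis=1) & (states[:, j] == 0)
                oracle = joint[sel1].sum() / (joint[sel1].sum() + joint[sel0].sum())
                z[j] = 1  # value at j is irrelevant to the conditional
                p = gibbs_conditional(x_i, alphas[j], C, z, j, s2)
                assert abs(p - oracle) < 1e-10


class TestSemMultiple:
    def test_exact_K_noiseless_limit_recovers_truth(self, em_inputs):
        split, old, K, _, alphas = em_inputs
        new, G_add = refit_with_added(split, [0, 1, 2])
        res = sem_attack(K, old, new, alphas, 3, SEMConfig(seed=1, **FAST_SEM))
        assert accuracy(res.genotypes, G_add) == 1.0

    def test_planted_constants_recovered(self):
        """x = Z C + noise with planted C=(0.2,0.5,0.9): averaged estimates land
        within 3 MC SE componentwise."""
        C_true = np.array([0.2, 0.5, 0.9])
        sigma, N = 0.02, 200
        rng = np.random.default_rng(7)
        ests = []
        for r in range(12):
            Z = (rng.random((N + 1, 3)) < 0.5).astype(float)
            Z[-1] = 1.0
            x = Z @ C_true + rng.normal(0, sigma, N + 1)
            d = DVector(x, 3, [f"s{i}" for i in range(N)])
            res = sem_multiple(d, 3, np.full(N, 0.5), SEMConfig(seed=100 + r, **FAST_SEM))
            ests.append(res.C.C_values)
        ests = np.array(ests)
        err = ests.mean(axis=0) - C_true
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert np.all(np.abs(err) <= 3 * np.maximum(mc_se, 1e-4))

    def test_averaging_window_shrinks_estimator_variance(self):
        """Longer post-burn-in averaging gives a lower-variance C estimate."""
        C_true = np.array([0.3, 0.8])
        N = 120
        rng = np.random.default_rng(3)
        Z = (rng.random((N + 1, 2)) < 0.5).astype(float)
        Z[-1] = 1.0
        x = Z @ C_true + rng.normal(0, 0.05, N + 1)
        d = DVector(x, 2, [f"s{i}" for i in range(N)])
        spreads = {}
        for window in (10, 200):
            runs = [sem_multiple(d, 2, np.full(N, 0.5),
                                 SEMConfig(seed=s, max_iter=300, burn_in=50,
                                           averaging_window=window)).C.C_values
                    for s in range(8)]
            spreads[window] = np.mean(np.var(np.array(runs), axis=0))
        assert spreads[200] < spreads[10]

    def test_m1_rejected(self):
        d = DVector(np.array([0.1, 0.2, 0.3]), 1, ["a", "b"])
        with pytest.raises(ValueError, match="m >= 2"):
            sem_multiple(d, 1, np.full(2, 0.5))


class TestAtypicalityRobustness:
    def test_em_advantage_grows_with_atypicality(self):
        """The EM attack degrades more slowly than the baseline as the added
        individual becomes atypical: corr(atypicality, em - baseline) > 0."""
        from grsleak.harness import atypicality as atyp
        records = []
        for s in range(6):
            cfg = SimConfig(seed=600 + s, n_private=400, n_added=0, n_public=300,
                            n_test=20, n_snps=80)
            split = make_split(cfg)
            old = fit_grs(split.private_base, split.private_phenotypes)
            K_hat = estimate_K(split.public, split.private_base.snp_ids)
            alphas = split.public.values.mean(axis=0)
            base = baseline_most_common(split.public, split.private_base.snp_ids)
            for t in range(20):
                new, G_add = refit_with_added(split, [t])
                res = em_attack(K_hat, old, new, alphas)
                records.append((
                    atyp(G_add.values[0], split.public, split.private_base.snp_ids),
                    accuracy(res.genotypes, G_add) - accuracy(base[None, :], G_add.values),
                ))
        a, adv = np.array(records).T
        assert np.corrcoef(a, adv)[0, 1] > 0


class TestCallGenotypes:
    def test_all_high_posteriors_call_ones(self):
        G = call_genotypes(np.full((4, 2), 0.99))
        assert np.all(G.values == 1) and G.values.shape == (2, 3)

    def test_tie_calls_one(self):
        G = call_genotypes(np.array([[0.5], [0.2], [1.0]]))
        assert G.values.tolist() == [[1, 0]]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            call_genotypes(np.array([[1.2], [1.0]]))
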