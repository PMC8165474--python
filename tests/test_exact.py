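import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grsleak import (
    CmSolution, DVector, DegenerateScalingError, GenotypeMatrix, NoisyDError,
    PhenotypeVector, ReconstructionInfeasibleError, SimConfig,
    SimplePreconditionError, accuracy, assign_genotypes, build_K, compute_d,
    fit_grs, identify_Cm_extended, identify_Cm_simple, make_split,
    reconstruct_single, release_pair, restrict_to_overlap, symmetric_difference_d,
)
from grsleak.exact import cluster_values
from grsleak.synthdata import BINARY

from conftest import refit_with_added


def make_d(C, presence, snp_ids=None):
    """Build a d vector from known constants and per-SNP carrier subsets."""
    C = np.asarray(C, dtype=float)
    vals = np.array([np.sum(C[list(s)]) for s in presence] + [C.sum()])
    ids = snp_ids or [f"s{i}" for i in range(len(presence))]
    return DVector(vals, len(C), ids)


@pytest.fixture(scope="module")
def pipeline(small_split):
    """Exact-K attack inputs on the shared small cohort."""
    old = fit_grs(small_split.private_base, small_split.private_phenotypes)
    K = build_K(small_split.private_base)
    return small_split, old, K


class TestComputeD:
    def test_identical_releases_give_zero(self, pipeline):
        split, old, K = pipeline
        same = fit_grs(split.private_base, split.private_phenotypes)
        same.cohort_size += 1   # declare one added; betas identical
        assert np.allclose(compute_d(K, old, same).values, 0.0)

    def test_single_added_takes_two_values(self, pipeline):
        split, old, K = pipeline
        new, _ = refit_with_added(split, [0])
        d = compute_d(K, old, new)
        _, reps = cluster_values(d.values)
        assert len(reps) <= 2
        assert d.m_declared == 1

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_at_most_2_to_m_distinct_values(self, pipeline, m):
        split, old, K = pipeline
        new, _ = refit_with_added(split, list(range(m)))
        d = compute_d(K, old, new)
        _, reps = cluster_values(d.values)
        assert len(reps) <= 2 ** m

    def test_snp_mismatch_rejected(self, pipeline):
        split, old, K = pipeline
        other = fit_grs(split.private_base.select_snps(split.private_base.snp_ids[:-1]),
                        split.private_phenotypes)
        other.cohort_size += 1
        with pytest.raises(ValueError, match="panel"):
            compute_d(K, old, other)


class TestReconstructSingle:
    def test_full_pipeline_recovers_added_genotype(self, pipeline):
        split, old, K = pipeline
        new, G_add = refit_with_added(split, [3])
        result = reconstruct_single(compute_d(K, old, new))
        assert accuracy(result.genotypes, G_add) == 1.0

    def test_handbuilt_d(self):
        d = DVector(0.37 * np.array([1, 0, 1, 1.0]), 1, ["a", "b", "c"])
        result = reconstruct_single(d)
        assert result.genotypes.values.tolist() == [[1, 0, 1]]
        assert np.isclose(result.C.C_values[0], 0.37)

    def test_all_zero_genotype(self):
        d = DVector(np.array([0, 0, 0, 0.5]), 1, ["a", "b", "c"])
        assert reconstruct_single(d).genotypes.values.tolist() == [[0, 0, 0]]

    def test_degenerate_scaling_error(self):
        with pytest.raises(DegenerateScalingError):
            reconstruct_single(DVector(np.array([0.0, 0.0, 0.0, 0.0]), 1, ["a", "b", "c"]))

    def test_noisy_d_redirects_to_em(self):
        d = DVector(np.array([0.5, 0.31, 0.02, 0.5]), 1, ["a", "b", "c"])
        with pytest.raises(NoisyDError, match="EM"):
            reconstruct_single(d)


class TestIdentifyCmSimple:
    def test_m1_returns_the_single_value(self):
        d = make_d(np.array([0.4]), [(), (0,), (0,), ()])
        sol = identify_Cm_simple(d, 1)
        assert np.allclose(sol.C_values, [0.4])

    def test_recovers_planted_constants(self):
        C = np.array([0.17, 0.45, 0.91])   # no subset-sum coincidences
        presence = [s for s in itertools.chain.from_iterable(
            itertools.combinations(range(3), r) for r in range(4))]
        sol = identify_Cm_simple(make_d(C, presence), 3)
        assert np.allclose(sol.C_values, C)
        # brute-force check: the subset sums of the result reproduce every d value
        sums = {round(sum(C[list(s)]), 9) for s in presence}
        recovered = {round(float(np.sum(sol.C_values[list(s)])), 9) for s in presence}
        assert sums == recovered

    def test_sum_coincidence_defeats_elimination_but_not_extended(self):
        """C=(0.2,0.5,0.9) has 0.9 = 0.2 + (0.2+0.5): the pairwise-sum
        elimination over-eliminates and signals fallback; the extended search
        still recovers the triple (unique by brute-force subset-sum check)."""
        C = np.array([0.2, 0.5, 0.9])
        presence = [s for s in itertools.chain.from_iterable(
            itertools.combinations(range(3), r) for r in range(4))]
        d = make_d(C, presence)
        with pytest.raises(SimplePreconditionError):
            identify_Cm_simple(d, 3)
        sol = identify_Cm_extended(d, 3, snp_freqs=np.full(len(presence), 0.5))
        assert np.allclose(sol.C_values, C, atol=1e-9)

    def test_missing_combination_signals_fallback(self):
        C = np.array([0.2, 0.5, 0.9])
        presence = [(), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]  # no lone 0
        with pytest.raises(SimplePreconditionError):
            identify_Cm_simple(make_d(C, presence), 3)

    def test_exact_K_m3_pipeline(self, pipeline):
        split, old, K = pipeline
        new, G_add = refit_with_added(split, [0, 1, 2])
        d = compute_d(K, old, new)
        sol = identify_Cm_simple(d, 3)
        assert np.isclose(sol.C_values.sum(), d.intercept_value, rtol=1e-8)
        result = assign_genotypes(d, sol)
        assert accuracy(result.genotypes, G_add) == 1.0


class TestIdentifyCmExtended:
    def test_recovers_constant_with_no_private_snp(self):
        """Individual 0 never appears alone; a pairwise difference exposes C_0."""
        C = np.array([0.2, 0.5, 0.9])
        presence = [(), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)] * 3
        freqs = np.full(len(presence), 0.5)
        d = make_d(C, presence)
        sol = identify_Cm_extended(d, 3, snp_freqs=freqs)
        assert np.allclose(sol.C_values, C, atol=1e-9)
        # forward oracle: regenerating d from the recovered assignment matches
        result = assign_genotypes(d, sol)
        regen = result.assignment @ sol.C_values
        assert np.max(np.abs(regen - d.values)) < 1e-10

    def test_agrees_with_simple_when_precondition_holds(self):
        C = np.array([0.15, 0.4])
        presence = [(), (0,), (1,), (0, 1), (0,), (1,)]
        d = make_d(C, presence)
        simple = identify_Cm_simple(d, 2)
        extended = identify_Cm_extended(d, 2)
        assert np.allclose(simple.C_values, extended.C_values)

    def test_sum_equals_intercept(self):
        C = np.array([0.3, 0.7, 1.1])
        presence = [s for s in itertools.chain.from_iterable(
            itertools.combinations(range(3), r) for r in range(4))]
        d = make_d(C, presence)
        sol = identify_Cm_extended(d, 3)
        assert np.isclose(sol.C_values.sum(), d.intercept_value, rtol=1e-8)

    def test_infeasible_when_snps_fewer_than_2_to_m(self):
        d = DVector(np.arange(1.0, 7.0), 5, [f"s{i}" for i in range(5)])
        with pytest.raises(ReconstructionInfeasibleError):
            identify_Cm_extended(d, 5)


class TestAssignGenotypes:
    def test_zero_entry_means_nobody_carries(self):
        C = np.array([0.2, 0.5])
        d = make_d(C, [(), (0,), (1,), (0, 1)])
        result = assign_genotypes(d, CmSolution(C))
        assert result.genotypes.values[:, 0].tolist() == [0, 0]

    def test_forward_reconstruction_oracle(self, pipeline):
        split, old, K = pipeline
        new, _ = refit_with_added(split, [4, 5, 6])
        d = compute_d(K, old, new)
        try:
            sol = identify_Cm_simple(d, 3)
        except SimplePreconditionError:   # a presence-combination is missing
            sol = identify_Cm_extended(d, 3)
        result = assign_genotypes(d, sol)
        regen = result.assignment @ sol.C_values
        assert np.max(np.abs(regen - d.values)) < 1e-6 * np.max(np.abs(d.values))

    def test_unmatched_entry_raises_noisy(self):
        d = DVector(np.array([0.1, 0.33, 0.5]), 2, ["a", "b"])
        with pytest.raises(NoisyDError):
            assign_genotypes(d, CmSolution(np.array([0.2, 0.3])))


class TestScaleInvariance:
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rescaling_y_rescales_C_not_genotypes(self, scale):
        C = np.array([0.17, 0.45, 0.91])
        presence = [s for s in itertools.chain.from_iterable(
            itertools.combinations(range(3), r) for r in range(4))]
        d = make_d(C, presence)
        d_scaled = DVector(d.values * scale, 3, d.snp_ids)
        a = assign_genotypes(d, identify_Cm_simple(d, 3))
        b = assign_genotypes(d_scaled, identify_Cm_simple(d_scaled, 3))
        assert np.array_equal(a.genotypes.values, b.genotypes.values)
        assert np.allclose(b.C.C_values, scale * a.C.C_values)


class TestRoundTripProperty:
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_synthetic_d_round_trip_up_to_permutation(self, seed, m):
        """Random constants + random carriers containing all 2^m combinations
        are always recovered exactly."""
        rng = np.random.default_rng(seed)
        C = np.sort(rng.uniform(0.1, 1.0, m))
        all_subsets = [s for r in range(m + 1) for s in itertools.combinations(range(m), r)]
        n_extra = 8 * 2 ** m
        presence = all_subsets + [tuple(np.nonzero(rng.random(m) < 0.5)[0])
                                  for _ in range(n_extra)]
        d = make_d(C, presence)
        truth = np.array([[int(j in s) for s in presence] for j in range(m)])
        if m == 1:
            result = reconstruct_single(d)
        else:
            result = assign_genotypes(d, identify_Cm_simple(d, m))
        assert accuracy(result.genotypes.values, truth) == 1.0


class TestOverlapAttack:
    def test_identical_panels_reduce_to_compute_d(self, pipeline):
        split, old, K = pipeline
        new, _ = refit_with_added(split, [0])
        d_ref = compute_d(K, old, new)
        d_overlap = restrict_to_overlap(old, new, K)
        assert np.allclose(d_overlap.values, d_ref.values, atol=1e-12)

    def test_partial_overlap_recovers_shared_snps_exactly(self):
        cfg = SimConfig(seed=31, n_private=400, n_added=0, n_public=50,
                        n_test=5, n_snps=120)
        split = make_split(cfg)
        panel1 = split.private_base.snp_ids[:90]
        panel2 = split.private_base.snp_ids[30:120]
        G1 = split.private_base.select_snps(panel1)
        old = fit_grs(G1, split.private_phenotypes)
        K1 = build_K(G1)
        K2 = build_K(split.private_base.select_snps(panel2))
        G_add = split.test_pool.take([0])
        joint = GenotypeMatrix(
            np.vstack([split.private_base.select_snps(panel2).values,
                       G_add.select_snps(panel2).values]),
            panel2,
            split.private_base.individual_ids + G_add.individual_ids, BINARY)
        y2 = PhenotypeVector(
            np.concatenate([split.private_phenotypes.values,
                            split.test_phenotypes.take([0]).values]),
            "trait", joint.individual_ids)
        new = fit_grs(joint, y2)
        d = restrict_to_overlap(old, new, K1, K2)
        assert len(d.snp_ids) == 60
        result = reconstruct_single(d)
        truth = G_add.select_snps(d.snp_ids)
        assert accuracy(result.genotypes, truth) == 1.0
        # recovered C is consistent with its defining residual
        C_true = (split.test_phenotypes.take([0]).values[0]
                  - np.append(G_add.select_snps(panel2).values[0], 1.0) @ new.beta) \
            / split.private_base.n_individuals
        assert np.isclose(result.C.C_values[0], C_true, rtol=1e-6)

    def test_empty_intersection_rejected(self, pipeline):
        split, old, K = pipeline
        other_ids = [f"other_{i}" for i in range(3)]
        other = fit_grs(
            GenotypeMatrix(split.private_base.values[:, :3], other_ids,
                           split.private_base.individual_ids, BINARY),
            split.private_phenotypes)
        K_other = build_K(GenotypeMatrix(split.private_base.values[:, :3], other_ids,
                                         split.private_base.individual_ids, BINARY))
        with pytest.raises(ValueError, match="share no SNPs"):
            restrict_to_overlap(old, other, K, K_other)


class TestSymmetricDifference:
    def test_one_sided_reduces_to_single_reconstruction(self, small_split):
        old = fit_grs(small_split.private_base, small_split.private_phenotypes)
        K = build_K(small_split.private_base)
        new, G_add = refit_with_added(small_split, [7])
        d = symmetric_difference_d(K, new, old, a=1, b=0)
        result = reconstruct_single(d)
        assert accuracy(result.genotypes, G_add) == 1.0

    def test_added_and_removed_both_recovered_with_signed_constants(self, small_split):
        split = small_split
        M = split.private_base.n_individuals
        K = build_K(split.private_base)
        rel_A, G_a = refit_with_added(split, [0])
        rel_B, G_b = refit_with_added(split, [1])
        d = symmetric_difference_d(K, rel_A, rel_B, a=1, b=1)
        sol = identify_Cm_simple(d, 2)
        result = assign_genotypes(d, sol)
        truth = np.vstack([G_a.values, G_b.values])
        assert accuracy(result.genotypes.values, truth) == 1.0
        # constants carry the signed residuals of the two studies
        r_a = (split.test_phenotypes.values[0]
               - np.append(G_a.values[0], 1.0) @ rel_A.beta) / M
        r_b = -(split.test_phenotypes.values[1]
                - np.append(G_b.values[0], 1.0) @ rel_B.beta) / M
        assert np.allclose(sol.C_values, np.sort([r_a, r_b]), rtol=1e-6)
        assert np.isclose(d.intercept_value, sol.C_values.sum(), rtol=1e-6)

    def test_zero_zero_with_difference_is_inconsistent(self, small_split):
        with pytest.raises(ValueError):
            old = fit_grs(small_split.private_base, small_split.private_phenotypes)
            K = build_K(small_split.private_base)
            symmetric_difference_d(K, old, old, a=0, b=0)
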