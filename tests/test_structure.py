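import itertools

import numpy as np
import pytest

from contactzone import (
    Genotypes,
    McmcConfig,
    admixture_mcmc,
    align_runs,
    allele_freq_pca,
    allele_frequency_table,
    bonferroni_threshold,
    cline_center,
    hard_assignments,
    hwe_test,
    ld_test,
    lnpd_from_trace,
    select_k,
    two_population_genotypes,
)
from conftest import make_genotypes

FAST = McmcConfig(burnin=1000, iters=4000, thin=5)


class TestLnpd:
    def test_constant_trace(self):
        assert lnpd_from_trace([-5.0, -5.0, -5.0]) == -5.0

    def test_hand_arithmetic(self):
        # mean 1, sample variance 2 (n-1 denominator) -> 1 - 1 = 0
        assert lnpd_from_trace([0.0, 2.0]) == pytest.approx(0.0)

    def test_shift_equivariance(self):
        trace = np.array([-10.0, -12.0, -9.5, -11.0])
        assert lnpd_from_trace(trace + 7.0) == pytest.approx(
            lnpd_from_trace(trace) + 7.0
        )

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            lnpd_from_trace([])


class TestAdmixtureMcmc:
    def test_k1_memberships_exact(self):
        gt, _ = two_population_genotypes(0.2, n_per_pop=10, n_loci=4, seed=0)
        est = admixture_mcmc(gt, 1, FAST, seed=1)
        assert est.Q.shape == (20, 1)
        np.testing.assert_array_equal(est.Q, np.ones((20, 1)))

    def test_simplex_invariants(self):
        gt, _ = two_population_genotypes(0.2, n_per_pop=15, n_loci=5, seed=2)
        est = admixture_mcmc(gt, 3, FAST, seed=3)
        np.testing.assert_allclose(est.Q.sum(axis=1), 1.0, atol=1e-9)
        for k in range(3):
            for l, codes in enumerate(est.allele_codes):
                np.testing.assert_allclose(
                    est.P[k, l, : len(codes)].sum(), 1.0, atol=1e-9
                )
        assert np.isfinite(est.lnpd)

    def test_fixed_populations_recover_truth(self):
        # two populations of 50 fixed for different alleles at all 9 loci
        gt = make_genotypes({
            "A": [[(1, 1)] * 9] * 50,
            "B": [[(2, 2)] * 9] * 50,
        })
        est = admixture_mcmc(gt, 2, McmcConfig(burnin=2000, iters=8000),
                             seed=4)
        q_true = np.array([1.0] * 50 + [0.0] * 50)
        q = est.Q[:, 0]
        if np.corrcoef(q, q_true)[0, 1] < 0:
            q = est.Q[:, 1]
        assert np.mean(np.abs(q - q_true)) < 0.05

    def test_f1_individual_is_intermediate(self):
        rows_a = [[(1, 1)] * 9] * 50
        rows_b = [[(2, 2)] * 9] * 50
        gt = make_genotypes({
            "A": rows_a, "B": rows_b, "F1": [[(1, 2)] * 9],
        })
        est = admixture_mcmc(gt, 2, McmcConfig(burnin=2000, iters=8000),
                             seed=5)
        q_f1 = est.Q[-1, 0]
        assert 0.35 <= q_f1 <= 0.65

    def test_exchangeability_under_individual_permutation(self):
        gt, _ = two_population_genotypes(0.3, n_per_pop=20, n_loci=6, seed=6)
        cfg = McmcConfig(burnin=2000, iters=8000)
        est = admixture_mcmc(gt, 2, cfg, seed=7)
        perm = np.random.default_rng(0).permutation(gt.n_individuals)
        gt_perm = gt.subset(perm.tolist())
        est_perm = admixture_mcmc(gt_perm, 2, cfg, seed=8)
        aligned, _, _ = align_runs([est.Q[perm], est_perm.Q])
        # Monte-Carlo tolerance on posterior means
        assert np.abs(aligned[0] - aligned[1]).mean() < 0.02

    def test_k_larger_than_sample_rejected(self):
        gt, _ = two_population_genotypes(0.2, n_per_pop=2, n_loci=3, seed=0)
        with pytest.raises(ValueError, match="K exceeds"):
            admixture_mcmc(gt, 5, FAST, seed=0)


class TestSelectK:
    def _runs(self, lnpds: dict[int, list[float]]):
        class Stub:
            def __init__(self, v):
                self.lnpd = v
        return {k: [Stub(v) for v in vals] for k, vals in lnpds.items()}

    def test_clear_winner(self):
        sel = select_k(self._runs({1: [-100.0, -100.0], 2: [-90.0, -91.0]}))
        assert sel.chosen_k == 2
        assert not sel.tie

    def test_tie_prefers_smaller_k(self):
        sel = select_k(self._runs({1: [-92.0, -88.0], 2: [-92.1, -88.1]}))
        assert sel.chosen_k == 1
        assert sel.tie

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_k({})


class TestAlignRuns:
    def test_column_swap_restored(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(3), size=30)
        aligned, mean_q, perms = align_runs([Q, Q[:, [2, 0, 1]]])
        np.testing.assert_allclose(aligned[1], Q, atol=1e-12)
        np.testing.assert_allclose(mean_q, Q, atol=1e-12)

    def test_identical_runs_mean_is_each(self):
        rng = np.random.default_rng(1)
        Q = rng.dirichlet(np.ones(2), size=10)
        _, mean_q, _ = align_runs([Q, Q, Q])
        np.testing.assert_allclose(mean_q, Q, atol=1e-12)

    def test_at_least_as_good_as_every_permutation(self):
        # exhaustive oracle at K = 3: the chosen permutation attains the
        # maximal summed column correlation
        rng = np.random.default_rng(2)
        ref = rng.dirichlet(np.ones(3), size=40)
        other = rng.dirichlet(np.ones(3), size=40)
        aligned, _, perms = align_runs([ref, other])

        def score(Q):
            return sum(
                np.corrcoef(ref[:, j], Q[:, j])[0, 1] for j in range(3)
            )
        best = max(score(other[:, list(p)])
                   for p in itertools.permutations(range(3)))
        assert score(aligned[1]) == pytest.approx(best, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_runs([np.ones((3, 2)) / 2, np.ones((4, 2)) / 2])


def test_hard_assignment_tie_goes_to_lower_cluster():
    q = np.array([[0.5, 0.5], [0.2, 0.8]])
    np.testing.assert_array_equal(hard_assignments(q), [0, 1])


def test_cline_center_interpolation():
    assert cline_center([1, 2, 3, 4], [1.0, 0.9, 0.1, 0.0]) == pytest.approx(2.5)
    assert cline_center([1, 2, 3], [0.9, 0.8, 0.7]) is None


class TestAlleleFreqPca:
    def test_identical_sites_zero_scores(self):
        gt = make_genotypes({
            "s1": [[(1, 2)], [(1, 2)]],
            "s2": [[(1, 2)], [(1, 2)]],
            "s3": [[(1, 2)], [(1, 2)]],
        })
        scores = allele_freq_pca(gt)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_two_blocks_separate_with_zero_within_spread(self):
        gt = make_genotypes({
            "s1": [[(1, 1)]] * 3, "s2": [[(1, 1)]] * 3,
            "s3": [[(2, 2)]] * 3, "s4": [[(2, 2)]] * 3,
        })
        scores = allele_freq_pca(gt)
        assert scores["s1"] == pytest.approx(scores["s2"], abs=1e-12)
        assert scores["s3"] == pytest.approx(scores["s4"], abs=1e-12)
        assert scores["s3"] > scores["s1"]  # oriented with position

    def test_frequencies_sum_to_one_within_locus(self):
        gt, _ = two_population_genotypes(0.3, n_per_pop=20, n_loci=4, seed=3)
        table = allele_frequency_table(gt)
        sums = table.T.groupby(level="locus").sum().T
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)


class TestHweTest:
    def test_exact_proportions_give_large_p(self):
        calls = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
        gt = make_genotypes({"s1": calls})
        p, mono = hwe_test(gt, "s1", "loc1", n_perm=2000, seed=0)
        assert not mono
        assert p > 0.5

    def test_all_homozygotes_rejected(self):
        calls = [[(1, 1)]] * 25 + [[(2, 2)]] * 25
        gt = make_genotypes({"s1": calls})
        p, mono = hwe_test(gt, "s1", "loc1", n_perm=2000, seed=0)
        assert p < 0.001

    def test_monomorphic_flag(self):
        gt = make_genotypes({"s1": [[(1, 1)]] * 10})
        p, mono = hwe_test(gt, "s1", "loc1", n_perm=100, seed=0)
        assert p == 1.0 and mono


class TestLdTest:
    def test_duplicated_locus_maximal_association(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(60):
            a = sorted(rng.integers(1, 4, size=2))
            rows.append([tuple(a), tuple(a)])
        gt = make_genotypes({"s1": rows})
        p, mono = ld_test(gt, "s1", "loc1", "loc2", n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_monomorphic_flag(self):
        gt = make_genotypes({"s1": [[(1, 1), (1, 2)]] * 10})
        p, mono = ld_test(gt, "s1", "loc1", "loc2", n_perm=100, seed=0)
        assert p == 1.0 and mono


def test_bonferroni_arithmetic():
    # raw p = 0.002 among 36 locus pairs: significant at 0.05 family level
    assert bonferroni_threshold(0.05, 36) == pytest.approx(0.05 / 36)
    assert 0.002 > bonferroni_threshold(0.05, 36)
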