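import itertools

import numpy as np
import pytest

from contactzone import (
    MISSING,
    amova,
    pairwise_fst,
    recode_max,
    standardized_fst,
    two_population_genotypes,
)
from conftest import make_genotypes


# ---------------------------------------------------------------------------
# Independent brute-force AMOVA oracle: full pairwise mismatch-distance
# matrices per locus, sums of squares straight from the distances.

def amova_brute(genotypes, pop_of, group_of):
    pops = sorted(set(pop_of.values()))
    groups = sorted(set(group_of[p] for p in pops))
    group_index = np.array([groups.index(group_of[p]) for p in pops])
    return _brute_components(genotypes, pops, pop_of, group_index,
                             len(groups))


def _brute_components(genotypes, pops, pop_of, group_index, n_groups):
    sa = sb = sc = 0.0
    ss_tot_all = ss_ag_all = ss_ap_all = ss_wp_all = 0.0
    for l in range(genotypes.n_loci):
        copies, pop_idx = [], []
        for i, ind in enumerate(genotypes.individual_ids):
            for s in range(2):
                v = genotypes.calls[i, l, s]
                if v != MISSING:
                    copies.append(int(v))
                    pop_idx.append(pops.index(pop_of[ind]))
        copies = np.array(copies)
        pop_idx = np.array(pop_idx)
        N = len(copies)
        D = (copies[:, None] != copies[None, :]).astype(float)

        def ss_of(mask):
            n = int(mask.sum())
            if n == 0:
                return 0.0
            sub = D[np.ix_(mask, mask)]
            return sub[np.triu_indices(n, 1)].sum() / n

        ss_tot = ss_of(np.ones(N, dtype=bool))
        ss_wp = sum(ss_of(pop_idx == p) for p in range(len(pops)))
        ss_wg = sum(
            ss_of(np.isin(pop_idx, np.nonzero(group_index == g)[0]))
            for g in range(n_groups)
        )
        ss_ag = ss_tot - ss_wg
        ss_ap = ss_wg - ss_wp
        ss_tot_all += ss_tot
        ss_ag_all += ss_ag
        ss_ap_all += ss_ap
        ss_wp_all += ss_wp

        P = len(pops)
        n_p = np.array([(pop_idx == p).sum() for p in range(P)], dtype=float)
        n_g = np.array([
            n_p[group_index == g].sum() for g in range(n_groups)
        ])
        df_ag, df_ap, df_wp = n_groups - 1, P - n_groups, N - P
        sigma_c = ss_wp / df_wp
        s_npg = sum((n_p[group_index == g] ** 2).sum() / n_g[g]
                    for g in range(n_groups))
        n1 = (N - s_npg) / df_ap if df_ap > 0 else 0.0
        n2 = (s_npg - (n_p ** 2).sum() / N) / df_ag
        n3 = (N - (n_g ** 2).sum() / N) / df_ag
        sigma_b = ((ss_ap / df_ap) - sigma_c) / n1 if df_ap > 0 and n1 > 0 else 0.0
        sigma_a = ((ss_ag / df_ag) - sigma_c - n2 * sigma_b) / n3
        sa, sb, sc = sa + sigma_a, sb + sigma_b, sc + sigma_c
    return (sa, sb, sc), (ss_tot_all, ss_ag_all, ss_ap_all, ss_wp_all)


def exhaustive_phi_ct_p(genotypes, pop_of, group_of):
    """Exact permutation p over all distinct assignments of populations to
    groups with group sizes preserved."""
    pops = sorted(set(pop_of.values()))
    groups = sorted(set(group_of[p] for p in pops))
    base = np.array([groups.index(group_of[p]) for p in pops])

    def phi_ct_of(gi):
        (sa, sb, sc), _ = _brute_components(
            genotypes, pops, pop_of, np.array(gi), len(groups)
        )
        return sa / (sa + sb + sc)

    obs = phi_ct_of(base)
    arrangements = sorted(set(itertools.permutations(base.tolist())))
    hits = sum(phi_ct_of(g) >= obs - 1e-12 for g in arrangements)
    return hits / len(arrangements), obs


GROUPS_3POP = {"p1": "g1", "p2": "g2", "p3": "g2"}


class TestAmova:
    def test_matches_brute_force_components(self, toy_three_pop):
        res = amova(toy_three_pop, toy_three_pop.site_of, GROUPS_3POP,
                    n_perm=99, seed=0)
        (sa, sb, sc), (ss_tot, ss_ag, ss_ap, ss_wp) = amova_brute(
            toy_three_pop, toy_three_pop.site_of, GROUPS_3POP
        )
        assert res.sigma_among_groups == pytest.approx(sa, abs=1e-10)
        assert res.sigma_among_pops == pytest.approx(sb, abs=1e-10)
        assert res.sigma_within == pytest.approx(sc, abs=1e-10)
        # sums of squares are additive
        assert ss_tot == pytest.approx(ss_ag + ss_ap + ss_wp, abs=1e-9)

    def test_fixed_difference_phi_st_is_one(self, fixed_difference_pops):
        # with zero within-population variance all variance is hierarchical
        group_of = {"A": "gA", "B": "gB"}
        res = amova(fixed_difference_pops, fixed_difference_pops.site_of,
                    group_of, n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0, abs=1e-12)

    def test_single_group_rejected(self, toy_three_pop):
        with pytest.raises(ValueError, match="group"):
            amova(toy_three_pop, toy_three_pop.site_of,
                  {"p1": "g", "p2": "g", "p3": "g"}, n_perm=9)

    def test_zero_variance_rejected(self):
        gt = make_genotypes({
            "p1": [[(1, 1)]] * 3, "p2": [[(1, 1)]] * 3,
        })
        with pytest.raises(ValueError, match="variance"):
            amova(gt, gt.site_of, {"p1": "a", "p2": "b"}, n_perm=9)

    def test_null_phi_ct_near_zero(self):
        rng = np.random.default_rng(0)
        phis = []
        for rep in range(10):
            pops = {}
            for p in range(4):
                pops[f"p{p+1}"] = [
                    [tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(2)]
                    for _ in range(10)
                ]
            gt = make_genotypes(pops)
            res = amova(gt, gt.site_of,
                        {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"},
                        n_perm=199, seed=rep)
            phis.append(res.phi_ct)
        assert abs(np.mean(phis)) < 0.05


class TestPairwiseFst:
    def test_identical_populations_theta_nonpositive(self):
        rows = [[(1, 2), (3, 3)], [(2, 2), (3, 4)], [(1, 1), (4, 4)],
                [(1, 2), (3, 4)]]
        gt = make_genotypes({"A": rows, "B": [list(r) for r in rows]})
        assert pairwise_fst(gt, "A", "B") <= 0.0

    def test_fixed_difference_theta_is_one(self, fixed_difference_pops):
        assert pairwise_fst(fixed_difference_pops, "A", "B") == pytest.approx(1.0)

    def test_estimator_consistency_under_generating_model(self):
        thetas = []
        for seed in range(50):
            gt, _ = two_population_genotypes(F=0.1, n_per_pop=48, seed=seed)
            thetas.append(pairwise_fst(gt, "pop1", "pop2"))
        assert abs(np.mean(thetas) - 0.1) < 0.02


class TestRecodeMax:
    def test_population_allele_spaces_disjoint(self, toy_three_pop):
        rec = recode_max(toy_three_pop)
        for l in range(rec.n_loci):
            per_pop = []
            for pop in ("p1", "p2", "p3"):
                rows = rec.individuals_at(pop)
                a = rec.calls[rows, l, :]
                per_pop.append(set(a[a != MISSING].tolist()))
            for s1, s2 in itertools.combinations(per_pop, 2):
                assert not (s1 & s2)
            # distinct alleles = sum of within-population distinct alleles
            orig_counts = sum(
                len(set(
                    toy_three_pop.calls[toy_three_pop.individuals_at(p), l, :]
                    .ravel().tolist()
                ) - {MISSING})
                for p in ("p1", "p2", "p3")
            )
            assert sum(len(s) for s in per_pop) == orig_counts

    def test_heterozygosity_preserved(self, toy_three_pop):
        rec = recode_max(toy_three_pop)
        het_before = toy_three_pop.calls[:, :, 0] != toy_three_pop.calls[:, :, 1]
        het_after = rec.calls[:, :, 0] != rec.calls[:, :, 1]
        np.testing.assert_array_equal(het_before, het_after)

    def test_relabeling_invariance_of_fst_std(self, toy_three_pop):
        base = standardized_fst(toy_three_pop, "p1", "p2")
        relabeled = toy_three_pop.subset(range(toy_three_pop.n_individuals))
        relabeled.calls[relabeled.calls != MISSING] = \
            relabeled.calls[relabeled.calls != MISSING] * 7 + 3
        other = standardized_fst(relabeled, "p1", "p2")
        assert other.fst == pytest.approx(base.fst, abs=1e-12)
        assert other.fst_std == pytest.approx(base.fst_std, abs=1e-12)


class TestStandardizedFst:
    def test_fully_differentiated_is_one(self, fixed_difference_pops):
        pair = standardized_fst(fixed_difference_pops, "A", "B")
        assert pair.fst_std == pytest.approx(1.0, abs=1e-9)

    def test_standardized_at_least_raw(self):
        for seed in range(5):
            gt, _ = two_population_genotypes(F=0.15, n_per_pop=20,
                                             n_loci=5, seed=seed)
            pair = standardized_fst(gt, "pop1", "pop2")
            assert pair.fst_std >= pair.fst - 1e-12
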