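"""Hierarchical AMOVA and pairwise F_ST with maximal-differentiation
standardization.

AMOVA partitions molecular variance among groups of populations, among
populations within groups, and within populations, using the mismatch
(infinite-allele) distance between allele copies; significance of the
among-group component (Phi_CT) is assessed by permuting whole populations
among groups.  Pairwise differentiation uses the multilocus
Weir–Cockerham theta; its standardized form F_ST' divides theta by the
maximum value attainable given the observed within-population diversity,
obtained by recoding alleles so that no two populations share any allele.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, Genotypes, TransectDataset
from .phenotype import HabitatPartition
from .rflp import lineage_site_frequencies


@dataclass
class AmovaResult:
    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_phi_ct: float
    n_permutations: int
    grouping: str = ""

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.sigma_among_groups, self.sigma_among_pops,
                self.sigma_within)


@dataclass
class FstPair:
    pop_a: str
    pop_b: str
    fst: float
    fst_max: float | None
    fst_std: float | None
    negative: bool


def _pop_allele_counts(genotypes: Genotypes, pops: list[str],
                       pop_of: dict[str, str]) -> list[np.ndarray]:
    """Per-locus (n_pops, n_alleles) count matrices of called copies."""
    rows_of = {p: [] for p in pops}
    for i, ind in enumerate(genotypes.individual_ids):
        p = pop_of.get(ind)
        if p in rows_of:
            rows_of[p].append(i)
    out = []
    for l in range(genotypes.n_loci):
        col = genotypes.calls[:, l, :]
        codes = np.unique(col[col != MISSING])
        lookup = {int(c): j for j, c in enumerate(codes)}
        C = np.zeros((len(pops), len(codes)))
        for pi, p in enumerate(pops):
            a = col[rows_of[p]]
            a = a[a != MISSING]
            for v in a:
                C[pi, lookup[int(v)]] += 1
        out.append(C)
    return out


def _ss_from_counts(counts: np.ndarray) -> float:
    """Sum of squared mismatch deviations within one set of allele copies,
    from its allele counts: SS = (n - sum c_a^2 / n) / 2."""
    n = counts.sum()
    if n == 0:
        return 0.0
    return float((n - (counts ** 2).sum() / n) / 2.0)


def _amova_components(locus_counts: list[np.ndarray],
                      group_index: np.ndarray, n_groups: int
                      ) -> tuple[float, float, float]:
    """Variance components summed over loci for one population grouping."""
    sa = sb = sc = 0.0
    P = locus_counts[0].shape[0]
    for C in locus_counts:
        n_p = C.sum(axis=1)                    # copies per population
        N = n_p.sum()
        if N == 0:
            continue
        ss_wp = sum(_ss_from_counts(C[p]) for p in range(P))
        group_counts = np.zeros((n_groups, C.shape[1]))
        np.add.at(group_counts, group_index, C)
        n_g = group_counts.sum(axis=1)
        ss_wg = sum(_ss_from_counts(group_counts[g]) for g in range(n_groups))
        ss_tot = _ss_from_counts(C.sum(axis=0))
        ss_ag = ss_tot - ss_wg
        ss_ap = ss_wg - ss_wp

        df_ag = n_groups - 1
        df_ap = P - n_groups
        df_wp = N - P
        if df_wp <= 0 or df_ap < 0 or df_ag <= 0:
            continue
        sigma_c = ss_wp / df_wp
        # unbalanced-design coefficients
        sum_np2_over_ng = sum(
            (n_p[group_index == g] ** 2).sum() / n_g[g]
            for g in range(n_groups) if n_g[g] > 0
        )
        n1 = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else 0.0
        n2 = (sum_np2_over_ng - (n_p ** 2).sum() / N) / df_ag
        n3 = (N - (n_g ** 2).sum() / N) / df_ag

        sigma_b = ((ss_ap / df_ap) - sigma_c) / n1 if df_ap > 0 and n1 > 0 else 0.0
        sigma_a = ((ss_ag / df_ag) - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
        sa += sigma_a
        sb += sigma_b
        sc += sigma_c
    return sa, sb, sc


def amova(genotypes: Genotypes, pop_of: dict[str, str],
          group_of: dict[str, str], n_perm: int = 9999, seed: int = 0
          ) -> AmovaResult:
    """Distance-based AMOVA on allele copies with mismatch distance.

    ``pop_of`` maps individual -> population; ``group_of`` maps population
    -> group.  Populations absent from ``group_of`` (e.g. sites whose modal
    lineage is tied) are excluded together with their individuals.  The
    Phi_CT p-value is the +1/+1-corrected proportion of permutations (whole
    populations shuffled among groups, group sizes in populations
    preserved) with Phi_CT at least the observed value.
    """
    pops = sorted(p for p in set(pop_of.values()) if p in group_of)
    if len(pops) < 2:
        raise ValueError("need >= 2 grouped populations")
    groups = sorted(set(group_of[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups (one group holds all populations)")
    group_lookup = {g: gi for gi, g in enumerate(groups)}
    group_index = np.array([group_lookup[group_of[p]] for p in pops])

    locus_counts = _pop_allele_counts(genotypes, pops, pop_of)
    total_ss = sum(_ss_from_counts(C.sum(axis=0)) for C in locus_counts)
    if total_ss <= 0:
        raise ValueError("total molecular variance is zero")

    sa, sb, sc = _amova_components(locus_counts, group_index, len(groups))
    total = sa + sb + sc
    phi_ct = sa / total
    phi_sc = sb / (sb + sc) if (sb + sc) != 0 else 0.0
    phi_st = (sa + sb) / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(group_index)
        a, b, c = _amova_components(locus_counts, perm, len(groups))
        tot = a + b + c
        if tot != 0 and a / tot >= phi_ct - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    return AmovaResult(
        sigma_among_groups=sa, sigma_among_pops=sb, sigma_within=sc,
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        p_phi_ct=p, n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# Weir–Cockerham theta

def pairwise_fst(genotypes: Genotypes, pop_a: str, pop_b: str,
                 pop_of: dict[str, str] | None = None) -> float:
    """Multilocus Weir–Cockerham theta between two populations.

    Variance components are summed over alleles and loci before the ratio;
    individuals with a missing copy at a locus are excluded at that locus.
    Returns the raw estimate (may be negative); nan when no shared
    polymorphic locus exists.
    """
    pop_of = pop_of or genotypes.site_of
    rows = {pop_a: [], pop_b: []}
    for i, ind in enumerate(genotypes.individual_ids):
        p = pop_of.get(ind)
        if p in rows:
            rows[p].append(i)
    if min(len(rows[pop_a]), len(rows[pop_b])) < 2:
        raise ValueError("both populations need >= 2 called individuals")
    r = 2
    num = den = 0.0
    informative = False
    for l in range(genotypes.n_loci):
        samples = []
        for p in (pop_a, pop_b):
            calls = genotypes.calls[rows[p], l, :]
            calls = calls[(calls != MISSING).all(axis=1)]
            samples.append(calls)
        n_i = np.array([len(s) for s in samples], dtype=float)
        if (n_i < 2).any():
            continue
        codes = np.unique(np.concatenate([s.ravel() for s in samples]))
        if len(codes) < 2:
            continue
        informative = True
        n_bar = n_i.mean()
        n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
        for allele in codes:
            p_i = np.array([
                (s == allele).sum() / (2 * n) for s, n in zip(samples, n_i)
            ])
            h_i = np.array([
                ((s == allele).sum(axis=1) == 1).mean() for s in samples
            ])
            p_bar = (n_i * p_i).sum() / (r * n_bar)
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / (r * n_bar)
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
                / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - s2 * (r - 1) / r
                - h_bar * (2 * n_bar - 1) / (4 * n_bar)
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    if not informative or den == 0:
        return float("nan")
    return float(num / den)


def recode_max(genotypes: Genotypes, pop_of: dict[str, str] | None = None
               ) -> Genotypes:
    """Recode alleles so no two populations share any allele at any locus.

    Within-population genotype structure (hence observed heterozygosity) is
    preserved exactly; between-population identity is destroyed, which
    drives theta to its maximum given the within-population diversity.
    """
    pop_of = pop_of or genotypes.site_of
    pops = sorted(set(pop_of.values()))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    pop_index = {p: k for k, p in enumerate(pops)}
    new_calls = genotypes.calls.copy()
    for l in range(genotypes.n_loci):
        col = genotypes.calls[:, l, :]
        codes = np.unique(col[col != MISSING])
        lookup = {int(c): j for j, c in enumerate(codes)}
        stride = len(codes)
        for i, ind in enumerate(genotypes.individual_ids):
            off = pop_index[pop_of[ind]] * stride
            for s in range(2):
                v = col[i, s]
                if v != MISSING:
                    new_calls[i, l, s] = 1 + off + lookup[int(v)]
    return Genotypes(
        individual_ids=list(genotypes.individual_ids),
        site_of=dict(genotypes.site_of),
        loci=list(genotypes.loci),
        calls=new_calls,
    )


def standardized_fst(genotypes: Genotypes, pop_a: str, pop_b: str,
                     pop_of: dict[str, str] | None = None) -> FstPair:
    """theta and its standardized form theta / theta_max for one pair.

    theta_max comes from recoding the two populations' alleles to be
    population-unique.  A negative raw theta is reported as is, with the
    standardized value truncated at 0.
    """
    pop_of = pop_of or genotypes.site_of
    sub_rows = [
        i for i, ind in enumerate(genotypes.individual_ids)
        if pop_of[ind] in (pop_a, pop_b)
    ]
    sub = genotypes.subset(sub_rows)
    sub_pop = {ind: pop_of[ind] for ind in sub.individual_ids}
    theta = pairwise_fst(sub, pop_a, pop_b, sub_pop)
    recoded = recode_max(sub, sub_pop)
    theta_max = pairwise_fst(recoded, pop_a, pop_b, sub_pop)
    if np.isnan(theta) or np.isnan(theta_max) or theta_max <= 0:
        return FstPair(pop_a, pop_b, theta, None, None, theta < 0)
    std = max(theta, 0.0) / theta_max
    return FstPair(pop_a, pop_b, theta, theta_max, std, theta < 0)


def mean_boundary_fst_std(dataset: TransectDataset, boundary: str = "lineage",
                          partition: HabitatPartition | None = None
                          ) -> tuple[float, pd.DataFrame]:
    """Mean standardized F_ST' over all site pairs crossing a boundary.

    ``boundary='lineage'`` splits sites by modal mtDNA lineage (exactly two
    modal labels required); ``boundary='habitat'`` uses the supplied
    :class:`HabitatPartition`.  Returns the cross-boundary mean and a pair
    table that also contains the within-block pairs (``cross`` False) as a
    control.
    """
    if boundary == "lineage":
        freqs = lineage_site_frequencies(dataset)
        blocks: dict[str, list[str]] = {}
        for site, row in freqs.iterrows():
            if row["empty"] or row["tie"]:
                continue
            blocks.setdefault(row["mode"], []).append(site)
        if len(blocks) != 2:
            raise ValueError(
                f"lineage boundary needs exactly 2 modal lineages, got {list(blocks)}"
            )
        block_a, block_b = blocks.values()
    elif boundary == "habitat":
        if partition is None or partition.no_ecotone:
            raise ValueError("habitat boundary requires an ecotone partition")
        labels = partition.labels
        block_a = [s for s in dataset.site_ids if labels.get(s) == "A"]
        block_b = [s for s in dataset.site_ids if labels.get(s) == "B"]
    else:
        raise ValueError("boundary must be 'lineage' or 'habitat'")
    if not block_a or not block_b:
        raise ValueError("a boundary block is empty")

    rows = []
    for a, b in itertools.combinations(block_a + block_b, 2):
        cross = (a in block_a) != (b in block_a)
        pair = standardized_fst(dataset.genotypes, a, b)
        rows.append({
            "site_a": a, "site_b": b, "cross": cross,
            "fst": pair.fst, "fst_max": pair.fst_max, "fst_std": pair.fst_std,
        })
    table = pd.DataFrame(rows)
    cross_vals = table.loc[table["cross"], "fst_std"].dropna()
    return float(cross_vals.mean()), table
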