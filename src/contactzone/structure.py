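"""Nuclear genetic structure: admixture-model Bayesian clustering,
model-size selection, replicate alignment, allele-frequency PCA and
HWE / linkage-disequilibrium quality checks.

The clustering model is the classic admixture model for unlinked
multiallelic loci: each individual carries a K-vector ``q`` of membership
proportions; each allele copy originates from cluster ``k`` with
probability ``q_k`` and is then drawn from that cluster's allele-frequency
vector at its locus.  Inference is by Gibbs sampling over the latent origin
of every allele copy, with Dirichlet conditional updates for cluster
frequencies ``P`` and memberships ``Q``, and a Metropolis random walk for
the symmetric Dirichlet parameter ``alpha`` of the membership prior.  Model
size K is chosen by the largest estimated model evidence
``lnPD = mean(lnL) - var(lnL)/2`` over replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .datamodel import MISSING, Genotypes


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Paper-scale runs use 100 000 burn-in / 400 000 iterations and 10
    replicates; the desk-scale defaults below (2 000 / 8 000, 3 replicates)
    are adequate for the simulated data sizes this package targets.
    """

    burnin: int = 2000
    iters: int = 8000
    n_replicates: int = 3
    k_range: tuple[int, ...] = (1, 2, 3)
    alpha_max: float = 10.0
    alpha_step_sd: float = 0.25
    lambda_: float = 1.0
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.burnin, self.iters, self.n_replicates, self.thin) <= 0:
            raise ValueError("all MCMC counts must be positive")
        if not all(1 <= k for k in self.k_range):
            raise ValueError("K range must be >= 1")


PAPER_SCALE = McmcConfig(burnin=100_000, iters=400_000, n_replicates=10,
                         k_range=tuple(range(1, 10)))


@dataclass
class AncestryEstimate:
    """Posterior summary of one MCMC run at fixed K."""

    K: int
    individual_ids: list[str]
    Q: np.ndarray                      # (n, K) posterior-mean memberships
    P: np.ndarray                      # (K, L, A_max) posterior-mean freqs
    allele_codes: list[np.ndarray]     # per locus, codes for P's allele axis
    alpha_mean: float
    lnpd: float
    loglik_mean: float
    loglik_var: float


@dataclass
class KSelection:
    per_k: pd.DataFrame            # index K, columns mean / sd / n_runs
    chosen_k: int
    tie: bool


def _encode(genotypes: Genotypes):
    """Flatten non-missing allele copies to index arrays."""
    L = genotypes.n_loci
    allele_codes = []
    G = np.full(genotypes.calls.shape, -1, dtype=np.int64)
    for l in range(L):
        col = genotypes.calls[:, l, :]
        codes = np.unique(col[col != MISSING])
        allele_codes.append(codes)
        lookup = {c: i for i, c in enumerate(codes.tolist())}
        for c, i in lookup.items():
            G[:, l, :][col == c] = i
    A_max = max((len(c) for c in allele_codes), default=0)
    mask = genotypes.calls != MISSING
    ind_idx, loc_idx, _ = np.nonzero(mask)
    allele_idx = G[mask]
    return ind_idx, loc_idx, allele_idx, allele_codes, A_max


def admixture_mcmc(genotypes: Genotypes, K: int, config: McmcConfig,
                   seed: int | None = None) -> AncestryEstimate:
    """One Gibbs-sampler run of the admixture model at fixed K.

    Missing allele copies contribute to no counts and no likelihood terms.
    Q and P are posterior means over thinned post-burn-in samples; the
    model evidence is ``mean - var/2`` of the complete-data log-likelihood
    trace at those samples.
    """
    if genotypes.n_individuals == 0:
        raise ValueError("empty genotype set")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > genotypes.n_individuals:
        raise ValueError("K exceeds number of individuals")
    for l in range(genotypes.n_loci):
        if not (genotypes.calls[:, l, :] != MISSING).any():
            raise ValueError(f"locus {genotypes.loci[l]} has no observed allele")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, L = genotypes.n_individuals, genotypes.n_loci
    ind_idx, loc_idx, allele_idx, allele_codes, A_max = _encode(genotypes)
    M = len(ind_idx)
    lam = config.lambda_

    valid = np.zeros((L, A_max), dtype=bool)
    for l, codes in enumerate(allele_codes):
        valid[l, : len(codes)] = True
    p_shape_base = np.where(valid, lam, 0.0)      # gamma(0) == 0 masks slots

    Q = np.full((n, K), 1.0 / K)
    P = rng.dirichlet(np.ones(A_max), size=(K, L))
    P = np.where(valid[None, :, :], P, 0.0)
    P /= P.sum(axis=2, keepdims=True)
    alpha = 1.0

    flat_pl = loc_idx * A_max + allele_idx        # per-copy column into (L*A)
    total = config.burnin + config.iters
    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    alpha_sum = 0.0
    loglik_trace: list[float] = []
    n_samples = 0

    for it in range(total):
        # P(z = k | ...) per copy
        Pflat = P.reshape(K, L * A_max)
        W = Q[ind_idx, :] * Pflat[:, flat_pl].T           # (M, K)
        if K == 1:
            Z = np.zeros(M, dtype=np.int64)
            Wsum = W[:, 0]
        else:
            cum = np.cumsum(W, axis=1)
            Wsum = cum[:, -1]
            u = rng.random(M) * Wsum
            Z = (u[:, None] > cum).sum(axis=1)

        # P | Z
        counts_p = np.bincount(
            Z * (L * A_max) + flat_pl, minlength=K * L * A_max
        ).reshape(K, L, A_max)
        g = rng.gamma(p_shape_base[None, :, :] + counts_p)
        P = g / g.sum(axis=2, keepdims=True)

        # Q | Z
        counts_q = np.bincount(ind_idx * K + Z, minlength=n * K).reshape(n, K)
        # floor guards against underflow to exactly 0 when alpha is tiny
        g = np.maximum(rng.gamma(alpha + counts_q), 1e-300)
        Q = g / g.sum(axis=1, keepdims=True)

        # alpha | Q (Metropolis random walk, uniform prior (0, alpha_max])
        if K > 1:
            prop = alpha + rng.normal(0.0, config.alpha_step_sd)
            if 0.0 < prop <= config.alpha_max:
                logQ = np.log(np.maximum(Q, 1e-300)).sum()
                cur = n * (gammaln(K * alpha) - K * gammaln(alpha)) \
                    + (alpha - 1.0) * logQ
                new = n * (gammaln(K * prop) - K * gammaln(prop)) \
                    + (prop - 1.0) * logQ
                if np.log(rng.random()) < new - cur:
                    alpha = prop

        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            Q_sum += Q
            P_sum += P
            alpha_sum += alpha
            Pflat = P.reshape(K, L * A_max)
            lik = (Q[ind_idx, :] * Pflat[:, flat_pl].T).sum(axis=1)
            loglik_trace.append(float(np.log(lik).sum()))
            n_samples += 1

    Q_mean = Q_sum / n_samples
    P_mean = P_sum / n_samples
    trace = np.asarray(loglik_trace)
    return AncestryEstimate(
        K=K,
        individual_ids=list(genotypes.individual_ids),
        Q=Q_mean,
        P=P_mean,
        allele_codes=allele_codes,
        alpha_mean=alpha_sum / n_samples,
        lnpd=lnpd_from_trace(trace),
        loglik_mean=float(trace.mean()),
        loglik_var=float(trace.var(ddof=1)) if len(trace) > 1 else 0.0,
    )


def lnpd_from_trace(trace) -> float:
    """Model-evidence estimate from a log-likelihood trace: mean - var/2
    (sample variance, n-1 denominator)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty log-likelihood trace")
    if trace.size == 1:
        return float(trace[0])
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def run_replicates(genotypes: Genotypes, config: McmcConfig,
                   seed: int | None = None
                   ) -> dict[int, list[AncestryEstimate]]:
    """Replicate runs over the configured K range with per-run subseeds."""
    base = np.random.SeedSequence(config.seed if seed is None else seed)
    runs: dict[int, list[AncestryEstimate]] = {}
    children = iter(base.spawn(len(config.k_range) * config.n_replicates))
    for K in config.k_range:
        runs[K] = [
            admixture_mcmc(
                genotypes, K, config,
                seed=int(next(children).generate_state(1)[0] % (2**31)),
            )
            for _ in range(config.n_replicates)
        ]
    return runs


def select_k(runs: dict[int, list[AncestryEstimate]]) -> KSelection:
    """Pick K with the largest mean model evidence over replicates.

    When the two best means differ by less than one pooled replicate SD,
    the smaller K of the pair is chosen and the tie flag set.
    """
    if not runs or any(not v for v in runs.values()):
        raise ValueError("empty run set")
    rows = {}
    for K, ests in sorted(runs.items()):
        vals = np.array([e.lnpd for e in ests])
        rows[K] = {"mean": vals.mean(),
                   "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                   "n_runs": len(vals)}
    table = pd.DataFrame(rows).T
    table.index.name = "K"
    order = table.sort_values("mean", ascending=False)
    chosen = int(order.index[0])
    tie = False
    if len(order) > 1:
        top, second = order.iloc[0], order.iloc[1]
        pooled_sd = float(np.sqrt((top["sd"] ** 2 + second["sd"] ** 2) / 2.0))
        if top["mean"] - second["mean"] < pooled_sd or \
                top["mean"] == second["mean"]:
            chosen = int(min(order.index[0], order.index[1]))
            tie = True
    return KSelection(per_k=table, chosen_k=chosen, tie=tie)


def align_runs(q_matrices: list[np.ndarray]
               ) -> tuple[list[np.ndarray], np.ndarray, list[tuple[int, ...]]]:
    """Resolve label switching across replicate runs.

    Each run's clusters are permuted to maximize the summed column-wise
    correlation with the first run (optimal assignment); returns the
    aligned matrices, their mean, and the permutation applied per run.
    """
    if not q_matrices:
        raise ValueError("no Q matrices")
    shape = q_matrices[0].shape
    if any(q.shape != shape for q in q_matrices):
        raise ValueError("inconsistent Q shapes")
    K = shape[1]
    ref = q_matrices[0]
    aligned, perms = [], []
    for Q in q_matrices:
        if K == 1:
            aligned.append(Q.copy())
            perms.append((0,))
            continue
        C = np.zeros((K, K))
        for j in range(K):
            for k in range(K):
                a, b = ref[:, j], Q[:, k]
                if a.std() < 1e-12 or b.std() < 1e-12:
                    C[j, k] = -np.abs(a - b).mean()   # fall back to closeness
                else:
                    C[j, k] = np.corrcoef(a, b)[0, 1]
        rows, cols = linear_sum_assignment(-C)
        perm = tuple(int(cols[list(rows).index(j)]) for j in range(K))
        aligned.append(Q[:, list(perm)])
        perms.append(perm)
    return aligned, np.mean(aligned, axis=0), perms


def hard_assignments(q_mean: np.ndarray) -> np.ndarray:
    """Cluster per individual = argmax membership, ties to lower index."""
    return np.argmax(q_mean, axis=1)


def site_cluster_frequencies(genotypes: Genotypes, q_mean: np.ndarray,
                             site_order: list[str]) -> pd.DataFrame:
    """Mean membership per site (the per-site cluster frequency profile)."""
    rows = []
    for site in site_order:
        idx = genotypes.individuals_at(site)
        rows.append(q_mean[idx].mean(axis=0))
    return pd.DataFrame(
        rows, index=site_order,
        columns=[f"cluster_{k + 1}" for k in range(q_mean.shape[1])],
    )


def cline_center(positions, values, midpoint: float = 0.5) -> float | None:
    """Linear-interpolated position where a monotone-ish site series
    crosses ``midpoint``; None when it never crosses."""
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    for i in range(len(values) - 1):
        a, b = values[i], values[i + 1]
        if (a - midpoint) * (b - midpoint) <= 0 and a != b:
            t = (midpoint - a) / (b - a)
            return float(positions[i] + t * (positions[i + 1] - positions[i]))
    return None


# ---------------------------------------------------------------------------
# Allele-frequency PCA

def allele_frequency_table(genotypes: Genotypes,
                           site_order: list[str] | None = None) -> pd.DataFrame:
    """Site x (locus, allele) frequency table; frequencies sum to 1 within
    each locus, missing copies excluded from denominators."""
    sites = site_order or genotypes.sites()
    cols, data = [], []
    for l, locus in enumerate(genotypes.loci):
        codes = np.unique(
            genotypes.calls[:, l, :][genotypes.calls[:, l, :] != MISSING]
        )
        freqs = np.zeros((len(sites), len(codes)))
        for s, site in enumerate(sites):
            counts = genotypes.allele_counts(l, genotypes.individuals_at(site))
            tot = sum(counts.values())
            if tot:
                freqs[s] = [counts.get(int(c), 0) / tot for c in codes]
            else:
                freqs[s] = np.nan
        data.append(freqs)
        cols.extend((locus, int(c)) for c in codes)
    frame = pd.DataFrame(
        np.hstack(data), index=sites,
        columns=pd.MultiIndex.from_tuples(cols, names=["locus", "allele"]),
    )
    return frame


def allele_freq_pca(genotypes: Genotypes, site_order: list[str] | None = None,
                    positions=None) -> pd.Series:
    """PC1 site scores of the centered allele-frequency table, sign-oriented
    to correlate positively with site position.  Sites with zero called
    copies at every locus are excluded with a warning."""
    sites = site_order or genotypes.sites()
    if len(sites) < 3:
        raise ValueError("allele-frequency PCA needs >= 3 sites")
    table = allele_frequency_table(genotypes, sites)
    empty = table.isna().all(axis=1)
    if empty.any():
        import warnings
        warnings.warn(f"excluding empty site(s) {list(table.index[empty])}")
        table = table[~empty]
    X = table.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, 0] * S[0]
    pos = np.asarray(
        positions if positions is not None else np.arange(len(table)),
        dtype=float,
    )
    if scores.std() > 1e-12 and np.corrcoef(scores, pos[: len(scores)])[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=table.index, name="PC1")


# ---------------------------------------------------------------------------
# HWE / LD quality checks

def _site_locus_calls(genotypes: Genotypes, site: str, locus: str) -> np.ndarray:
    l = genotypes.loci.index(locus)
    rows = genotypes.individuals_at(site)
    calls = genotypes.calls[rows, l, :]
    return calls[(calls != MISSING).all(axis=1)]


def hwe_test(genotypes: Genotypes, site: str, locus: str,
             n_perm: int = 10_000, seed: int = 0) -> tuple[float, bool]:
    """Monte-Carlo exact-style test of Hardy-Weinberg proportions.

    Statistic: absolute deviation of the heterozygote count from its
    random-pairing expectation; the null resamples genotypes by randomly
    re-pairing the observed allele pool.  Returns ``(p, monomorphic_flag)``;
    a monomorphic locus gives p = 1 with the flag set.
    """
    calls = _site_locus_calls(genotypes, site, locus)
    if len(calls) < 5:
        raise ValueError("need >= 5 called individuals")
    pool = calls.ravel()
    if len(np.unique(pool)) < 2:
        return 1.0, True
    n = len(calls)
    obs_het = int((calls[:, 0] != calls[:, 1]).sum())
    two_n = 2 * n
    _, counts = np.unique(pool, return_counts=True)
    exp_het = n * (1 - (counts * (counts - 1)).sum() / (two_n * (two_n - 1)))
    obs_dev = abs(obs_het - exp_het)

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, two_n)), axis=1)
    perms = pool[order]
    het = (perms[:, 0::2] != perms[:, 1::2]).sum(axis=1)
    exceed = int((np.abs(het - exp_het) >= obs_dev - 1e-9).sum())
    return (exceed + 1) / (n_perm + 1), False


def _genotype_categories(calls: np.ndarray) -> np.ndarray:
    """Encode unordered allele pairs as small ints."""
    lo = np.minimum(calls[:, 0], calls[:, 1])
    hi = np.maximum(calls[:, 0], calls[:, 1])
    pairs = lo * 10_000 + hi
    _, inv = np.unique(pairs, return_inverse=True)
    return inv


def ld_test(genotypes: Genotypes, site: str, locus_a: str, locus_b: str,
            n_perm: int = 10_000, seed: int = 0) -> tuple[float, bool]:
    """Permutation test of genotypic association between two loci.

    Statistic: Pearson chi-square of the genotype-category contingency
    table; null built by permuting one locus's genotypes across the shared
    individuals.  Either locus monomorphic gives p = 1 with the flag set.
    """
    la, lb = genotypes.loci.index(locus_a), genotypes.loci.index(locus_b)
    rows = genotypes.individuals_at(site)
    calls = genotypes.calls[rows][:, [la, lb], :]
    ok = (calls != MISSING).all(axis=(1, 2))
    calls = calls[ok]
    if len(calls) < 5:
        raise ValueError("need >= 5 shared called individuals")
    cat_a = _genotype_categories(calls[:, 0, :])
    cat_b = _genotype_categories(calls[:, 1, :])
    na, nb = cat_a.max() + 1, cat_b.max() + 1
    if na < 2 or nb < 2:
        return 1.0, True
    n = len(cat_a)

    def chi2_of(joint: np.ndarray) -> float:
        exp = joint.sum(1, keepdims=True) * joint.sum(0, keepdims=True) / n
        mask = exp > 0
        return float(((joint - exp)[mask] ** 2 / exp[mask]).sum())

    joint = np.zeros((na, nb))
    np.add.at(joint, (cat_a, cat_b), 1.0)
    obs = chi2_of(joint)

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = cat_b[order]                       # (n_perm, n)
    # joint counts for all permutations, cell by cell
    stats = np.zeros(n_perm)
    row_marg = np.bincount(cat_a, minlength=na).astype(float)
    col_marg = np.bincount(cat_b, minlength=nb).astype(float)
    exp = np.outer(row_marg, col_marg) / n
    for a in range(na):
        sel = permuted[:, cat_a == a]             # (n_perm, n_a)
        for b in range(nb):
            if exp[a, b] <= 0:
                continue
            cnt = (sel == b).sum(axis=1)
            stats += (cnt - exp[a, b]) ** 2 / exp[a, b]
    exceed = int((stats >= obs - 1e-9).sum())
    return (exceed + 1) / (n_perm + 1), False


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold for a family of locus-pair (or site-locus)
    tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
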