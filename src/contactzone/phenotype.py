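"""Habitat characterization and quantitative-trait summarization.

Climate is reduced by PCA of the ln-transformed 19-variable profile; the
component tracking the transect ("the climatic trend") is identified by its
correlation with position, and an ecotone — if any — is placed at the
midpoint between that component's extreme site scores.  Quantitative traits
are summarized by canonical variates with sites as groups, scaled so the
pooled within-group SD is one; when the within-site covariances are too
unequal for CVA to be trusted, a PCA of standardized site means is used
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datamodel import CLIMATE_VARS


@dataclass
class ClimateProfile:
    """The climatic trend along one transect."""

    transect_id: str
    component_index: int          # 0-based index among PCs
    scores: pd.Series             # per-site scores of the trend component
    proportion_variance: float
    magnitude: float              # max site score - min site score
    loadings: pd.Series           # unit-norm direction over retained columns
    r_with_position: float


@dataclass
class HabitatPartition:
    """Two-way habitat split of sites on the climate-trend axis."""

    cut_point: float
    labels: pd.Series                      # per site, 'A' / 'B'
    boundary: tuple[str, str] | None       # adjacent site pair, or None
    multiple_boundaries: bool = False
    no_ecotone: bool = False


@dataclass
class CvaResult:
    """Trait ordination summary.

    ``method`` is ``cva`` (canonical variates, within-group SD of scores
    = 1) or ``pca_site_means`` (heteroscedastic fallback).
    """

    method: str
    individual_scores: pd.Series | None    # axis-1 score per trait individual
    site_mean_scores: pd.Series
    magnitude: float
    pooled_within_sd: float | None
    heteroscedasticity_spread: float
    imputed_cells: int = 0


def climate_pca(site_frame: pd.DataFrame, positions: np.ndarray | pd.Series,
                transect_id: str = "") -> ClimateProfile:
    """PCA of ln-transformed climate over the sites of one transect.

    Each variable is transformed ``x -> ln(x + s)`` with ``s = 1`` for
    variables containing zeros and ``s = 0`` otherwise, then column
    standardized (the variables mix degC and mm scales).  The trend
    component is the PC whose score vector is most correlated (|Pearson r|)
    with site position; magnitude is the score range of that component.
    """
    if len(site_frame) < 3:
        raise ValueError("climate PCA needs >= 3 sites")
    cols = [c for c in CLIMATE_VARS if c in site_frame.columns]
    if len(cols) != len(CLIMATE_VARS):
        missing = sorted(set(CLIMATE_VARS) - set(cols))
        raise ValueError(f"missing climate columns: {missing}")
    X = site_frame[cols].to_numpy(dtype=float)
    positions = np.asarray(positions, dtype=float)

    shift = (X == 0).any(axis=0).astype(float)   # ln(x+1) only where zeros occur
    X = np.log(X + shift[None, :])

    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-12
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant climate column(s) {dropped}")
    cols = [c for c, k in zip(cols, keep) if k]
    X = X[:, keep]
    if X.shape[1] == 0:
        # completely constant climate: zero-variance profile
        scores = pd.Series(np.zeros(len(site_frame)), index=site_frame.index)
        return ClimateProfile(transect_id, 0, scores, 0.0, 0.0,
                              pd.Series(dtype=float), 0.0)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    score_mat = U * S                       # sites x components
    var = S ** 2 / max(len(site_frame) - 1, 1)
    prop = var / var.sum()

    # trend = component most correlated with position
    best, best_r = 0, 0.0
    for k in range(score_mat.shape[1]):
        s = score_mat[:, k]
        if s.std() < 1e-12:
            continue
        r = np.corrcoef(s, positions)[0, 1]
        if abs(r) > abs(best_r):
            best, best_r = k, r

    scores = score_mat[:, best]
    loadings = Vt[best]
    if best_r < 0:                          # orient with position
        scores, loadings, best_r = -scores, -loadings, -best_r
    return ClimateProfile(
        transect_id=transect_id,
        component_index=best,
        scores=pd.Series(scores, index=site_frame.index),
        proportion_variance=float(prop[best]),
        magnitude=float(scores.max() - scores.min()),
        loadings=pd.Series(loadings, index=cols),
        r_with_position=float(best_r),
    )


def ecotone_partition(profile: ClimateProfile) -> HabitatPartition:
    """Split sites by the midpoint of the extreme climate-trend scores.

    The cut-point is ``(max + min) / 2``; sites score above it are habitat
    ``B``.  The boundary is the first adjacent pair where the label changes
    (flagged if the labels change more than once).  All-equal scores give a
    degenerate all-``A`` partition with ``no_ecotone`` set.
    """
    s = profile.scores
    if len(s) < 2:
        raise ValueError("need >= 2 sites")
    lo, hi = float(s.min()), float(s.max())
    if hi - lo < 1e-12:
        return HabitatPartition(
            cut_point=lo, labels=pd.Series("A", index=s.index),
            boundary=None, no_ecotone=True,
        )
    cut = (hi + lo) / 2.0
    labels = pd.Series(np.where(s.to_numpy() > cut, "B", "A"), index=s.index)
    changes = [
        (s.index[i], s.index[i + 1])
        for i in range(len(s) - 1)
        if labels.iloc[i] != labels.iloc[i + 1]
    ]
    return HabitatPartition(
        cut_point=cut,
        labels=labels,
        boundary=changes[0] if changes else None,
        multiple_boundaries=len(changes) > 1,
        no_ecotone=not changes,
    )


def ecotone_is_real(profile: ClimateProfile, min_magnitude: float = 3.0,
                    min_proportion: float = 0.5,
                    min_abs_r: float = 0.7) -> bool:
    """Judge whether the climatic trend marks a genuine habitat transition.

    A midpoint split can always be drawn, even through pure noise, so a
    transect is only treated as crossing an ecotone when the trend
    component is large (score range), dominant (share of variance) and
    actually tracks the transect (|r| with position).  Transects running
    within one habitat type fail at least one of the three.
    """
    return (
        profile.magnitude >= min_magnitude
        and profile.proportion_variance >= min_proportion
        and abs(profile.r_with_position) >= min_abs_r
    )


def _heteroscedasticity_spread(by_site: dict[str, np.ndarray]) -> float:
    """Proxy for Box's M: spread of per-site log total variance.

    Per-site full covariance determinants are unusable at typical group
    sizes (10 individuals, 27 traits), so the diagnostic compares the log
    of each site's total variance (trace of its covariance); the spread
    max - min is returned.
    """
    logs = []
    for X in by_site.values():
        if X.shape[0] < 2:
            continue
        tr = float(np.trace(np.cov(X, rowvar=False).reshape(X.shape[1], -1)))
        logs.append(np.log(max(tr, 1e-300)))
    return float(max(logs) - min(logs)) if len(logs) > 1 else 0.0


def cva_traits(traits_by_site: dict[str, pd.DataFrame],
               positions: dict[str, float] | None = None,
               heteroscedasticity_threshold: float = 2.5) -> CvaResult:
    """Canonical variate analysis with sites as groups.

    Missing trait cells are imputed by the site mean (counted in the
    result).  The leading canonical axis maximizes between-site relative to
    pooled within-site variance; scores are scaled to unit pooled
    within-group SD and the axis sign is chosen so site-mean scores
    correlate positively with site position.  If the per-site dispersions
    are too unequal (log total-variance spread above the threshold), the
    method falls back to PCA of standardized site-mean vectors.
    """
    site_ids = list(traits_by_site)
    if len(site_ids) < 2:
        raise ValueError("CVA needs >= 2 sites")
    cols = list(traits_by_site[site_ids[0]].columns)
    if len(cols) < 1:
        raise ValueError("no trait columns")

    imputed = 0
    by_site: dict[str, np.ndarray] = {}
    for sid in site_ids:
        df = traits_by_site[sid][cols].astype(float)
        n_missing = int(df.isna().sum().sum())
        if n_missing:
            df = df.fillna(df.mean())
            imputed += n_missing
        X = df.to_numpy()
        if X.shape[0] < 2:
            raise ValueError(f"site {sid} has < 2 trait individuals")
        by_site[sid] = X

    pos = np.array([
        positions[sid] if positions else float(i)
        for i, sid in enumerate(site_ids)
    ])
    spread = _heteroscedasticity_spread(by_site)

    if spread > heteroscedasticity_threshold:
        return _pca_site_means(by_site, site_ids, pos, spread, imputed)

    N = sum(X.shape[0] for X in by_site.values())
    g = len(site_ids)
    p = len(cols)
    grand = np.vstack(list(by_site.values())).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = {}
    for sid, X in by_site.items():
        m = X.mean(axis=0)
        means[sid] = m
        W += (X - m).T @ (X - m)
        B += X.shape[0] * np.outer(m - grand, m - grand)
    Sw = W / (N - g)
    Sb = B / (g - 1)

    # ridge if the pooled within covariance is singular
    try:
        cond = np.linalg.cond(Sw)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        lam = 1e-6 * np.trace(Sw) / p
        warnings.warn(f"singular pooled within-group covariance; ridge {lam:.3g}")
        Sw = Sw + lam * np.eye(p)

    evals, evecs = linalg.eigh(Sb, Sw)
    v = evecs[:, -1]                       # leading canonical direction
    v = v / np.sqrt(v @ Sw @ v)            # unit pooled within-group SD

    site_means = pd.Series({sid: float(means[sid] @ v) for sid in site_ids})
    if len(site_ids) > 2 and np.corrcoef(site_means.to_numpy(), pos)[0, 1] < 0:
        v = -v
        site_means = -site_means
    elif len(site_ids) <= 2 and site_means.iloc[-1] < site_means.iloc[0]:
        v = -v
        site_means = -site_means

    ind_scores = pd.concat({
        sid: pd.Series(X @ v, index=traits_by_site[sid].index)
        for sid, X in by_site.items()
    })
    # center scores on the grand mean for readability
    center = float(grand @ v)
    ind_scores -= center
    site_means -= center

    return CvaResult(
        method="cva",
        individual_scores=ind_scores,
        site_mean_scores=site_means,
        magnitude=float(site_means.max() - site_means.min()),
        pooled_within_sd=1.0,
        heteroscedasticity_spread=spread,
        imputed_cells=imputed,
    )


def _pca_site_means(by_site, site_ids, pos, spread, imputed) -> CvaResult:
    M = np.vstack([by_site[sid].mean(axis=0) for sid in site_ids])
    sd = M.std(axis=0, ddof=1)
    keep = sd > 1e-12
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    if len(site_ids) > 2 and np.corrcoef(scores, pos)[0, 1] < 0:
        scores = -scores
    site_means = pd.Series(scores, index=site_ids)
    return CvaResult(
        method="pca_site_means",
        individual_scores=None,
        site_mean_scores=site_means,
        magnitude=float(site_means.max() - site_means.min()),
        pooled_within_sd=None,
        heteroscedasticity_spread=spread,
        imputed_cells=imputed,
    )


def site_correlation(x, y) -> tuple[float, float, int]:
    """Pearson correlation of paired per-site values with the t-based
    two-sided p (n - 2 df); returns ``(r, p, n)``.

    Zero variance in either vector yields ``(nan, nan, n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 sites")
    if x.std() < 1e-14 or y.std() < 1e-14:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
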