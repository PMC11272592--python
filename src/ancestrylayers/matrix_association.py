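"""Permutation statistics on distance matrices.

Mantel tests (Spearman by default, matching the reported "Mantel rho"),
multiple matrix regression (MMRR), congruence among distance matrices
(CADM: Kendall's W over the ranked unfolded distances, global and
a posteriori variants), and multiplicity adjustment.

All null distributions are built by relabelling objects — permuting rows
and columns of a matrix simultaneously — never by shuffling cells
independently, which would destroy the dependence structure of a distance
matrix. P values use the add-one estimator (1 + #extreme) / (1 + n_perm),
so they are never zero, and are two-sided for Mantel/MMRR and one-sided
(toward congruence) for CADM. Everything is bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datatypes import DataFormatError, DistanceMatrix, align_distance_matrices

__all__ = [
    "MantelResult",
    "MmrrResult",
    "CadmResult",
    "mantel_test",
    "mmrr",
    "cadm_global",
    "cadm_post",
    "p_adjust",
]


@dataclass
class MantelResult:
    rho: float
    p: float
    n_permutations: int
    seed: int
    method: str


@dataclass
class MmrrResult:
    coefficients: dict
    t_values: dict
    p_values: dict
    r_squared: float
    n_permutations: int
    seed: int


@dataclass
class CadmResult:
    W: float
    chi2: float
    df: int
    p_global: float
    n_permutations: int
    seed: int
    post_mean_correlations: dict = field(default_factory=dict)
    post_p: dict = field(default_factory=dict)
    post_p_adjusted: dict = field(default_factory=dict)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise DataFormatError("constant distance matrix: correlation undefined")
    return float(xc @ yc / (sx * sy))


def _rank_square(dm: DistanceMatrix) -> np.ndarray:
    """Square matrix holding mid-ranks of the unfolded upper triangle."""
    iu = np.triu_indices(dm.n, 1)
    r = rankdata(dm.values[iu])
    out = np.zeros_like(dm.values)
    out[iu] = r
    return out + out.T


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 1000,
                seed: int = 0, method: str = "spearman") -> MantelResult:
    """Mantel correlation between two distance matrices with permutation p.

    rho is the Spearman (default) or Pearson correlation of the unfolded
    upper triangles. The null relabels the objects of ``d2``; the two-sided
    p value counts permuted |rho*| >= |rho|.
    """
    d1, d2 = align_distance_matrices(d1, d2)
    n = d1.n
    iu = np.triu_indices(n, 1)
    if method == "spearman":
        m1, m2 = _rank_square(d1), _rank_square(d2)
    elif method == "pearson":
        m1, m2 = d1.values, d2.values
    else:
        raise DataFormatError(f"unknown Mantel method {method!r}")
    x = m1[iu]
    rho = _pearson(x, m2[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        y = m2[np.ix_(p, p)][iu]
        if abs(_pearson(x, y)) >= abs(rho) - 1e-12:
            hits += 1
    pval = (1 + hits) / (1 + n_perm)
    return MantelResult(rho=rho, p=pval, n_permutations=n_perm, seed=seed,
                        method=method)


def _ols(X: np.ndarray, y: np.ndarray):
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof if dof > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
    return beta, beta / se, resid


def mmrr(d_response: DistanceMatrix, d_predictors: dict,
         n_perm: int = 1000, seed: int = 0) -> MmrrResult:
    """Multiple regression of one distance matrix on several others.

    OLS on the unfolded upper triangles; the permutation null relabels the
    response matrix's objects and recomputes the t statistics, giving a
    two-sided p per coefficient. Perfectly collinear predictors raise an
    error naming the offending pair.
    """
    names = list(d_predictors)
    mats = align_distance_matrices(d_response, *d_predictors.values())
    resp, preds = mats[0], dict(zip(names, mats[1:]))
    n = resp.n
    iu = np.triu_indices(n, 1)
    cols = [preds[name].values[iu] for name in names]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(_pearson(cols[i], cols[j])) > 1 - 1e-9:
                raise DataFormatError(
                    f"predictors {names[i]!r} and {names[j]!r} are collinear")
    X = np.column_stack([np.ones(len(iu[0]))] + cols)
    y = resp.values[iu]
    beta, t_obs, resid = _ols(X, y)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - resid @ resid / tss if tss > 0 else np.nan
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(names))
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = resp.values[np.ix_(p, p)][iu]
        _, t_perm, _ = _ols(X, yp)
        hits += np.abs(t_perm[1:]) >= np.abs(t_obs[1:]) - 1e-12
    pvals = (1 + hits) / (1 + n_perm)
    return MmrrResult(coefficients=dict(zip(names, beta[1:])) | {"intercept": beta[0]},
                      t_values=dict(zip(names, t_obs[1:])),
                      p_values=dict(zip(names, pvals)),
                      r_squared=float(r2), n_permutations=n_perm, seed=seed)


def _kendall_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``ranks``: (k judges, m objects) mid-rank rows.
    """
    k, m = ranks.shape
    S = float(np.sum((ranks.sum(axis=0) - k * (m + 1) / 2.0) ** 2))
    T = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        T += float(np.sum(counts ** 3 - counts))
    denom = k ** 2 * (m ** 3 - m) - k * T
    if denom <= 0:
        raise DataFormatError("degenerate rank matrix in Kendall's W")
    return 12.0 * S / denom


def cadm_global(matrices: list[DistanceMatrix], n_perm: int = 1000,
                seed: int = 0) -> CadmResult:
    """Global congruence test over two or more distance matrices.

    Unfolded distances of each matrix are ranked; Kendall's W measures
    concordance across matrices. The null (full incongruence) relabels each
    matrix's objects independently; p is one-sided toward high W. The
    Friedman chi-square approximation k(m-1)W is reported alongside. For
    k = 2 matrices, W = (r + 1) / 2 where r is their Spearman correlation.
    """
    if len(matrices) < 2:
        raise DataFormatError("CADM requires at least two matrices")
    mats = align_distance_matrices(*matrices)
    n = mats[0].n
    iu = np.triu_indices(n, 1)
    squares = [_rank_square(m) for m in mats]
    ranks = np.stack([s[iu] for s in squares])
    k, m = ranks.shape
    W = _kendall_w(ranks)
    chi2 = k * (m - 1) * W
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_ranks = np.stack([
            s[np.ix_(p, p)][iu]
            for s, p in zip(squares, (rng.permutation(n) for _ in squares))])
        if _kendall_w(perm_ranks) >= W - 1e-12:
            hits += 1
    p_global = (1 + hits) / (1 + n_perm)
    return CadmResult(W=W, chi2=chi2, df=m - 1, p_global=p_global,
                      n_permutations=n_perm, seed=seed)


def cadm_post(matrices: list[DistanceMatrix], n_perm: int = 1000,
              seed: int = 0, labels: list[str] | None = None) -> CadmResult:
    """A posteriori congruence tests: one per matrix, Holm-adjusted.

    For matrix j the statistic is its mean Spearman correlation with the
    other matrices; the null permutes the objects of matrix j only. The
    per-matrix p values are adjusted for multiple testing with Holm's
    procedure. With exactly two matrices both tests coincide with the
    global test's hypothesis.
    """
    res = cadm_global(matrices, n_perm=n_perm, seed=seed)
    mats = align_distance_matrices(*matrices)
    names = labels or [f"matrix_{j + 1}" for j in range(len(mats))]
    n = mats[0].n
    iu = np.triu_indices(n, 1)
    squares = [_rank_square(m) for m in mats]
    ranks = [s[iu] for s in squares]

    def mean_corr(vec, others):
        return float(np.mean([_pearson(vec, o) for o in others]))

    rng = np.random.default_rng(seed)
    raw_p, stats = [], []
    for j, name in enumerate(names):
        others = [r for i, r in enumerate(ranks) if i != j]
        obs = mean_corr(ranks[j], others)
        hits = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            vec = squares[j][np.ix_(p, p)][iu]
            if mean_corr(vec, others) >= obs - 1e-12:
                hits += 1
        stats.append(obs)
        raw_p.append((1 + hits) / (1 + n_perm))
    adjusted = p_adjust(raw_p, method="holm")
    res.post_mean_correlations = dict(zip(names, stats))
    res.post_p = dict(zip(names, raw_p))
    res.post_p_adjusted = dict(zip(names, adjusted))
    return res


def p_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (step-up) or Holm (step-down) adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataFormatError("p values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm"}.get(method)
    if key is None:
        raise DataFormatError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]
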