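"""Shared-vocabulary counting, tree-based linguistic distances, and the
zero-inflated Poisson test battery.

Word lists are cognate-coded by experts (the coding is an input, never
computed here): each record carries a group, a cultural domain, an object,
the word form, a cognate-set id, and flags for CAHG-uniqueness and coding
confidence. Dyadic shared-word counts (number of cognate sets two groups
both carry) are modelled with zero-inflated Poisson regressions on
standardized dyadic predictors; linguistic distances come from Glottolog
trees (internal-node counts) and dated phylogenies (patristic distances,
with a maximum-depth rule for languages outside the tree's family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.discrete.count_model import ZeroInflatedPoisson

from .datatypes import DataFormatError

__all__ = [
    "CognateTable",
    "ZipModel",
    "shared_word_counts",
    "glottolog_node_distance",
    "patristic_distance",
    "zip_fit",
    "wilcoxon_signed_rank",
    "spearman_with_S",
]

COGNATE_COLUMNS = ["group", "domain", "object_id", "word", "cognate_set",
                   "unique_to_cahg", "confidence"]


@dataclass
class CognateTable:
    """Cognate-coded word records across groups.

    The *broader* view is every row; the *restricted* view keeps rows whose
    coding confidence is conclusive and whose term is unique to CAHGs.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COGNATE_COLUMNS) - set(self.table.columns)
        if missing:
            raise DataFormatError(f"cognate table missing columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, source) -> "CognateTable":
        return cls(pd.read_csv(source))

    def view(self, domain: str | None = None, restricted: bool = False) -> pd.DataFrame:
        t = self.table
        if domain is not None:
            t = t[t["domain"] == domain]
        if restricted:
            t = t[(t["confidence"] == "conclusive") & t["unique_to_cahg"].astype(bool)]
        return t


def shared_word_counts(cognates: CognateTable, domain: str | None = None,
                       restricted: bool = False):
    """Dyadic shared-cognate-set counts and the degree distribution.

    Returns ``(counts, degrees)`` where ``counts`` is a symmetric group x
    group DataFrame (entry = number of cognate sets present in both groups)
    and ``degrees`` maps degree d (>= 2) to the number of cognate sets
    carried by exactly d groups. Duplicate (group, cognate-set) rows are
    collapsed with a warning.
    """
    t = cognates.view(domain=domain, restricted=restricted)
    groups = sorted(t["group"].unique()) if len(t) else []
    pairs = t[["group", "cognate_set"]]
    if pairs.duplicated().any():
        warnings.warn("duplicate (group, cognate set) rows collapsed", stacklevel=2)
        pairs = pairs.drop_duplicates()
    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    degrees: dict[int, int] = {}
    for _, members in pairs.groupby("cognate_set")["group"]:
        carriers = sorted(set(members))
        d = len(carriers)
        if d >= 2:
            degrees[d] = degrees.get(d, 0) + 1
        for i in range(d):
            for j in range(i + 1, d):
                counts.loc[carriers[i], carriers[j]] += 1
                counts.loc[carriers[j], carriers[i]] += 1
    return counts, dict(sorted(degrees.items()))


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def _find_taxon(tree: dendropy.Tree, label: str):
    taxon = tree.taxon_namespace.get_taxon(label)
    if taxon is None:
        raise DataFormatError(f"tip {label!r} absent from tree")
    return taxon


def glottolog_node_distance(tree, language_a: str, language_b: str) -> int:
    """Number of internal nodes strictly on the tip-to-tip path.

    Endpoints are excluded; each internal node on the path counts once, so
    for ``((A,B),C)`` the A-B distance is 1 (their parent) and A-C is 2
    (parent plus root). The same tip gives 0.
    """
    t = _load_tree(tree)
    if language_a == language_b:
        _find_taxon(t, language_a)
        return 0
    ta, tb = _find_taxon(t, language_a), _find_taxon(t, language_b)
    pdm = t.phylogenetic_distance_matrix()
    edges = pdm.path_edge_count(ta, tb)
    return int(edges) - 1


def patristic_distance(tree, language_a: str, language_b: str,
                       out_of_family: set | frozenset = frozenset()) -> float:
    """Branch-length sum between two tips of a dated phylogeny.

    Languages outside the tree's family (``out_of_family``) are assigned
    the maximum root-to-tip depth of the tree as their distance to every
    other language. A missing tip that is not declared out-of-family is an
    error.
    """
    t = _load_tree(tree)
    if language_a in out_of_family or language_b in out_of_family:
        return float(max(leaf.distance_from_root() for leaf in t.leaf_node_iter()))
    if language_a == language_b:
        _find_taxon(t, language_a)
        return 0.0
    ta, tb = _find_taxon(t, language_a), _find_taxon(t, language_b)
    pdm = t.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(ta, tb))


@dataclass
class ZipModel:
    """Fitted zero-inflated Poisson regression.

    ``beta`` are the count-model (log link) coefficients, ``gamma`` the
    zero-inflation (logit link) coefficients, both with the intercept first;
    standard errors come from the observed information matrix.
    """

    beta: np.ndarray
    gamma: np.ndarray
    beta_se: np.ndarray
    gamma_se: np.ndarray
    log_likelihood: float
    converged: bool
    fitted_lambda: np.ndarray
    fitted_pi: np.ndarray

    def predicted_mean(self) -> np.ndarray:
        return (1.0 - self.fitted_pi) * self.fitted_lambda


def zip_fit(y, X, standardize_check: bool = True) -> ZipModel:
    """Maximum-likelihood zero-inflated Poisson fit.

    ``y``: non-negative integer dyadic counts. ``X``: predictor matrix
    without intercept, standardized per column (checked unless
    ``standardize_check`` is False); the same predictors enter the count
    and the zero model. Non-convergence and an all-zero response raise.
    """
    y = np.asarray(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size and X.shape[1] == y.size:
        X = X.T
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise DataFormatError("counts must be non-negative integers")
    if not y.any():
        raise DataFormatError("all-zero response: ZIP model unidentifiable")
    if standardize_check and X.size:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        if np.any(np.abs(mu) > 1e-6) or np.any(np.abs(sd - 1) > 1e-6):
            raise DataFormatError("predictors must be standardized (mean 0, sd 1)")
    exog = np.column_stack([np.ones(y.size), X])
    model = ZeroInflatedPoisson(y, exog, exog_infl=exog, inflation="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", maxiter=500, disp=0)
    if not fit.mle_retvals.get("converged", False):
        raise DataFormatError(f"ZIP fit did not converge: {fit.mle_retvals}")
    k = exog.shape[1]
    params = np.asarray(fit.params)
    ses = np.asarray(fit.bse)
    gamma, beta = params[:k], params[k:]
    gamma_se, beta_se = ses[:k], ses[k:]
    lam = np.exp(exog @ beta)
    pi = 1.0 / (1.0 + np.exp(-(exog @ gamma)))
    return ZipModel(beta=beta, gamma=gamma, beta_se=beta_se, gamma_se=gamma_se,
                    log_likelihood=float(fit.llf), converged=True,
                    fitted_lambda=lam, fitted_pi=pi)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W, p).

    W is the rank sum of positive differences (x - y); zero differences are
    dropped and ties mid-ranked. The p value is exact for n <= 25 nonzero
    pairs and a tie-corrected normal approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataFormatError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise DataFormatError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    method = "exact" if d.size <= 25 and not _has_ties(np.abs(d)) else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=False)
    return w_plus, float(res.pvalue)


def _has_ties(v: np.ndarray) -> bool:
    return np.unique(v).size < v.size


def spearman_with_S(x, y) -> tuple[float, float]:
    """Spearman correlation reported together with the rank statistic S.

    S = sum of squared rank differences (mid-ranks under ties); rho is the
    Pearson correlation of the ranks, which equals 1 - 6S/(n^3 - n) in the
    absence of ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataFormatError("vectors must have equal length")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.unique(rx).size == 1 or np.unique(ry).size == 1:
        raise DataFormatError("constant vector: Spearman undefined")
    S = float(np.sum((rx - ry) ** 2))
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, S
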