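"""Ancestry-specific allele frequencies, Hudson's FST, and classical MDS.

Frequencies are computed over retained (unmasked) haplotype alleles only:
f_i = a_i / n_i where a_i counts alternate alleles among retained
hunter-gatherer-ancestry chromosomes of population i and n_i counts all
retained chromosomes there. Sites retained by one or fewer chromosomes in
any population are dropped for all populations (so n_i > 1 everywhere).

Hudson's FST is the ratio-of-averages estimator: per site

    num = (f_A - f_B)^2 - f_A(1-f_A)/(n_A-1) - f_B(1-f_B)/(n_B-1)
    den = f_A(1-f_B) + f_B(1-f_A)

averaged separately across SNPs before dividing. Averaging the numerator
and denominator first (never averaging per-site ratios) is what makes the
multi-locus estimator consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, DataFormatError, DistanceMatrix, MaskedHaplotypeSet
from .ancestry_masking import GenotypeFrequencyMatrix

__all__ = [
    "SiteFrequencyTable",
    "FstResult",
    "site_frequencies",
    "hudson_fst",
    "fst_matrix",
    "pairwise_difference_distance",
    "classical_mds",
]


@dataclass
class SiteFrequencyTable:
    """Per-population alternate-allele counts over retained chromosomes."""

    populations: list[str]
    a: np.ndarray             # (n_pops, n_kept_sites) alternate-allele counts
    n: np.ndarray             # (n_pops, n_kept_sites) retained chromosome counts
    site_index: np.ndarray    # kept site indices in the originating set
    n_dropped: int

    @property
    def f(self) -> np.ndarray:
        return self.a / self.n

    @property
    def n_sites(self) -> int:
        return self.a.shape[1]


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    numerator_mean: float
    denominator_mean: float
    fst: float
    n_sites: int


def site_frequencies(mhs: MaskedHaplotypeSet,
                     populations: list[str] | None = None) -> SiteFrequencyTable:
    """Count retained alleles per population and drop under-covered sites.

    A site is dropped for *all* populations as soon as any population
    retains one or fewer alleles there, guaranteeing n_i > 1 at every kept
    site. The alternate allele is counted with a consistent reference
    across populations (the statistic is invariant to a global label swap).
    """
    pops = populations or sorted(set(mhs.populations))
    hap_pop = np.repeat(mhs.populations, 2)
    observed = mhs.alleles != MISSING
    alt = mhs.alleles == 1
    a_rows, n_rows = [], []
    for p in pops:
        cols = hap_pop == p
        if not cols.any():
            raise DataFormatError(f"population {p!r} has zero individuals")
        a_rows.append(alt[:, cols].sum(axis=1))
        n_rows.append(observed[:, cols].sum(axis=1))
    a = np.asarray(a_rows, dtype=float)
    n = np.asarray(n_rows, dtype=float)
    keep = (n > 1).all(axis=0)
    return SiteFrequencyTable(populations=list(pops), a=a[:, keep], n=n[:, keep],
                              site_index=np.flatnonzero(keep),
                              n_dropped=int((~keep).sum()))


def _hudson_terms(fA, fB, nA, nB):
    num = (fA - fB) ** 2 - fA * (1 - fA) / (nA - 1) - fB * (1 - fB) / (nB - 1)
    den = fA * (1 - fB) + fB * (1 - fA)
    return num, den


def hudson_fst(table: SiteFrequencyTable, pop_a: str, pop_b: str) -> FstResult:
    """Hudson's FST between two populations, ratio of averages across sites."""
    ia, ib = table.populations.index(pop_a), table.populations.index(pop_b)
    fA, fB = table.f[ia], table.f[ib]
    num, den = _hudson_terms(fA, fB, table.n[ia], table.n[ib])
    den_mean = float(den.mean()) if den.size else 0.0
    num_mean = float(num.mean()) if num.size else 0.0
    if den.size == 0 or den_mean == 0.0:
        warnings.warn(f"FST undefined for ({pop_a}, {pop_b}): "
                      "all sites monomorphic in both populations", stacklevel=2)
        fst = np.nan
    else:
        fst = num_mean / den_mean
    return FstResult(pop_a, pop_b, num_mean, den_mean, fst, int(den.size))


def fst_matrix(table: SiteFrequencyTable) -> DistanceMatrix:
    """All pairwise Hudson FSTs as a DistanceMatrix.

    Slightly negative estimates (sampling noise around zero differentiation)
    are clipped to 0 so the matrix remains a valid dissimilarity; the
    unclipped values are available through :func:`hudson_fst`.
    """
    k = len(table.populations)
    v = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = hudson_fst(table, table.populations[i], table.populations[j])
            v[i, j] = v[j, i] = max(r.fst, 0.0) if np.isfinite(r.fst) else np.nan
    if np.isnan(v).any():
        raise DataFormatError("FST undefined for at least one population pair")
    return DistanceMatrix(v, table.populations, kind="fst")


def pairwise_difference_distance(gfm: GenotypeFrequencyMatrix) -> DistanceMatrix:
    """Average pairwise allele difference between individuals.

    d(a, b) = mean over co-observed sites of g_a(1-g_b) + g_b(1-g_a) — the
    expected allele mismatch probability when drawing one allele from each
    individual, which scales directly with genetic drift. With a completed
    matrix every site is co-observed.
    """
    G = np.asarray(gfm.values, dtype=float)
    W = (~np.isnan(G)).astype(float)
    X = np.where(np.isnan(G), 0.0, G)
    Y = np.where(np.isnan(G), 0.0, 1.0 - G)
    counts = W @ W.T
    off = ~np.eye(len(G), dtype=bool)
    if (counts[off] == 0).any():
        raise DataFormatError("some individual pair shares no observed site")
    num = X @ Y.T + Y @ X.T
    d = num / np.maximum(counts, 1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, gfm.samples, kind="pairwise-difference")


def classical_mds(dm: DistanceMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS / principal coordinates of a distance matrix.

    Double-centres the squared distances, eigendecomposes the Gram matrix
    and returns the top-``k`` coordinates scaled by sqrt(eigenvalue).
    Negative eigenvalues (legal for non-Euclidean inputs such as Jaccard)
    are reported in the returned eigenvalue vector but their axes are
    excluded; ``k`` is truncated with a warning if it exceeds the number of
    positive eigenvalues. ``k=0`` returns eigenvalues only.
    """
    D = dm.values
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int(np.sum(eigvals > max(1e-10, 1e-10 * abs(eigvals).max())))
    if k > n_pos:
        warnings.warn(f"requested {k} axes but only {n_pos} positive "
                      "eigenvalues; truncating", stacklevel=2)
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    frame = pd.DataFrame(coords, index=dm.labels,
                         columns=[f"PCo{i + 1}" for i in range(k)])
    return frame, eigvals
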