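"""Local-ancestry masking and the ancestry-specific genotype frequency matrix.

Masking removes genotype entries whose local-ancestry call is not the
ancestry class under study (typically: removing farmer-derived segments so
only hunter-gatherer-derived alleles remain). The two haplotypes of each
diploid are then averaged into a genotype frequency vector with entries
0, 0.5 or 1; sites with no retained ancestry on either haplotype are
missing, and matrix completion fills them before ordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    MASK_ANCESTRY,
    MISSING,
    DataFormatError,
    HaplotypeSet,
    LocalAncestryCalls,
    MaskedHaplotypeSet,
)

__all__ = [
    "GenotypeFrequencyMatrix",
    "select_reference_panel",
    "mask_by_ancestry",
    "mask_by_codes",
    "genotype_frequency_vector",
    "complete_matrix",
]


def select_reference_panel(proportions, threshold: float = 0.98) -> dict:
    """Assign individuals to unadmixed reference panels.

    ``proportions`` is a mapping ``individual -> {class: proportion}`` (or a
    DataFrame with individuals as rows). An individual joins a class panel
    iff that class's genome proportion is strictly greater than
    ``threshold`` (default 0.98, i.e. the ">98% associated ancestry" rule);
    all others remain unassigned (value ``None``).
    """
    try:
        items = {idx: row.to_dict() for idx, row in proportions.iterrows()}
    except AttributeError:
        items = dict(proportions)
    assignment: dict = {}
    for ind, props in items.items():
        total = float(sum(props.values()))
        if abs(total - 1.0) > 1e-6:
            raise DataFormatError(
                f"ancestry proportions for {ind!r} sum to {total}, not 1")
        assignment[ind] = None
        for cls, p in props.items():
            if p > threshold:
                assignment[ind] = cls
    return assignment


def mask_by_codes(hs: HaplotypeSet, codes: np.ndarray,
                  keep_code: int) -> MaskedHaplotypeSet:
    """Mask using a precomputed (site x haplotype) ancestry-code matrix.

    ``codes`` uses -1 for sites covered by no call; those are masked too
    (never invent ancestry).
    """
    if codes.shape != hs.alleles.shape:
        raise DataFormatError("ancestry code matrix shape mismatch")
    out = MaskedHaplotypeSet.from_haplotypes(hs) if not isinstance(hs, MaskedHaplotypeSet) \
        else hs.copy()
    drop = (codes != keep_code) & (out.alleles != MISSING)
    out.alleles[drop] = MISSING
    out.mask_reason[drop] = MASK_ANCESTRY
    return out


def mask_by_ancestry(hs: HaplotypeSet, calls: LocalAncestryCalls,
                     keep_class: str) -> MaskedHaplotypeSet:
    """Retain a site on a haplotype iff its covering interval is ``keep_class``.

    Sites covered by no interval (gaps) are masked as well. Allele values
    are never altered, only removed; masking is idempotent.
    """
    if keep_class not in calls.classes:
        raise DataFormatError(f"unknown ancestry class {keep_class!r}")
    codes = calls.site_labels(hs)
    return mask_by_codes(hs, codes, calls.classes.index(keep_class))


@dataclass
class GenotypeFrequencyMatrix:
    """Individuals x sites average alternate-allele counts (0, 0.5, 1, NaN)."""

    values: np.ndarray            # float (n_individuals, n_sites), NaN = missing
    samples: list[str]
    populations: list[str]
    site_index: np.ndarray        # indices into the originating site axis

    def __post_init__(self) -> None:
        obs = self.values[~np.isnan(self.values)]
        if not np.isin(obs, (0.0, 0.5, 1.0)).all():
            raise DataFormatError("genotype frequencies must be 0, 0.5 or 1")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


def genotype_frequency_vector(mhs: MaskedHaplotypeSet) -> GenotypeFrequencyMatrix:
    """Average each diploid's two haplotypes into one frequency vector.

    Both haplotypes retained -> their mean (0, 0.5 or 1); exactly one
    retained -> that allele; neither -> missing. Using single-haplotype
    sites (rather than discarding them) follows from marking a site missing
    only when the individual has no retained ancestry on *either* haplotype.
    """
    a = mhs.alleles.astype(float)
    a[mhs.alleles == MISSING] = np.nan
    h1 = a[:, 0::2]
    h2 = a[:, 1::2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        g = np.nanmean(np.stack([h1, h2]), axis=0)  # NaN when both missing
    return GenotypeFrequencyMatrix(values=g.T, samples=list(mhs.samples),
                                   populations=list(mhs.populations),
                                   site_index=np.arange(mhs.n_sites))


def complete_matrix(gfm: GenotypeFrequencyMatrix, rank: int | None = None,
                    shrinkage: float = 0.0, max_iter: int = 100,
                    tol: float = 1e-5) -> GenotypeFrequencyMatrix:
    """Fill missing genotype frequencies by iterative low-rank SVD completion.

    Missing entries are initialized at column (site) means, then refined by
    repeatedly taking a soft-thresholded truncated SVD of the current matrix
    and overwriting only the missing entries, until the RMS change drops
    below ``tol`` or ``max_iter`` iterations. ``rank=None`` keeps, each
    iteration, the components whose singular value is at least 5% of the
    leading one. Observed entries are never touched; filled values are
    clipped to [0, 1]. All-missing sites are dropped with a warning.
    ``max_iter=0`` returns the column-mean initialization itself.
    """
    X = np.asarray(gfm.values, dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return gfm
    all_missing = miss.all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} sites with no observed "
                      "genotype", stacklevel=2)
        X = X[:, ~all_missing]
        miss = miss[:, ~all_missing]
    site_index = gfm.site_index[~all_missing] if all_missing.any() else gfm.site_index
    if not miss.any():
        return _CompletedGenotypeFrequencyMatrix(values=X, samples=gfm.samples,
                                                 populations=gfm.populations,
                                                 site_index=site_index)

    col_means = np.nanmean(X, axis=0)
    Z = np.where(miss, col_means[None, :], X)
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        s_thr = np.maximum(s - shrinkage, 0.0)
        if rank is None:
            r = max(1, int(np.sum(s_thr >= 0.05 * s_thr[0])))
        else:
            r = min(rank, s_thr.size)
        approx = (U[:, :r] * s_thr[:r]) @ Vt[:r]
        new = np.where(miss, approx, X)
        delta = float(np.sqrt(np.mean((new[miss] - Z[miss]) ** 2)))
        Z = new
        if delta < tol:
            break
    Z = np.where(miss, np.clip(Z, 0.0, 1.0), X)
    return _CompletedGenotypeFrequencyMatrix(values=Z, samples=gfm.samples,
                                             populations=gfm.populations,
                                             site_index=site_index)


class _CompletedGenotypeFrequencyMatrix(GenotypeFrequencyMatrix):
    """Post-completion variant: continuous entries in [0,1], no missing."""

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise DataFormatError("completed matrix may not contain missing entries")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise DataFormatError("completed frequencies must lie in [0,1]")
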