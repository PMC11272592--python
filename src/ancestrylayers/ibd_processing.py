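"""Post-processing of identity-by-descent segment calls.

The published pipeline detects IBD on the ancestry-masked haplotypes, merges
blocks separated by at most a 0.6 cM gap when at most one allele mismatch
occurs across the gap-plus-blocks region, keeps only segments shared between
individuals of *different* populations exceeding 1 cM, and masks those
segments on the two haplotypes that carry them. A naive exact-match detector
is provided for synthetic phased data (real calls come from an HMM caller
and are consumed as a TSV).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    IBD_COLUMNS,
    MASK_IBD,
    MISSING,
    DataFormatError,
    HaplotypeSet,
    IBDSegmentSet,
    MaskedHaplotypeSet,
)

__all__ = [
    "detect_ibd_exact",
    "merge_ibd_blocks",
    "filter_cross_population",
    "mask_ibd_segments",
]


def detect_ibd_exact(hs: HaplotypeSet, min_len_cm: float = 1.0) -> IBDSegmentSet:
    """Maximal identical-allele runs between every haplotype pair.

    Intended for synthetic data (no missing entries allowed). A run over
    sites ``i..j`` is reported iff its cM span ``cm[j] - cm[i]`` is at least
    ``min_len_cm``. Segments are half-open in bp: ``[positions[i],
    positions[j] + 1)``.
    """
    if (hs.alleles == MISSING).any():
        raise DataFormatError("exact IBD detection requires complete haplotypes")
    n_hap = hs.alleles.shape[1]
    names = hs.haplotype_names()
    rows = []
    A = hs.alleles
    for a in range(n_hap):
        for b in range(a + 1, n_hap):
            mism = np.flatnonzero(A[:, a] != A[:, b])
            bounds = np.concatenate(([-1], mism, [hs.n_sites]))
            for k in range(len(bounds) - 1):
                i, j = bounds[k] + 1, bounds[k + 1] - 1
                if j <= i:
                    continue
                span = hs.cm[j] - hs.cm[i]
                if span >= min_len_cm:
                    sa, ha = names[a].rsplit("_", 1)
                    sb, hb = names[b].rsplit("_", 1)
                    rows.append((sa, int(ha), sb, int(hb), hs.chrom,
                                 int(hs.positions[i]), int(hs.positions[j]) + 1,
                                 np.nan, float(span)))
    return IBDSegmentSet(pd.DataFrame(rows, columns=IBD_COLUMNS))


def _cm_at(hs: HaplotypeSet, bp: float) -> float:
    return float(np.interp(bp, hs.positions, hs.cm))


def merge_ibd_blocks(segments: IBDSegmentSet, hs: HaplotypeSet,
                     gap_max_cm: float = 0.6,
                     max_inconsistent: int = 1) -> IBDSegmentSet:
    """Merge nearby IBD blocks of the same haplotype pair.

    Two consecutive blocks merge iff their cM gap is at most ``gap_max_cm``
    and the two haplotypes disagree at no more than ``max_inconsistent``
    sites across the union of both blocks and the gap. Merging proceeds
    transitively left-to-right; blocks of different haplotype pairs are
    never merged. Idempotent: merging a merged set changes nothing.
    """
    t = segments.table
    if not len(t):
        return segments
    out = []
    for (id1, hap1, id2, hap2, chrom), grp in t.groupby(
            ["id1", "hap1", "id2", "hap2", "chrom"], sort=False):
        ca = hs.haplotype_column(id1, int(hap1))
        cb = hs.haplotype_column(id2, int(hap2))
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = [row.start, row.end]
                continue
            gap_cm = _cm_at(hs, row.start) - _cm_at(hs, cur[1])
            lo = np.searchsorted(hs.positions, cur[0], side="left")
            hi = np.searchsorted(hs.positions, row.end, side="left")
            mism = int(np.sum(hs.alleles[lo:hi, ca] != hs.alleles[lo:hi, cb]))
            if gap_cm <= gap_max_cm and mism <= max_inconsistent:
                cur[1] = max(cur[1], row.end)
            else:
                out.append((id1, hap1, id2, hap2, chrom, cur[0], cur[1]))
                cur = [row.start, row.end]
        out.append((id1, hap1, id2, hap2, chrom, cur[0], cur[1]))
    merged = pd.DataFrame(out, columns=["id1", "hap1", "id2", "hap2",
                                        "chrom", "start", "end"])
    merged["lod"] = np.nan
    merged["length_cm"] = [
        _cm_at(hs, r.end - 1) - _cm_at(hs, r.start)
        for r in merged.itertuples(index=False)]
    extra = [c for c in ("pop1", "pop2") if c in t.columns]
    if extra:
        pops = dict(zip(hs.samples, hs.populations))
        merged["pop1"] = merged["id1"].map(pops)
        merged["pop2"] = merged["id2"].map(pops)
    return IBDSegmentSet(merged)


def filter_cross_population(segments: IBDSegmentSet, hs: HaplotypeSet,
                            min_len_cm: float = 1.0) -> IBDSegmentSet:
    """Keep only segments shared across populations and exceeding ``min_len_cm``.

    Retention is strict (> 1 cM by default, matching "exceeding 1 cM");
    within-population segments are removed regardless of length.
    """
    seg = segments.with_populations(hs)
    t = seg.table
    if not len(t):
        return seg
    keep = (t["pop1"] != t["pop2"]) & (t["length_cm"] > min_len_cm)
    return IBDSegmentSet(t[keep].reset_index(drop=True))


def mask_ibd_segments(mhs: MaskedHaplotypeSet,
                      segments: IBDSegmentSet) -> MaskedHaplotypeSet:
    """Mask every site inside each retained segment on its two named haplotypes.

    Only the two haplotypes recorded on a segment are touched (not every
    carrier of the region); entries already missing keep their original
    provenance code.
    """
    out = mhs.copy()
    for row in segments.table.itertuples(index=False):
        if row.chrom != mhs.chrom:
            continue
        cols = [mhs.haplotype_column(row.id1, int(row.hap1)),
                mhs.haplotype_column(row.id2, int(row.hap2))]
        lo = np.searchsorted(mhs.positions, row.start, side="left")
        hi = np.searchsorted(mhs.positions, row.end, side="left")
        for col in cols:
            newly = out.alleles[lo:hi, col] != MISSING
            out.alleles[lo:hi, col][newly] = MISSING
            out.mask_reason[lo:hi, col][newly] = MASK_IBD
    return out
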