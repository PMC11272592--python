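"""Core in-memory containers shared by every pipeline stage.

The pipeline decomposes phased genomes of admixed Central African
hunter-gatherer (CAHG) individuals into ancestry layers, so the central
containers are a phased 0/1 allele matrix (:class:`HaplotypeSet`), interval
annotations attached to single haplotypes (:class:`LocalAncestryCalls`,
:class:`IBDSegmentSet`), and symmetric group-level dissimilarity matrices
(:class:`DistanceMatrix`).

Conventions
-----------
* Genomic intervals are half-open ``[start, end)`` in 1-based bp.
* Haplotypes of diploid individual ``i`` occupy allele-matrix columns
  ``2*i`` and ``2*i + 1``; externally they are named ``<sample>_<1|2>``.
* Missing alleles are coded ``-1`` in the int8 allele matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: codes for the provenance of a masked (missing) entry
MASK_OBSERVED = 0
MASK_ANCESTRY = 1
MASK_IBD = 2
MASK_GAP = 3

MISSING = -1


class DataFormatError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM coordinate system, one table per chromosome.

    ``tables`` maps chromosome name to a DataFrame with ascending ``bp`` and
    non-decreasing ``cm`` columns. Interpolation is linear with clamped
    endpoints, so every physical position resolves to a cM coordinate.
    """

    tables: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for chrom, tab in self.tables.items():
            bp = np.asarray(tab["bp"], dtype=float)
            cm = np.asarray(tab["cm"], dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise DataFormatError(f"map positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise DataFormatError(f"cM positions decrease on {chrom}")

    def interpolate(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """cM coordinates for bp ``positions`` (endpoints clamped)."""
        if chrom not in self.tables:
            raise DataFormatError(f"chromosome {chrom!r} absent from genetic map")
        tab = self.tables[chrom]
        return np.interp(np.asarray(positions, dtype=float),
                         tab["bp"].to_numpy(dtype=float),
                         tab["cm"].to_numpy(dtype=float))

    def span_cm(self, chrom: str, start_bp: float, end_bp: float) -> float:
        a, b = self.interpolate(chrom, np.array([start_bp, end_bp]))
        return float(b - a)


@dataclass
class HaplotypeSet:
    """Phased 0/1 alleles: ``alleles[site, haplotype]`` with -1 = missing."""

    alleles: np.ndarray          # int8, (n_sites, 2 * n_individuals)
    positions: np.ndarray        # int64 bp, ascending
    cm: np.ndarray               # float64 cM per site
    samples: list[str]
    populations: list[str]       # one label per individual
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.alleles.shape != (self.positions.size, 2 * len(self.samples)):
            raise DataFormatError("allele matrix shape inconsistent with sites/samples")
        if len(self.populations) != len(self.samples):
            raise DataFormatError("one population label per individual required")
        if np.any(np.diff(self.positions) <= 0):
            raise DataFormatError("site positions must be strictly ascending")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise DataFormatError("alleles must be 0, 1 or -1 (missing)")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def haplotype_column(self, sample: str, hap: int) -> int:
        """Column index for haplotype ``hap`` (1 or 2) of ``sample``."""
        if hap not in (1, 2):
            raise DataFormatError(f"haplotype index must be 1 or 2, got {hap}")
        try:
            i = self.samples.index(sample)
        except ValueError:
            raise DataFormatError(f"unknown sample id {sample!r}") from None
        return 2 * i + (hap - 1)

    def haplotype_names(self) -> list[str]:
        return [f"{s}_{h}" for s in self.samples for h in (1, 2)]

    def population_of_haplotype(self, column: int) -> str:
        return self.populations[column // 2]

    def copy(self) -> "HaplotypeSet":
        return replace(self, alleles=self.alleles.copy())


@dataclass
class MaskedHaplotypeSet(HaplotypeSet):
    """HaplotypeSet whose missing entries carry a provenance code.

    ``mask_reason`` holds MASK_OBSERVED / MASK_ANCESTRY / MASK_IBD / MASK_GAP
    per entry; an entry is missing (allele -1) iff its code is non-zero.
    """

    mask_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mask_reason is None:
            self.mask_reason = np.zeros_like(self.alleles, dtype=np.int8)
        self.mask_reason = np.asarray(self.mask_reason, dtype=np.int8)
        if self.mask_reason.shape != self.alleles.shape:
            raise DataFormatError("mask_reason shape mismatch")
        if not ((self.alleles == MISSING) == (self.mask_reason != MASK_OBSERVED)).all():
            raise DataFormatError("mask_reason inconsistent with missing alleles")

    @classmethod
    def from_haplotypes(cls, hs: HaplotypeSet) -> "MaskedHaplotypeSet":
        reason = np.where(hs.alleles == MISSING, MASK_GAP, MASK_OBSERVED).astype(np.int8)
        return cls(alleles=hs.alleles.copy(), positions=hs.positions, cm=hs.cm,
                   samples=list(hs.samples), populations=list(hs.populations),
                   chrom=hs.chrom, mask_reason=reason)

    def copy(self) -> "MaskedHaplotypeSet":
        return replace(self, alleles=self.alleles.copy(),
                       mask_reason=self.mask_reason.copy())


#: canonical column order of an ancestry-call table
LOCAL_ANCESTRY_COLUMNS = ["sample", "hap", "chrom", "start", "end", "label"]


@dataclass
class LocalAncestryCalls:
    """Per-haplotype half-open genomic intervals labelled with an ancestry class.

    ``table`` columns: sample, hap (1/2), chrom, start, end, label.
    Intervals are non-overlapping and sorted per haplotype; sites covered by
    no interval have unknown ancestry and are masked in every layer.
    """

    table: pd.DataFrame
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        missing = set(LOCAL_ANCESTRY_COLUMNS) - set(t.columns)
        if missing:
            raise DataFormatError(f"ancestry table missing columns {sorted(missing)}")
        unknown = set(t["label"]) - set(self.classes)
        if unknown:
            raise DataFormatError(f"unknown ancestry labels {sorted(unknown)}")
        if (t["end"] <= t["start"]).any():
            raise DataFormatError("ancestry intervals must satisfy start < end")
        t = t.sort_values(["sample", "hap", "chrom", "start"], kind="mergesort")
        for (sample, hap, chrom), grp in t.groupby(["sample", "hap", "chrom"], sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise DataFormatError(
                    f"overlapping ancestry intervals on {sample} hap {hap} chrom {chrom}")
        self.table = t.reset_index(drop=True)

    def site_labels(self, hs: HaplotypeSet) -> np.ndarray:
        """Integer label codes per (site, haplotype); -1 where uncovered.

        Code ``k`` refers to ``self.classes[k]``.
        """
        codes = {c: k for k, c in enumerate(self.classes)}
        out = np.full((hs.n_sites, 2 * hs.n_individuals), -1, dtype=np.int8)
        pos = hs.positions
        sub = self.table[self.table["chrom"] == hs.chrom]
        for row in sub.itertuples(index=False):
            col = hs.haplotype_column(row.sample, int(row.hap))
            lo = np.searchsorted(pos, row.start, side="left")
            hi = np.searchsorted(pos, row.end, side="left")  # end exclusive
            out[lo:hi, col] = codes[row.label]
        return out


#: canonical column order of an IBD segment table
IBD_COLUMNS = ["id1", "hap1", "id2", "hap2", "chrom", "start", "end",
               "lod", "length_cm"]


@dataclass
class IBDSegmentSet:
    """Shared-haplotype intervals between two named haplotypes.

    ``table`` columns: id1, hap1, id2, hap2, chrom, start, end, lod,
    length_cm, and optionally file_cm (value read from disk when the map
    recomputed the length), pop1, pop2. Pairs are stored in canonical order
    (lexicographic by sample id then haplotype) so symmetric duplicates
    collapse.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        required = set(IBD_COLUMNS) - {"lod"}
        missing = required - set(t.columns)
        if missing:
            raise DataFormatError(f"IBD table missing columns {sorted(missing)}")
        if "lod" not in t.columns:
            t["lod"] = np.nan
        if len(t):
            if (t["end"] <= t["start"]).any():
                raise DataFormatError("IBD segments must satisfy start < end")
            if (t["length_cm"] < 0).any():
                raise DataFormatError("negative IBD segment length")
            if not t["hap1"].isin((1, 2)).all() or not t["hap2"].isin((1, 2)).all():
                raise DataFormatError("haplotype indices must be 1 or 2")
            swap = (t["id1"] > t["id2"]) | (
                (t["id1"] == t["id2"]) & (t["hap1"] > t["hap2"]))
            if swap.any():
                for a, b in (("id1", "id2"), ("hap1", "hap2")):
                    t.loc[swap, [a, b]] = t.loc[swap, [b, a]].to_numpy()
                if {"pop1", "pop2"} <= set(t.columns):
                    t.loc[swap, ["pop1", "pop2"]] = t.loc[swap, ["pop2", "pop1"]].to_numpy()
            t = t.sort_values(["id1", "hap1", "id2", "hap2", "chrom", "start"],
                              kind="mergesort").reset_index(drop=True)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def with_populations(self, hs: HaplotypeSet) -> "IBDSegmentSet":
        t = self.table.copy()
        pops = dict(zip(hs.samples, hs.populations))
        unknown = (set(t["id1"]) | set(t["id2"])) - set(hs.samples) if len(t) else set()
        if unknown:
            raise DataFormatError(f"IBD segments reference unknown samples {sorted(unknown)}")
        t["pop1"] = t["id1"].map(pops) if len(t) else pd.Series(dtype=object)
        t["pop2"] = t["id2"].map(pops) if len(t) else pd.Series(dtype=object)
        return IBDSegmentSet(t)

    def total_cm(self) -> float:
        return float(self.table["length_cm"].sum()) if len(self) else 0.0


class DistanceMatrix:
    """Symmetric group x group dissimilarities with zero diagonal.

    Thin container (labels + float matrix + ``kind`` tag) validating the
    invariants every downstream permutation statistic relies on: symmetry
    within 1e-12, exactly zero diagonal, non-negativity.
    """

    def __init__(self, values, labels, kind: str = "generic"):
        v = np.array(values, dtype=float)
        labels = list(labels)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(labels):
            raise DataFormatError("distance matrix must be square with matching labels")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise DataFormatError("distance matrix asymmetric beyond 1e-12")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if np.any(v < 0):
            raise DataFormatError("negative dissimilarity")
        self.values = v
        self.labels = labels
        self.kind = kind

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper triangle, row-major (scipy ``squareform`` order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels) -> "DistanceMatrix":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], labels, self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DistanceMatrix(kind={self.kind!r}, n={self.n})"


def align_distance_matrices(*matrices: DistanceMatrix) -> list[DistanceMatrix]:
    """Reorder all matrices to the label order of the first; labels must agree."""
    ref = matrices[0]
    for m in matrices[1:]:
        if set(m.labels) != set(ref.labels):
            raise DataFormatError("distance matrices carry different label sets")
    return [ref] + [m.reorder(ref.labels) for m in matrices[1:]]
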