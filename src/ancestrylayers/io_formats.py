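"""Readers and writers for every external format the pipeline touches.

Formats: phased VCF (read via cyvcf2, written as plain text), PLINK-style
genetic maps, msp-style local-ancestry TSV, refinedIBD-style IBD TSV, the
cultural CSV tables (traits, centroids, biome composition, cognate-coded
word lists), a NEXUS DISTANCES export for external NeighborNet plotting,
and a flat YAML run configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .datatypes import (
    IBD_COLUMNS,
    LOCAL_ANCESTRY_COLUMNS,
    MISSING,
    DataFormatError,
    DistanceMatrix,
    GeneticMap,
    HaplotypeSet,
    IBDSegmentSet,
    LocalAncestryCalls,
)

__all__ = [
    "RunConfig",
    "load_genotypes",
    "write_vcf",
    "load_genetic_map",
    "write_genetic_map",
    "load_local_ancestry",
    "write_local_ancestry",
    "load_ibd",
    "write_ibd",
    "load_culture",
    "export_distance_nexus",
    "read_distance_nexus",
]


@dataclass
class RunConfig:
    """Run configuration: input paths, thresholds, permutation settings.

    Thresholds default to the published pipeline settings: cross-population
    IBD retained above 1 cM, IBD blocks merged across gaps of at most
    0.6 cM with at most one inconsistent allele, 1,000 permutations.
    """

    vcf: str | None = None
    genetic_map: str | None = None
    local_ancestry: str | None = None
    ibd: str | None = None
    traits: str | None = None
    coordinates: str | None = None
    biomes: str | None = None
    cognates: str | None = None
    ancestry_classes: tuple[str, ...] = ("cahg", "farmer")
    keep_class: str = "cahg"
    ibd_min_len_cm: float = 1.0
    ibd_merge_gap_cm: float = 0.6
    ibd_merge_max_inconsistent: int = 1
    n_permutations: int = 1000
    rng_seed: int = 0
    adjustment: dict = field(default_factory=lambda: {"mantel": "bh", "cadm": "holm"})

    def __post_init__(self) -> None:
        if self.ibd_min_len_cm <= 0 or self.ibd_merge_gap_cm <= 0:
            raise DataFormatError("IBD thresholds must be strictly positive")
        if self.ibd_merge_max_inconsistent < 0:
            raise DataFormatError("max inconsistent sites must be non-negative")
        self.ancestry_classes = tuple(self.ancestry_classes)
        if self.keep_class not in self.ancestry_classes:
            raise DataFormatError("keep_class must be one of ancestry_classes")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# genetic map (PLINK .map dialect: chrom, id, cM, bp)
# ---------------------------------------------------------------------------

def load_genetic_map(source) -> GeneticMap:
    df = pd.read_csv(source, sep=r"\s+", header=None,
                     names=["chrom", "id", "cm", "bp"], dtype={"chrom": str})
    tables = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        tables[chrom] = grp.sort_values("bp")[["bp", "cm"]].reset_index(drop=True)
    return GeneticMap(tables)


def write_genetic_map(gmap: GeneticMap, sink) -> None:
    rows = []
    for chrom, tab in gmap.tables.items():
        for i, row in enumerate(tab.itertuples(index=False)):
            rows.append(f"{chrom}\tsite{i}\t{row.cm:.8g}\t{int(row.bp)}")
    Path(sink).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def load_genotypes(vcf_source, map_source, *, populations=None,
                   drop_multiallelic: bool = False,
                   allow_extrapolation: bool = True) -> tuple[HaplotypeSet, GeneticMap]:
    """Load a phased bi-allelic VCF plus genetic map into a HaplotypeSet.

    ``populations`` maps sample id -> population label (defaults to one
    population ``"pop"``). Multi-allelic records raise unless
    ``drop_multiallelic``; unphased genotypes always raise. Each site gets a
    cM coordinate by linear interpolation in the map; positions outside the
    map range are clamped (standard practice) unless ``allow_extrapolation``
    is False, in which case they raise.
    """
    gmap = load_genetic_map(map_source)
    vcf = VCF(str(vcf_source))
    samples = list(vcf.samples)
    positions, rows, chroms = [], [], set()
    for var in vcf:
        if len(var.ALT) != 1:
            if drop_multiallelic:
                continue
            raise DataFormatError(
                f"multi-allelic record at {var.CHROM}:{var.POS} (ALT={var.ALT})")
        gts = var.genotypes  # [[a0, a1, phased], ...]
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) == 3 and not g[2] and g[0] != MISSING and g[1] != MISSING:
                raise DataFormatError(
                    f"unphased genotype for sample {samples[i]} at {var.CHROM}:{var.POS}")
            alleles[2 * i] = g[0]
            alleles[2 * i + 1] = g[1]
        chroms.add(var.CHROM)
        positions.append(var.POS)
        rows.append(alleles)
    if len(chroms) > 1:
        raise DataFormatError("multi-chromosome VCFs are not supported per call")
    chrom = chroms.pop() if chroms else "1"
    positions = np.asarray(positions, dtype=np.int64)
    if not allow_extrapolation and chrom in gmap.tables:
        tab = gmap.tables[chrom]
        out = (positions < tab["bp"].iloc[0]) | (positions > tab["bp"].iloc[-1])
        if out.any():
            raise DataFormatError(
                f"{int(out.sum())} sites outside genetic map range on {chrom}")
    cm = gmap.interpolate(chrom, positions)
    if populations is None:
        pops = ["pop"] * len(samples)
    else:
        pops = [populations[s] for s in samples]
    hs = HaplotypeSet(alleles=np.asarray(rows, dtype=np.int8),
                      positions=positions, cm=cm, samples=samples,
                      populations=pops, chrom=chrom)
    return hs, gmap


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(hs: HaplotypeSet, sink) -> None:
    """Write a HaplotypeSet as a minimal phased bi-allelic VCF."""
    lines = [_VCF_HEADER.format(chrom=hs.chrom, samples="\t".join(hs.samples)).rstrip("\n")]
    for s in range(hs.n_sites):
        gts = []
        for i in range(hs.n_individuals):
            a, b = hs.alleles[s, 2 * i], hs.alleles[s, 2 * i + 1]
            fmt = lambda x: "." if x == MISSING else str(int(x))
            gts.append(f"{fmt(a)}|{fmt(b)}")
        lines.append(
            f"{hs.chrom}\t{int(hs.positions[s])}\tsnp{s}\tA\tG\t.\tPASS\t.\tGT\t"
            + "\t".join(gts))
    Path(sink).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# msp-style local ancestry TSV
# ---------------------------------------------------------------------------
# Dialect (fixed here; the upstream tool's column layout varies by version):
# long table with columns sample, hap (1/2), chrom, start, end, label,
# half-open [start, end) 1-based bp. Gaps are legal and mean unknown
# ancestry; such sites are masked in every layer.

def load_local_ancestry(source, classes) -> LocalAncestryCalls:
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    return LocalAncestryCalls(df[LOCAL_ANCESTRY_COLUMNS], tuple(classes))


def write_local_ancestry(calls: LocalAncestryCalls, sink) -> None:
    calls.table[LOCAL_ANCESTRY_COLUMNS].to_csv(sink, sep="\t", index=False)


# ---------------------------------------------------------------------------
# refinedIBD-style IBD TSV
# ---------------------------------------------------------------------------

def load_ibd(source, gmap: GeneticMap | None = None,
             samples: list[str] | None = None) -> IBDSegmentSet:
    """Load IBD segments; columns id1 hap1 id2 hap2 chrom start end lod length_cm.

    When a genetic map is supplied the cM length is recomputed from it and
    used downstream; the file's value is retained in ``file_cm``.
    """
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = set(IBD_COLUMNS) - set(df.columns)
    if missing:
        raise DataFormatError(f"IBD file missing columns {sorted(missing)}")
    if samples is not None and len(df):
        unknown = (set(df["id1"]) | set(df["id2"])) - set(samples)
        if unknown:
            raise DataFormatError(f"IBD file references unknown samples {sorted(unknown)}")
    if gmap is not None and len(df):
        df["file_cm"] = df["length_cm"]
        df["length_cm"] = [gmap.span_cm(r.chrom, r.start, r.end)
                           for r in df.itertuples(index=False)]
    return IBDSegmentSet(df)


def write_ibd(segments: IBDSegmentSet, sink) -> None:
    cols = [c for c in IBD_COLUMNS if c in segments.table.columns]
    segments.table[cols].to_csv(sink, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cultural tables
# ---------------------------------------------------------------------------

def load_culture(traits_csv, coords_csv, biome_csv, cognates_csv):
    """Load trait/coordinate/biome/cognate tables, reconciling group names.

    Returns ``(trait_df, coords_df, biome_df, cognate_df)`` restricted to the
    intersection of group names; a warning reports groups dropped from any
    file. Trait cells must be binary; latitudes/longitudes must be in range.
    """
    traits = pd.read_csv(traits_csv, index_col=0)
    if not traits.isin((0, 1)).all().all():
        raise DataFormatError("trait matrix must be binary presence/absence")
    coords = pd.read_csv(coords_csv, index_col=0)
    if not {"lat", "lon"} <= set(coords.columns):
        raise DataFormatError("coordinate file needs 'lat' and 'lon' columns")
    bad = (coords["lat"].abs() > 90) | (coords["lon"].abs() > 180)
    if bad.any():
        raise DataFormatError(
            f"out-of-range coordinates for groups {list(coords.index[bad])}")
    biomes = pd.read_csv(biome_csv, index_col=0)
    cognates = pd.read_csv(cognates_csv)

    sets = {"traits": set(traits.index), "coordinates": set(coords.index),
            "biomes": set(biomes.index), "cognates": set(cognates["group"])}
    common = set.intersection(*sets.values())
    for name, s in sets.items():
        extra = s - common
        if extra:
            warnings.warn(f"groups {sorted(extra)} only partially covered "
                          f"(present in {name}); using intersection", stacklevel=2)
    order = sorted(common)
    return (traits.loc[order], coords.loc[order], biomes.loc[order],
            cognates[cognates["group"].isin(common)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# NEXUS DISTANCES export (for external NeighborNet / SplitsTree plotting)
# ---------------------------------------------------------------------------

def _nexus_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]{}/\\,;:=*'\"`<>") or label == "":
        return "'" + label.replace("'", "''") + "'"
    return label


def export_distance_nexus(dm: DistanceMatrix, sink) -> str:
    """Write a NEXUS DISTANCES block (full symmetric matrix, labels kept)."""
    n = dm.n
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={n};",
             "    TAXLABELS " + " ".join(_nexus_label(l) for l in dm.labels) + ";",
             "END;", "", "BEGIN DISTANCES;", f"    DIMENSIONS NTAX={n};",
             "    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;", "    MATRIX"]
    for i, label in enumerate(dm.labels):
        row = " ".join(f"{dm.values[i, j]:.10g}" for j in range(n))
        lines.append(f"        {_nexus_label(label)} {row}")
    lines += ["    ;", "END;", ""]
    text = "\n".join(lines)
    if sink is not None:
        Path(sink).write_text(text)
    return text


def read_distance_nexus(source) -> DistanceMatrix:
    """Parse the DISTANCES block written by :func:`export_distance_nexus`."""
    text = Path(source).read_text() if not str(source).lstrip().startswith("#NEXUS") \
        else str(source)
    in_matrix = False
    labels, rows = [], []
    for raw in text.splitlines():
        line = raw.strip()
        if line.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if line == ";" or line.upper().startswith("END"):
                break
            if not line:
                continue
            if line.startswith("'"):
                end = line.index("'", 1)
                while end + 1 < len(line) and line[end + 1] == "'":
                    end = line.index("'", end + 2)
                label = line[1:end].replace("''", "'")
                rest = line[end + 1:]
            else:
                label, _, rest = line.partition(" ")
            labels.append(label)
            rows.append([float(x) for x in rest.split()])
    return DistanceMatrix(np.array(rows), labels)
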