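"""Ancestry-layer decomposition and the timing classification of exchange.

The core procedure: decompose the phased genomes into four nested layers —

* ``full``          all genomic segments (no masking),
* ``cahg``          only hunter-gatherer-ancestry segments (farmer masked),
* ``cahg_no_ibd``   additionally masking cross-population IBD > 1 cM, i.e.
                    the residue not attributable to recent exchange,
* ``bantu``         the complement: only farmer-ancestry segments —

compute layer-specific Hudson FST matrices, run the Mantel association
battery of each layer (plus geography and ecology) against a cultural
distance matrix with Benjamini-Hochberg adjustment, and classify the timing
of cultural exchange from the pattern of significant layers:

======================  ======  =====  ===========  =================================
pattern (adjusted sig)  full    cahg   cahg_no_ibd  classification
======================  ======  =====  ===========  =================================
none                    -       -      -            no_signal
full only               x       -      -            recent_farmer_origin
cahg (any combination)  any     x      any          prefarming_with_continued_exchange
no-IBD residue only     -       -      x            prefarming_only
full + residue          x       -      x            recent_farmer_origin
======================  ======  =====  ===========  =================================

Patterns outside the three idealized predictions are mapped by the
precedence cahg > full > residue-only; the raw pattern is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    DataFormatError,
    DistanceMatrix,
    HaplotypeSet,
    IBDSegmentSet,
    LocalAncestryCalls,
    MaskedHaplotypeSet,
)
from .ancestry_masking import mask_by_ancestry, mask_by_codes
from .ibd_processing import mask_ibd_segments
from .io_formats import RunConfig
from .matrix_association import mantel_test, p_adjust
from .popgen_stats import fst_matrix, site_frequencies

__all__ = [
    "AncestryLayerSet",
    "TimingClassification",
    "LAYER_NAMES",
    "build_layers",
    "layered_association",
    "classify_timing",
    "simulate_and_classify",
]

LAYER_NAMES = ("full", "cahg", "cahg_no_ibd", "bantu")

CLASSIFICATIONS = ("recent_farmer_origin", "prefarming_with_continued_exchange",
                   "prefarming_only", "no_signal")


@dataclass
class AncestryLayerSet:
    """The four masked views of one cohort; unmasked sets are nested."""

    full: MaskedHaplotypeSet
    cahg: MaskedHaplotypeSet
    cahg_no_ibd: MaskedHaplotypeSet
    bantu: MaskedHaplotypeSet

    def __post_init__(self) -> None:
        obs = {name: getattr(self, name).alleles != MISSING for name in LAYER_NAMES}
        if (obs["cahg_no_ibd"] & ~obs["cahg"]).any():
            raise DataFormatError("layer nesting violated: cahg_no_ibd not in cahg")
        if (obs["cahg"] & ~obs["full"]).any():
            raise DataFormatError("layer nesting violated: cahg not in full")
        if (obs["bantu"] & obs["cahg"]).any():
            raise DataFormatError("bantu and cahg layers overlap")

    def __getitem__(self, name: str) -> MaskedHaplotypeSet:
        if name not in LAYER_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class TimingClassification:
    classification: str
    pattern: dict              # layer -> bool (adjusted significance)
    alpha: float
    table: pd.DataFrame        # the full association table


def build_layers(hs: HaplotypeSet,
                 calls: LocalAncestryCalls | np.ndarray,
                 ibd_filtered: IBDSegmentSet,
                 keep_class: str = "cahg",
                 complement_class: str = "farmer") -> AncestryLayerSet:
    """Two-step masking: ancestry mask, then cross-population IBD mask.

    ``calls`` may be a :class:`LocalAncestryCalls` table or a precomputed
    (site x haplotype) ancestry-code matrix (0 = keep class, as produced by
    the synthetic generator). ``ibd_filtered`` must already be restricted to
    cross-population segments above the length threshold.
    """
    full = MaskedHaplotypeSet.from_haplotypes(hs)
    if isinstance(calls, LocalAncestryCalls):
        cahg = mask_by_ancestry(hs, calls, keep_class)
        bantu = mask_by_ancestry(hs, calls, complement_class)
    else:
        cahg = mask_by_codes(hs, calls, 0)
        bantu = mask_by_codes(hs, calls, 1)
    cahg_no_ibd = mask_ibd_segments(cahg, ibd_filtered)
    return AncestryLayerSet(full=full, cahg=cahg, cahg_no_ibd=cahg_no_ibd,
                            bantu=bantu)


#: association-table rows and the layer each genetic row derives from
GENETIC_ROWS = {"genes_full": "full", "genes_cahg": "cahg",
                "genes_cahg_no_ibd": "cahg_no_ibd", "genes_bantu": "bantu"}


def layered_association(layers: AncestryLayerSet,
                        cultural: DistanceMatrix,
                        covariates: dict[str, DistanceMatrix],
                        config: RunConfig | None = None,
                        populations: list[str] | None = None):
    """The per-layer Mantel battery against one cultural distance matrix.

    Rows: geography/ecology covariates plus one per ancestry layer (its
    Hudson FST matrix vs the cultural matrix). P values are adjusted with
    Benjamini-Hochberg within the table. A layer with too few usable sites
    yields an NA row rather than an error. Returns ``(table, fst_matrices)``.
    """
    config = config or RunConfig()
    if cultural.n < 3:
        raise DataFormatError("at least 3 groups required")
    rows = []
    fst_mats: dict[str, DistanceMatrix] = {}
    for name, dm in covariates.items():
        res = mantel_test(cultural, dm, n_perm=config.n_permutations,
                          seed=config.rng_seed)
        rows.append((name, res.rho, res.p))
    for row_name, layer_name in GENETIC_ROWS.items():
        layer = layers[layer_name]
        try:
            sft = site_frequencies(layer, populations)
            if sft.n_sites == 0:
                raise DataFormatError("zero usable sites")
            fst = fst_matrix(sft)
        except DataFormatError:
            rows.append((row_name, np.nan, np.nan))
            continue
        fst_mats[layer_name] = fst
        res = mantel_test(cultural, fst, n_perm=config.n_permutations,
                          seed=config.rng_seed)
        rows.append((row_name, res.rho, res.p))
    table = pd.DataFrame(rows, columns=["predictor", "rho", "p"])
    ok = table["p"].notna()
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = p_adjust(table.loc[ok, "p"], method="bh")
    table["p_adjusted"] = adj
    table["n_permutations"] = config.n_permutations
    table["seed"] = config.rng_seed
    return table, fst_mats


def classify_timing(table: pd.DataFrame, alpha: float = 0.05) -> TimingClassification:
    """Map the adjusted-significance pattern of the three mandatory layers.

    A significant hunter-gatherer-ancestry layer (with or without the
    IBD-masked residue) indicates exchange predating farming that continued
    afterwards; significance confined to the full genome indicates recent
    introgression from farmers along with genes; significance confined to
    the IBD-masked residue indicates purely pre-farming exchange.
    """
    idx = table.set_index("predictor")
    required = ["genes_full", "genes_cahg", "genes_cahg_no_ibd"]
    missing = [r for r in required if r not in idx.index]
    if missing:
        raise DataFormatError(f"association table lacks rows {missing}")
    sig = {}
    for r in required:
        p = idx.loc[r, "p_adjusted"]
        if not np.isfinite(p):
            raise DataFormatError(f"adjusted p missing for layer row {r!r}")
        sig[r] = bool(p < alpha)
    full, cahg, residue = (sig["genes_full"], sig["genes_cahg"],
                           sig["genes_cahg_no_ibd"])
    if cahg:
        label = "prefarming_with_continued_exchange"
    elif full:
        label = "recent_farmer_origin"
    elif residue:
        label = "prefarming_only"
    else:
        label = "no_signal"
    return TimingClassification(classification=label, pattern=sig, alpha=alpha,
                                table=table)


def simulate_and_classify(scenario: str, seed: int,
                          n_permutations: int = 999,
                          sim_config=None) -> TimingClassification:
    """End-to-end synthetic run: simulate, mask, associate, classify.

    Generates a cohort under one trait scenario, masks with the true
    ancestry and cross-population IBD, runs the layered Mantel battery
    against the simulated trait distances plus geography and ecology, and
    returns the timing classification with its statistics table attached.
    """
    from .distances import gower_matrix, greatcircle_matrix, jaccard_matrix
    from .ibd_processing import filter_cross_population
    from .synthetic_data import SimulationConfig, simulate_cohort, simulate_traits

    sim = sim_config or SimulationConfig(rng_seed=seed, trait_scenario=scenario)
    cohort = simulate_cohort(sim)
    kept = filter_cross_population(cohort.ibd, cohort.haplotypes,
                                   sim.ibd_length_min_cm)
    layers = build_layers(cohort.haplotypes, cohort.ancestry_codes, kept)
    traits = simulate_traits(cohort, sim)
    cfg = RunConfig(n_permutations=n_permutations, rng_seed=seed)
    table, _ = layered_association(
        layers, jaccard_matrix(traits),
        {"geography": greatcircle_matrix(cohort.centroids),
         "ecology": gower_matrix(cohort.biomes)}, cfg)
    return classify_timing(table)
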