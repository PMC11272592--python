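"""Synthetic admixed cohorts with known ancestry tracts, IBD and culture.

The generator emulates the demographic structure the layered-ancestry method
assumes: two deeply divergent ancestral gene pools (hunter-gatherer and
farmer), a single admixture pulse ``t`` generations ago that leaves each
admixed haplotype a mosaic of exponentially distributed ancestry tracts
(mean 100/t cM), hierarchical hunter-gatherer population structure (two
regional clusters of demes, echoing the western/eastern split of Central
African groups), and recent between-deme haplotype copying that implants
cross-population IBD segments longer than 1 cM with exact ground truth.

Cultural trait matrices are generated under three competing causal
scenarios — sharing driven by farmer contact, by hunter-gatherer exchange,
or by ecology — so the downstream timing classification can be validated
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    DataFormatError,
    GeneticMap,
    HaplotypeSet,
    IBDSegmentSet,
    LocalAncestryCalls,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_traits",
    "simulate_word_counts",
    "scenario_similarity",
]

SCENARIOS = ("farmer_borrowing", "hg_exchange", "ecology")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a cohort of 10 demes x 10 diploids typed at 3,000 SNPs
    on one 100 cM chromosome; admixture 50 generations ago (mean tract
    2 cM); Balding-Nichols divergence 0.2 between the two ancestral pools,
    0.05 between regional clusters and 0.015 between demes within a cluster;
    farmer admixture fractions spread over 0.05-0.55 across demes.
    """

    n_demes: int = 10
    n_individuals_per_deme: int = 10
    n_sites: int = 3000
    chromosome_length_cm: float = 100.0
    chromosome_length_bp: int = 100_000_000
    ancestral_divergence_F: dict = field(
        default_factory=lambda: {"cahg": 0.25, "farmer": 0.25})
    cluster_divergence_F: float = 0.05
    deme_divergence_F: float = 0.015
    n_clusters: int = 2
    admixture_time_generations: int = 50
    admixture_fraction: Optional[np.ndarray] = None  # per deme; None -> spread 0.05..0.55
    recent_exchange_matrix: Optional[np.ndarray] = None  # deme x deme Poisson means
    exchange_rate_within: float = 8.0   # used when matrix is None
    exchange_rate_between: float = 0.2
    ibd_length_min_cm: float = 1.0
    ibd_length_mean_extra_cm: float = 1.5
    trait_scenario: str = "hg_exchange"
    n_traits: int = 80
    trait_base_rate: float = 0.10
    trait_share_weight: float = 0.80
    zip_params: dict = field(default_factory=lambda: {
        "beta": (np.log(2.0), 0.8), "gamma": (-1.0, 0.7)})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cls, F in self.ancestral_divergence_F.items():
            if not 0 < F < 1:
                raise DataFormatError(f"divergence F for {cls!r} must lie in (0,1)")
        if self.admixture_time_generations < 1:
            raise DataFormatError("admixture time must be >= 1 generation")
        if self.trait_scenario not in SCENARIOS:
            raise DataFormatError(f"trait_scenario must be one of {SCENARIOS}")
        if self.admixture_fraction is not None:
            a = np.asarray(self.admixture_fraction, dtype=float)
            if a.shape != (self.n_demes,) or np.any(a < 0) or np.any(a > 1):
                raise DataFormatError("admixture fractions must be per-deme in [0,1]")
            self.admixture_fraction = a
        if self.recent_exchange_matrix is not None:
            r = np.asarray(self.recent_exchange_matrix, dtype=float)
            if (r.shape != (self.n_demes, self.n_demes) or np.any(r < 0)
                    or np.any(np.diag(r) != 0)):
                raise DataFormatError(
                    "exchange matrix must be deme x deme, non-negative, zero diagonal")
            self.recent_exchange_matrix = r
        # mean tract length is 100/t cM; the chromosome must hold several tracts
        if self.chromosome_length_cm < 2 * 100.0 / self.admixture_time_generations:
            raise DataFormatError(
                "chromosome shorter than the minimum tract resolution (2 mean tracts)")


@dataclass
class SyntheticCohort:
    """A simulated cohort with full ground truth for every pipeline stage."""

    haplotypes: HaplotypeSet
    ancestry: LocalAncestryCalls
    ancestry_codes: np.ndarray        # (n_sites, n_hap) 0=cahg 1=farmer, truth
    ibd: IBDSegmentSet                # implanted cross-deme IBD, truth
    gmap: GeneticMap
    demes: list[str]
    centroids: pd.DataFrame           # deme -> lat, lon
    biomes: pd.DataFrame              # deme x biome composition (fractions)
    admixture_fraction: np.ndarray    # per deme
    clusters: np.ndarray              # per deme cluster id
    config: SimulationConfig


def _balding_nichols(rng, p, F):
    """Draw descendant frequencies around ``p`` with divergence ``F``."""
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _draw_tracts(rng, length_cm, mean_cm, alpha):
    """One haplotype's ancestry mosaic: list of (start_cm, end_cm, code)."""
    edges = [0.0]
    while edges[-1] < length_cm:
        edges.append(edges[-1] + rng.exponential(mean_cm))
    edges[-1] = length_cm
    codes = (rng.random(len(edges) - 1) < alpha).astype(np.int8)
    return np.asarray(edges), codes


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort; deterministic under ``config.rng_seed``."""
    c = config
    streams = np.random.SeedSequence(c.rng_seed).spawn(6)
    rng_freq, rng_tract, rng_allele, rng_exch, rng_geo, _ = \
        (np.random.default_rng(s) for s in streams)

    demes = [f"D{i + 1}" for i in range(c.n_demes)]
    clusters = np.arange(c.n_demes) * c.n_clusters // c.n_demes
    n_hap = 2 * c.n_demes * c.n_individuals_per_deme

    # --- ancestral and deme-level allele frequencies ----------------------
    p_anc = rng_freq.uniform(0.1, 0.9, c.n_sites)
    freq_cahg = _balding_nichols(rng_freq, p_anc, c.ancestral_divergence_F["cahg"])
    freq_farmer = _balding_nichols(rng_freq, p_anc, c.ancestral_divergence_F["farmer"])
    freq_cluster = np.stack([
        _balding_nichols(rng_freq, freq_cahg, c.cluster_divergence_F)
        for _ in range(c.n_clusters)])
    freq_deme = np.stack([
        _balding_nichols(rng_freq, freq_cluster[clusters[d]], c.deme_divergence_F)
        for d in range(c.n_demes)])

    if c.admixture_fraction is None:
        # admixture fractions spread over 0.05..0.55, shuffled so that farmer
        # contact is independent of the hunter-gatherer cluster structure
        alphas = rng_freq.permutation(np.linspace(0.05, 0.55, c.n_demes))
    else:
        alphas = np.asarray(c.admixture_fraction, dtype=float)

    # --- site coordinate systems -----------------------------------------
    positions = np.unique(np.linspace(1, c.chromosome_length_bp, c.n_sites)
                          .round().astype(np.int64))
    if positions.size != c.n_sites:
        raise DataFormatError("n_sites too large for chromosome length in bp")
    cm_per_bp = c.chromosome_length_cm / c.chromosome_length_bp
    site_cm = positions * cm_per_bp
    gmap = GeneticMap({"1": pd.DataFrame(
        {"bp": [1, c.chromosome_length_bp],
         "cm": [1 * cm_per_bp, c.chromosome_length_cm]})})

    # --- ancestry mosaics and alleles -------------------------------------
    mean_tract = 100.0 / c.admixture_time_generations
    codes = np.empty((c.n_sites, n_hap), dtype=np.int8)
    samples, populations = [], []
    for d in range(c.n_demes):
        for i in range(c.n_individuals_per_deme):
            samples.append(f"{demes[d]}_I{i + 1:02d}")
            populations.append(demes[d])
    for h in range(n_hap):
        deme = h // (2 * c.n_individuals_per_deme)
        edges, tcodes = _draw_tracts(rng_tract, c.chromosome_length_cm,
                                     mean_tract, alphas[deme])
        codes[:, h] = tcodes[np.clip(np.searchsorted(edges, site_cm, side="right") - 1,
                                     0, len(tcodes) - 1)]

    u = rng_allele.random((c.n_sites, n_hap))
    deme_of_hap = np.repeat(np.arange(c.n_demes), 2 * c.n_individuals_per_deme)
    hg_f = freq_deme[deme_of_hap].T        # (n_sites, n_hap)
    alleles = np.where(codes == 0, (u < hg_f), (u < freq_farmer[:, None])) \
        .astype(np.int8)

    # --- recent exchange: copy blocks between demes, log as true IBD ------
    if c.recent_exchange_matrix is None:
        same = clusters[:, None] == clusters[None, :]
        rates = np.where(same, c.exchange_rate_within, c.exchange_rate_between)
        np.fill_diagonal(rates, 0.0)
    else:
        rates = c.recent_exchange_matrix
    used: dict[int, list[tuple[float, float]]] = {}
    ibd_rows = []
    for i in range(c.n_demes):
        for j in range(c.n_demes):
            if i == j or rates[i, j] == 0:
                continue
            for _ in range(rng_exch.poisson(rates[i, j])):
                for _try in range(20):
                    src = int(rng_exch.integers(0, 2 * c.n_individuals_per_deme))
                    dst = int(rng_exch.integers(0, 2 * c.n_individuals_per_deme))
                    hsrc = 2 * c.n_individuals_per_deme * i + src
                    hdst = 2 * c.n_individuals_per_deme * j + dst
                    length = c.ibd_length_min_cm + rng_exch.exponential(
                        c.ibd_length_mean_extra_cm)
                    start = rng_exch.uniform(0, c.chromosome_length_cm - length)
                    window = (start, start + length)
                    if any(not (window[1] <= a or window[0] >= b)
                           for h in (hsrc, hdst) for a, b in used.get(h, [])):
                        continue
                    lo = np.searchsorted(site_cm, window[0])
                    hi = np.searchsorted(site_cm, window[1])
                    if hi - lo < 2:
                        continue
                    alleles[lo:hi, hdst] = alleles[lo:hi, hsrc]
                    codes[lo:hi, hdst] = codes[lo:hi, hsrc]
                    used.setdefault(hsrc, []).append(window)
                    used.setdefault(hdst, []).append(window)
                    start_bp = int(np.ceil(window[0] / cm_per_bp))
                    end_bp = int(np.floor(window[1] / cm_per_bp)) + 1
                    ibd_rows.append((samples[hsrc // 2], hsrc % 2 + 1,
                                     samples[hdst // 2], hdst % 2 + 1,
                                     "1", max(1, start_bp), end_bp, np.nan, length))
                    break

    hs = HaplotypeSet(alleles=alleles, positions=positions, cm=site_cm,
                      samples=samples, populations=populations, chrom="1")
    # ancestry intervals are derived from the final per-site codes (after
    # exchange copying) so the interval table and the truth matrix agree;
    # interval boundaries sit halfway between the flanking sites
    tract_rows = []
    for h in range(n_hap):
        sample, hap = samples[h // 2], h % 2 + 1
        col = codes[:, h]
        change = np.flatnonzero(np.diff(col)) + 1  # run starts (site index)
        starts = np.concatenate(([0], change))
        bounds = [1] + [int(positions[s - 1] + positions[s]) // 2 for s in change] \
            + [c.chromosome_length_bp + 1]
        for k, s in enumerate(starts):
            tract_rows.append((sample, hap, "1", bounds[k], bounds[k + 1],
                               ("cahg", "farmer")[col[s]]))
    ancestry = LocalAncestryCalls(
        pd.DataFrame(tract_rows, columns=["sample", "hap", "chrom",
                                          "start", "end", "label"]),
        classes=("cahg", "farmer"))
    ibd = IBDSegmentSet(pd.DataFrame(
        ibd_rows, columns=["id1", "hap1", "id2", "hap2", "chrom",
                           "start", "end", "lod", "length_cm"])).with_populations(hs)

    # --- geography and ecology --------------------------------------------
    centroids = pd.DataFrame(
        {"lat": rng_geo.uniform(-5, 5, c.n_demes),
         "lon": rng_geo.uniform(10, 30, c.n_demes)}, index=demes)
    eco_type = rng_geo.integers(0, 2, c.n_demes)
    type_means = np.array([[0.60, 0.30, 0.05, 0.05],
                           [0.05, 0.05, 0.60, 0.30]])
    comp = np.stack([rng_geo.dirichlet(type_means[t] * 50) for t in eco_type])
    biomes = pd.DataFrame(comp, index=demes,
                          columns=[f"biome_{k + 1}" for k in range(4)])

    return SyntheticCohort(haplotypes=hs, ancestry=ancestry, ancestry_codes=codes,
                           ibd=ibd, gmap=gmap, demes=demes, centroids=centroids,
                           biomes=biomes, admixture_fraction=alphas,
                           clusters=clusters, config=c)


def scenario_similarity(cohort: SyntheticCohort, config: SimulationConfig) -> np.ndarray:
    """Deme x deme similarity in [0,1] driving trait sharing under the scenario."""
    c = config
    if c.trait_scenario == "farmer_borrowing":
        a = cohort.admixture_fraction
        diff = np.abs(a[:, None] - a[None, :])
        return 1.0 - diff / max(diff.max(), 1e-12)
    if c.trait_scenario == "hg_exchange":
        if c.recent_exchange_matrix is None:
            same = cohort.clusters[:, None] == cohort.clusters[None, :]
            r = np.where(same, c.exchange_rate_within, c.exchange_rate_between)
            np.fill_diagonal(r, 0.0)
        else:
            r = c.recent_exchange_matrix
        r = (r + r.T) / 2.0
        return r / max(r.max(), 1e-12)
    # ecology: similarity = 1 - range-normalised Gower dissimilarity of biomes
    from .distances import gower_matrix
    g = gower_matrix(cohort.biomes).values
    return 1.0 - g / max(g.max(), 1e-12)


def simulate_traits(cohort: SyntheticCohort, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Binary deme x trait matrix whose sharing tracks the scenario driver.

    Each trait originates in a random seed deme and spreads to deme ``d``
    with probability ``base + weight * S[seed, d]`` where ``S`` is the
    scenario similarity; with an all-zero driver traits are independent
    across demes at the base rate.
    """
    c = config
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(c.rng_seed).spawn(6)[5])
    S = scenario_similarity(cohort, c)
    n = c.n_demes
    traits = np.zeros((n, c.n_traits), dtype=np.int8)
    for k in range(c.n_traits):
        seed_deme = int(rng.integers(0, n))
        p = np.clip(c.trait_base_rate + c.trait_share_weight * S[seed_deme],
                    0.0, 0.95)
        traits[:, k] = rng.random(n) < p
        traits[seed_deme, k] = 1
    return pd.DataFrame(traits, index=cohort.demes,
                        columns=[f"trait_{k + 1}" for k in range(c.n_traits)])


def simulate_word_counts(X: np.ndarray, zip_params: dict,
                         seed: int) -> np.ndarray:
    """Dyadic shared-word counts under a zero-inflated Poisson model.

    ``log lambda = b0 + X @ beta`` and ``logit pi = g0 + X @ gamma`` where
    ``zip_params["beta"]`` and ``["gamma"]`` each carry the intercept first.
    ``X`` columns must be standardized. A structural zero occurs with
    probability pi, otherwise the count is Poisson(lambda) (which may itself
    be zero).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(zip_params["beta"], dtype=float)
    gamma = np.asarray(zip_params["gamma"], dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    if design.shape[1] != beta.size or design.shape[1] != gamma.size:
        raise DataFormatError("zip_params length must equal 1 + n_predictors")
    eta = design @ beta
    with np.errstate(over="ignore"):
        lam = np.exp(eta)
    if not np.all(np.isfinite(lam)):
        raise DataFormatError("non-finite Poisson rate lambda")
    with np.errstate(over="ignore"):
        pi = 1.0 / (1.0 + np.exp(-(design @ gamma)))
    rng = np.random.default_rng(seed)
    structural = rng.random(len(X)) < pi
    counts = rng.poisson(lam)
    counts[structural] = 0
    return counts
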