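import numpy as np
import pandas as pd
import pytest

from ancestrylayers.datatypes import (
    DistanceMatrix,
    HaplotypeSet,
    IBDSegmentSet,
    LocalAncestryCalls,
)
from ancestrylayers.synthetic_data import SimulationConfig, simulate_cohort


def make_haplotypes(alleles, positions=None, cm=None, samples=None,
                    populations=None, chrom="1"):
    """Small helper: HaplotypeSet from a (sites x haplotypes) array."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites, n_hap = alleles.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if cm is None:
        cm = np.asarray(positions, dtype=float) / 100.0  # 1 cM per site
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_hap // 2)]
    if populations is None:
        populations = ["pop"] * (n_hap // 2)
    return HaplotypeSet(alleles=alleles, positions=np.asarray(positions),
                        cm=np.asarray(cm, dtype=float), samples=samples,
                        populations=populations, chrom=chrom)


def make_calls(rows, classes=("cahg", "farmer")):
    return LocalAncestryCalls(
        pd.DataFrame(rows, columns=["sample", "hap", "chrom", "start",
                                    "end", "label"]),
        classes=classes)


def make_ibd(rows):
    return IBDSegmentSet(pd.DataFrame(
        rows, columns=["id1", "hap1", "id2", "hap2", "chrom", "start",
                       "end", "lod", "length_cm"]))


def random_distance_matrix(rng, n, labels=None):
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return DistanceMatrix(a, labels or [f"G{i}" for i in range(n)])


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort reused across oracle-scan tests."""
    cfg = SimulationConfig(n_demes=4, n_individuals_per_deme=4, n_sites=400,
                           rng_seed=7)
    return simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the default study conditions."""
    cfg = SimulationConfig(rng_seed=11)
    return simulate_cohort(cfg), cfg
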