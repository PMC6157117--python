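import numpy as np
import pytest

from famblup.pedigree import Pedigree, PedigreeRecord
from famblup.simulate import (SimulationConfig, prepare_traits,
                              simulate_genotypes, simulate_pedigree,
                              simulate_phenotypes)


def simulate_all(cfg: SimulationConfig):
    """Pedigree, genotypes, IBD truth and prepared phenotypes for a config."""
    ped = simulate_pedigree(cfg)
    panel, ibd = simulate_genotypes(ped, cfg)
    pheno = prepare_traits(simulate_phenotypes(ped, panel, ibd, cfg))
    return ped, panel, ibd, pheno


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_families=8, generations=2, mean_sibship=3,
                            n_snps=400, n_chromosomes=4, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def nuclear_family() -> Pedigree:
    """Two founder parents and three full-sib offspring."""
    return Pedigree([
        PedigreeRecord("fa", None, None, "male", 0),
        PedigreeRecord("mo", None, None, "female", 0),
        PedigreeRecord("c1", "fa", "mo", "male", 1),
        PedigreeRecord("c2", "fa", "mo", "female", 1),
        PedigreeRecord("c3", "fa", "mo", "male", 1),
    ])


@pytest.fixture(scope="session")
def halfsib_mating_pedigree() -> Pedigree:
    """Half sibs (shared father) whose mating produces an inbred offspring."""
    return Pedigree([
        PedigreeRecord("fa", None, None, "male", 0),
        PedigreeRecord("m1", None, None, "female", 0),
        PedigreeRecord("m2", None, None, "female", 0),
        PedigreeRecord("h1", "fa", "m1", "male", 1),
        PedigreeRecord("h2", "fa", "m2", "female", 1),
        PedigreeRecord("inb", "h1", "h2", "female", 2),
    ])


def rng_seeds(base: int, n: int) -> list[int]:
    """Deterministic distinct seeds for replicate loops."""
    return [base + 1000 * k for k in range(n)]
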