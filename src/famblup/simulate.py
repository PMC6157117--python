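"""Synthetic family data with known identity-by-descent.

Generates the three inputs of the analysis pipeline — a multigenerational
pedigree, a dense biallelic SNP panel with local linkage disequilibrium, and a
twice-measured pre/post-intervention quantitative trait with covariates — while
recording the founder origin of every transmitted allele.  That record
(:class:`IbdTruth`) provides exact realized IBD sharing at any map position,
which downstream modules use to validate kinship estimators and to build locus
IBD matrices for linkage scans.

Simulation model
----------------
* Pedigree: each family starts from one founder couple.  Offspring in
  non-terminal generations mate with newly created, unrelated immigrant
  founders; terminal-generation offspring remain unmated.  Sibship sizes are
  ``1 + Poisson(mean_sibship - 1)`` (or fixed at ``round(mean_sibship)``).
* Genotypes: founder haplotypes are drawn SNP-by-SNP from allele frequencies
  with a latent-uniform copying scheme that produces local LD decaying with
  map distance while preserving marginal allele frequencies exactly.
  Non-founders receive haplotypes by gene dropping with Haldane (no
  interference) recombination.
* Phenotypes: log-scale trait = covariate effects + polygenic breeding value
  (+ optional single QTL) + shared household effect + per-time-point residual;
  each time point is observed as ``replicate_measurements`` noisy replicates.
  Post-treatment values are shifted by ``treatment_mean_shift``.

Random draws are consumed in a documented, fixed order so that tests can
replay the construction independently from the same stage stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .pedigree import Pedigree, PedigreeError, PedigreeRecord

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "GenotypePanel",
    "IbdTruth",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "prepare_traits",
    "replicate_columns",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# Fixed covariate effect sizes on the (log) trait scale.  These are part of
# the generative model, not tuning knobs: age in years, male offset, second
# study-center offset, smoking offset.
COVARIATE_EFFECTS = {
    "intercept": 3.0,
    "age_per_year": 0.008,
    "sex_male": 0.15,
    "center_C2": 0.10,
    "smoking": 0.20,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Variance fractions are relative to the non-covariate part of the trait:
    ``h2`` (polygenic) + ``qtl_fraction`` + ``household_variance_fraction`` +
    residual = 1.
    """

    n_families: int = 60
    generations: int = 2
    mean_sibship: float = 3.0
    sibship_model: str = "poisson"  # "poisson" | "fixed"
    n_snps: int = 5000
    n_chromosomes: int = 10
    chromosome_length_cM: float = 100.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_length_cM: float = 1.0
    h2: float = 0.4
    household_variance_fraction: float = 0.2
    treatment_mean_shift: float = -0.3
    n_causal: Union[int, str] = "infinitesimal"
    # one variance fraction per QTL; positions as (chromosome, cM) pairs, or
    # None to place the k-th QTL mid-chromosome k+1
    qtl_fraction: tuple[float, ...] = ()
    qtl_position: tuple[tuple[int, float], ...] | None = None
    missing_phenotype_rate: float = 0.1
    replicate_measurements: int = 2
    measurement_error_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(fieldname: str, why: str) -> ConfigError:
            return ConfigError(f"{fieldname}: {why}")

        if self.n_families < 1:
            raise bad("n_families", "must be >= 1")
        if self.generations < 1:
            raise bad("generations", "must be >= 1")
        if self.mean_sibship < 1:
            raise bad("mean_sibship", "must be >= 1")
        if self.sibship_model not in ("poisson", "fixed"):
            raise bad("sibship_model", "must be 'poisson' or 'fixed'")
        if self.n_snps < 1:
            raise bad("n_snps", "must be >= 1")
        if self.n_chromosomes < 1:
            raise bad("n_chromosomes", "must be >= 1")
        if self.chromosome_length_cM <= 0:
            raise bad("chromosome_length_cM", "must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise bad("maf_range", "must satisfy 0 < low <= high < 1")
        if self.ld_block_length_cM < 0:
            raise bad("ld_block_length_cM", "must be >= 0")
        if not 0 <= self.h2 <= 1:
            raise bad("h2", "must be in [0, 1]")
        if not 0 <= self.household_variance_fraction <= 1:
            raise bad("household_variance_fraction", "must be in [0, 1]")
        if isinstance(self.qtl_fraction, (int, float)):
            object.__setattr__(self, "qtl_fraction",
                               (float(self.qtl_fraction),)
                               if self.qtl_fraction else ())
        if any(not 0 < f <= 1 for f in self.qtl_fraction):
            raise bad("qtl_fraction", "each fraction must be in (0, 1]")
        if self.qtl_position is not None and \
                len(self.qtl_position) != len(self.qtl_fraction):
            raise bad("qtl_position", "must give one (chromosome, cM) pair "
                                      "per qtl_fraction entry")
        if self.h2 + self.household_variance_fraction \
                + sum(self.qtl_fraction) > 1:
            raise bad("h2", "h2 + household_variance_fraction + "
                            "sum(qtl_fraction) must be <= 1")
        if isinstance(self.n_causal, str):
            if self.n_causal != "infinitesimal":
                raise bad("n_causal", "must be a positive integer or 'infinitesimal'")
        elif self.n_causal < 1:
            raise bad("n_causal", "must be >= 1")
        if not 0 <= self.missing_phenotype_rate <= 1:
            raise bad("missing_phenotype_rate", "must be in [0, 1]")
        if self.replicate_measurements < 1:
            raise bad("replicate_measurements", "must be >= 1")
        if self.measurement_error_sd < 0:
            raise bad("measurement_error_sd", "must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a multifamily pedigree.

    Random stream order (one stage generator, consumed in this order): for
    each family, for each generation from 1, for each couple in creation
    order: one sibship-size draw (``poisson(mean_sibship - 1)``; skipped for
    the ``fixed`` model), then one ``random()`` per child for sex.  Immigrant
    spouses consume no randomness (sex is the child's opposite).
    """
    rng = stage_rng(config.seed, "pedigree")
    records: list[PedigreeRecord] = []

    for fam in range(1, config.n_families + 1):
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"F{fam:03d}-{counter:03d}"

        father = PedigreeRecord(new_id(), None, None, "male", 0)
        mother = PedigreeRecord(new_id(), None, None, "female", 0)
        records += [father, mother]
        couples = [(father, mother)]

        for gen in range(1, config.generations + 1):
            next_couples = []
            for (pa, ma) in couples:
                if config.sibship_model == "fixed":
                    nsib = max(1, round(config.mean_sibship))
                else:
                    nsib = 1 + int(rng.poisson(config.mean_sibship - 1.0))
                for _ in range(nsib):
                    sex = "male" if rng.random() < 0.5 else "female"
                    child = PedigreeRecord(new_id(), pa.individual_id,
                                           ma.individual_id, sex, gen)
                    records.append(child)
                    if gen < config.generations:
                        spouse_sex = "female" if sex == "male" else "male"
                        spouse = PedigreeRecord(new_id(), None, None,
                                                spouse_sex, gen)
                        records.append(spouse)
                        pair = (child, spouse) if sex == "male" else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples

    return Pedigree(records)


# ---------------------------------------------------------------------------
# Genotypes and IBD truth
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Biallelic dosages (count of the reference allele) with a genetic map."""

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray          # (n, m) int8 in {0, 1, 2}
    chromosome: np.ndarray      # (m,) int
    cM: np.ndarray              # (m,) float, strictly increasing per chromosome
    bp: np.ndarray              # (m,) int
    allele_freq: np.ndarray     # (m,) float in (0, 1): generating frequencies

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise ValueError("dosage dimensions do not match id lists")
        for c in np.unique(self.chromosome):
            pos = self.cM[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"cM positions not strictly increasing on chr {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index_at(self, chromosome: int, cM: float) -> int:
        """Index of the panel SNP nearest to (chromosome, cM)."""
        on = np.flatnonzero(self.chromosome == chromosome)
        if on.size == 0:
            raise ValueError(f"no SNPs on chromosome {chromosome}")
        lo, hi = self.cM[on[0]], self.cM[on[-1]]
        if not (lo - 1e-9 <= cM <= hi + 1e-9):
            raise ValueError(
                f"position {cM} cM outside mapped range [{lo}, {hi}] on "
                f"chromosome {chromosome}")
        return int(on[np.argmin(np.abs(self.cM[on] - cM))])


@dataclass
class IbdTruth:
    """Founder-allele labels for every individual, haplotype and SNP.

    ``labels[i, h, j]`` is the founder-haplotype index from which individual
    *i*'s haplotype *h* at SNP *j* descends.  Realized IBD sharing between two
    individuals at a locus is the number of label matches among the four
    haplotype pairings divided by two — 0, 0.5 or 1 per locus for non-inbred
    pairs, 1 on the diagonal of a non-inbred individual.
    """

    individual_ids: list[str]
    labels: np.ndarray          # (n, 2, m) int32
    chromosome: np.ndarray
    cM: np.ndarray

    def share_matrix(self, snp_index: int) -> np.ndarray:
        """(n, n) realized IBD-sharing matrix at one SNP."""
        L = self.labels[:, :, snp_index]              # (n, 2)
        a = L[:, None, :, None]                       # (n, 1, 2, 1)
        b = L[None, :, None, :]                       # (1, n, 1, 2)
        return (a == b).sum(axis=(2, 3)) / 2.0

    def pair_share(self, i: int, j: int) -> np.ndarray:
        """Per-SNP realized sharing between individuals *i* and *j*."""
        a, b = self.labels[i], self.labels[j]         # (2, m) each
        eq = (a[:, None, :] == b[None, :, :])         # (2, 2, m)
        return eq.sum(axis=(0, 1)) / 2.0

    def mean_share_matrix(self, snp_indices: np.ndarray | None = None) -> np.ndarray:
        """Genome-average sharing matrix over the given SNPs (default: all)."""
        idx = np.arange(self.labels.shape[2]) if snp_indices is None \
            else np.asarray(snp_indices)
        n = self.labels.shape[0]
        out = np.zeros((n, n))
        for j in idx:
            out += self.share_matrix(int(j))
        return out / len(idx)


def _genetic_map(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evenly spaced SNP positions: (chromosome, cM, bp) arrays."""
    base, rem = divmod(config.n_snps, config.n_chromosomes)
    chroms, cms = [], []
    for c in range(1, config.n_chromosomes + 1):
        m_c = base + (1 if c <= rem else 0)
        if m_c == 0:
            continue
        pos = (np.arange(m_c) + 0.5) * config.chromosome_length_cM / m_c
        chroms.append(np.full(m_c, c, dtype=int))
        cms.append(pos)
    chromosome = np.concatenate(chroms)
    cM = np.concatenate(cms)
    bp = np.round(cM * 1e6).astype(np.int64)
    return chromosome, cM, bp


def _founder_haplotypes(rng: np.random.Generator, n_haps: int,
                        p: np.ndarray, chromosome: np.ndarray, cM: np.ndarray,
                        ld_block_length: float) -> np.ndarray:
    """Founder haplotypes with latent-uniform copying LD.

    Each haplotype carries a latent uniform that is kept from the previous SNP
    with probability ``exp(-d_cM / ld_block_length)`` and redrawn otherwise;
    the allele is the indicator ``u < p_j``.  Marginal frequencies equal
    ``p_j`` exactly while adjacent SNPs are positively correlated with r²
    decaying in map distance.
    """
    m = p.size
    U = rng.random((n_haps, m))
    refresh = np.ones((n_haps, m), dtype=bool)
    if ld_block_length > 0:
        d = np.empty(m)
        d[0] = np.inf
        d[1:] = np.diff(cM)
        new_chrom = np.empty(m, dtype=bool)
        new_chrom[0] = True
        new_chrom[1:] = chromosome[1:] != chromosome[:-1]
        d[new_chrom] = np.inf
        keep_prob = np.exp(-d / ld_block_length)
        refresh = rng.random((n_haps, m)) >= keep_prob[None, :]
        refresh[:, 0] = True
        refresh[:, new_chrom] = True
    # latent value at j = uniform drawn at the most recent refresh point
    idx = np.where(refresh, np.arange(m)[None, :], 0)
    src = np.maximum.accumulate(idx, axis=1)
    latent = np.take_along_axis(U, src, axis=1)
    return (latent < p[None, :]).astype(np.int8)


def _meiosis(rng: np.random.Generator, parent_labels: np.ndarray,
             chromosome: np.ndarray, cM: np.ndarray,
             chrom_ids: np.ndarray, chrom_len: float) -> np.ndarray:
    """One gamete from a parent: Haldane recombination, no interference.

    Per chromosome the stream consumes: one starting-phase draw, one Poisson
    crossover count, then that many uniform crossover positions.
    """
    m = parent_labels.shape[1]
    phase = np.empty(m, dtype=np.int64)
    for c in chrom_ids:
        sel = chromosome == c
        pos = cM[sel]
        start = int(rng.integers(2))
        ncross = int(rng.poisson(chrom_len / 100.0))
        if ncross:
            xpos = np.sort(rng.random(ncross) * chrom_len)
            phase[sel] = (start + np.searchsorted(xpos, pos)) % 2
        else:
            phase[sel] = start
    return parent_labels[phase, np.arange(m)]


def simulate_genotypes(pedigree: Pedigree,
                       config: SimulationConfig) -> tuple[GenotypePanel, IbdTruth]:
    """Gene-drop genotypes through a pedigree, recording founder-allele labels.

    Stream order: founder allele frequencies; founder haplotype field (one
    block); then for each non-founder in pedigree order, the paternal gamete
    followed by the maternal gamete (see :func:`_meiosis`).
    """
    pedigree.validate()
    rng = stage_rng(config.seed, "genotypes")
    chromosome, cM, bp = _genetic_map(config)
    m = chromosome.size
    chrom_ids = np.unique(chromosome)

    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)

    founders = [r.individual_id for r in pedigree.records
                if r.father_id is None]
    founder_row = {fid: k for k, fid in enumerate(founders)}
    FA = _founder_haplotypes(rng, 2 * len(founders), p, chromosome, cM,
                             config.ld_block_length_cM)

    n = len(pedigree)
    labels = np.empty((n, 2, m), dtype=np.int32)
    for i, rec in enumerate(pedigree.records):
        if rec.father_id is None:
            k = founder_row[rec.individual_id]
            labels[i, 0, :] = 2 * k
            labels[i, 1, :] = 2 * k + 1
        else:
            for h, pid in enumerate((rec.father_id, rec.mother_id)):
                pi = pedigree.index_of(pid)
                labels[i, h, :] = _meiosis(rng, labels[pi], chromosome, cM,
                                           chrom_ids, config.chromosome_length_cM)

    alleles = FA[labels, np.arange(m)[None, None, :]]
    dosage = alleles.sum(axis=1, dtype=np.int8)

    snp_ids = [f"snp{c}_{k}" for c, k in
               zip(chromosome, _within_chrom_index(chromosome))]
    panel = GenotypePanel(pedigree.ids, snp_ids, dosage, chromosome, cM, bp, p)
    ibd = IbdTruth(pedigree.ids, labels, chromosome, cM)
    return panel, ibd


def _within_chrom_index(chromosome: np.ndarray) -> np.ndarray:
    out = np.zeros_like(chromosome)
    for c in np.unique(chromosome):
        sel = chromosome == c
        out[sel] = np.arange(sel.sum()) + 1
    return out


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _households(pedigree: Pedigree) -> list[str]:
    """One household per nuclear family: a couple plus its unmated offspring."""
    is_parent: dict[str, tuple[str, str]] = {}
    for rec in pedigree.records:
        if rec.father_id is not None:
            couple = (rec.father_id, rec.mother_id)
            is_parent[rec.father_id] = couple
            is_parent[rec.mother_id] = couple

    def household_of(rec: PedigreeRecord) -> tuple[str, str] | str:
        iid = rec.individual_id
        if iid in is_parent:
            return is_parent[iid]
        if rec.father_id is not None:
            return (rec.father_id, rec.mother_id)
        return iid  # unmated founder: own household

    keys = [household_of(r) for r in pedigree.records]
    seen: dict[object, str] = {}
    out = []
    for k in keys:
        if k not in seen:
            seen[k] = f"H{len(seen) + 1:04d}"
        out.append(seen[k])
    return out


def replicate_columns(config: SimulationConfig) -> list[str]:
    r = config.replicate_measurements
    return [f"trait_pre_r{k + 1}" for k in range(r)] + \
           [f"trait_post_r{k + 1}" for k in range(r)]


def _breeding_values(rng: np.random.Generator, pedigree: Pedigree,
                     h2: float) -> np.ndarray:
    """Infinitesimal polygenic values by generation-wise gene flow.

    Founders ~ N(0, h2); offspring = midparent + N(0, h2/2) Mendelian
    sampling (non-inbred approximation for the sampling variance).
    """
    n = len(pedigree)
    bv = np.zeros(n)
    founder_idx = [i for i, r in enumerate(pedigree.records) if r.father_id is None]
    bv[founder_idx] = rng.normal(0.0, math.sqrt(h2) if h2 > 0 else 0.0,
                                 size=len(founder_idx))
    gens = sorted({r.generation for r in pedigree.records
                   if r.father_id is not None})
    for g in gens:
        idx = [i for i, r in enumerate(pedigree.records)
               if r.generation == g and r.father_id is not None]
        if not idx:
            continue
        fa = np.array([pedigree.index_of(pedigree.records[i].father_id) for i in idx])
        mo = np.array([pedigree.index_of(pedigree.records[i].mother_id) for i in idx])
        mendelian = rng.normal(0.0, math.sqrt(h2 / 2) if h2 > 0 else 0.0,
                               size=len(idx))
        bv[idx] = 0.5 * (bv[fa] + bv[mo]) + mendelian
    return bv


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def simulate_phenotypes(pedigree: Pedigree, panel: GenotypePanel,
                        ibd: IbdTruth, config: SimulationConfig) -> pd.DataFrame:
    """Simulate the phenotype/covariate table.

    Returns a DataFrame with one row per pedigree member: replicate trait
    measurements (``trait_pre_r*``, ``trait_post_r*``), covariates (age, sex,
    center, smoking), ``household_id``, ``true_breeding_value`` and
    ``generation``.  Missing phenotypes are NaN in every replicate column for
    exactly ``round(missing_phenotype_rate * n)`` individuals; genotypes are
    unaffected.  Apply :func:`prepare_traits` to average replicates into
    ``trait_pre`` / ``trait_post``.
    """
    pedigree.validate()
    if len(pedigree) == 0:
        raise PedigreeError("cannot assign households in an empty pedigree")
    rng = stage_rng(config.seed, "phenotypes")
    n = len(pedigree)
    recs = pedigree.records

    # 1. polygenic breeding values
    if config.n_causal == "infinitesimal":
        bv = _breeding_values(rng, pedigree, config.h2)
    else:
        k = min(int(config.n_causal), panel.n_snps)
        causal = np.linspace(0, panel.n_snps - 1, k).astype(int)  # spread out
        beta = rng.normal(size=k)
        raw = (panel.dosage[:, causal].astype(float)
               - 2 * panel.allele_freq[causal]) @ beta
        bv = _standardize(raw) * math.sqrt(config.h2)

    # 2. optional discrete QTLs (each adds its variance fraction at a map
    #    position; default placement: mid-chromosome k+1 for the k-th QTL)
    qtl = np.zeros(n)
    chrom_ids = sorted(int(c) for c in np.unique(panel.chromosome))
    for k, frac in enumerate(config.qtl_fraction):
        if config.qtl_position is None:
            chrom = chrom_ids[k % len(chrom_ids)]
            pos = float(np.median(panel.cM[panel.chromosome == chrom]))
        else:
            chrom, pos = config.qtl_position[k]
        j = panel.snp_index_at(int(chrom), float(pos))
        qtl = qtl + _standardize(panel.dosage[:, j].astype(float)) * \
            math.sqrt(frac)

    # 3. household effects
    household = _households(pedigree)
    hh_ids = sorted(set(household))
    hh_sd = math.sqrt(config.household_variance_fraction)
    hh_effect_by_id = dict(zip(hh_ids, rng.normal(0.0, hh_sd, size=len(hh_ids))))
    hh = np.array([hh_effect_by_id[h] for h in household])

    # 4. covariates
    generation = np.array([r.generation for r in recs])
    age = np.clip(rng.normal(65.0 - 15.0 * generation, 5.0), 18.0, None)
    sex = np.array([r.sex for r in recs])
    fam = np.asarray(pedigree.families())
    center = np.where(fam % 2 == 0, "C1", "C2")
    smoking = (rng.random(n) < 0.25).astype(int)

    eff = COVARIATE_EFFECTS
    fixed = (eff["intercept"] + eff["age_per_year"] * (age - 50.0)
             + eff["sex_male"] * (sex == "male")
             + eff["center_C2"] * (center == "C2")
             + eff["smoking"] * smoking)

    # 5. per-time-point residuals, then replicate measurement error
    resid_var = 1.0 - config.h2 - sum(config.qtl_fraction) \
        - config.household_variance_fraction
    resid_sd = math.sqrt(max(resid_var, 0.0))
    base = fixed + bv + qtl + hh
    e_pre = rng.normal(0.0, resid_sd, size=n)
    e_post = rng.normal(0.0, resid_sd, size=n)
    pre = base + e_pre
    post = base + e_post + config.treatment_mean_shift

    r = config.replicate_measurements
    data: dict[str, np.ndarray] = {}
    for k in range(r):
        data[f"trait_pre_r{k + 1}"] = pre + rng.normal(
            0.0, config.measurement_error_sd, size=n)
    for k in range(r):
        data[f"trait_post_r{k + 1}"] = post + rng.normal(
            0.0, config.measurement_error_sd, size=n)

    # 6. missing phenotypes (genotypes retained)
    n_missing = int(round(config.missing_phenotype_rate * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False) if n_missing else \
        np.empty(0, dtype=int)

    table = pd.DataFrame({
        "individual_id": pedigree.ids,
        **data,
        "age": age,
        "sex": sex,
        "center": center,
        "smoking": smoking,
        "household_id": household,
        "generation": generation,
        "true_breeding_value": bv + qtl,
    })
    rep_cols = replicate_columns(config)
    table.loc[table.index[missing_idx], rep_cols] = np.nan
    return table


def prepare_traits(table: pd.DataFrame,
                   replicate_measurements: int | None = None) -> pd.DataFrame:
    """Average replicate measurements into ``trait_pre`` / ``trait_post``.

    Mirrors the standard pre-analysis step of averaging repeated measurements
    per time point to reduce measurement error.  A copy is returned.
    """
    out = table.copy()
    pre_cols = [c for c in table.columns if c.startswith("trait_pre_r")]
    post_cols = [c for c in table.columns if c.startswith("trait_post_r")]
    if replicate_measurements is not None:
        pre_cols = pre_cols[:replicate_measurements]
        post_cols = post_cols[:replicate_measurements]
    if not pre_cols or not post_cols:
        raise ValueError("no replicate trait columns found")
    # all-NaN rows (missing phenotypes) stay NaN; partial rows average the rest
    out["trait_pre"] = table[pre_cols].mean(axis=1)
    out["trait_post"] = table[post_cols].mean(axis=1)
    return out
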