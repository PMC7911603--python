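"""Synthetic pedigrees, genotypes and phenotypes with known ground truth.

The generators emulate a small, closed beef-cattle herd: a
multi-generation pedigree with few heavily used sires and many dams,
optionally incomplete parent recording; 29-autosome SNP genotypes
produced by *gene dropping* founder haplotypes through the pedigree
(so pedigree-expected and genomic inbreeding agree in expectation);
and birth/weaning weights with sex, birth-year and inbreeding effects.
A Wright–Fisher forward simulator provides equilibrium populations of
known census size for LD-based Ne recovery checks.

All generators take an explicit seed and are bit-reproducible; there
is no hidden global random state.  Recombination follows the Haldane
(no-interference) model at 1 cM per Mb, implemented as a Markov switch
process along each chromosome: the probability of switching parental
haplotype between adjacent markers ``j-1, j`` is
``r_j = (1 - exp(-2 d_j)) / 2`` with ``d_j`` the interval in Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import Pedigree, GenotypeMatrix, MarkerMap, MISSING
from .pedigree_metrics import a_matrix

__all__ = [
    "SimPedigreeConfig",
    "SimGenomeConfig",
    "SimPhenoConfig",
    "SimulatedPedigree",
    "SimulatedGenotypes",
    "sim_pedigree",
    "sim_genotypes",
    "sim_wright_fisher",
    "sim_phenotypes",
]


@dataclass(frozen=True)
class SimPedigreeConfig:
    """Pedigree simulation settings.

    ``mating_scheme``:

    * ``random`` — offspring draw a sire from a small, skew-weighted
      subset of the previous generation's males (``prop_sires_used``
      controls the sire bottleneck) and a dam uniformly from its
      females.
    * ``assortative`` — like ``random`` but the dam maximizing the
      additive relationship to the chosen sire among a few sampled
      candidates is taken, inflating inbreeding.
    * ``full_sib_lines`` — founders are paired once to create full-sib
      groups, then each of ``n_generations`` rounds mates a brother x
      sister pair per line, so the first generated round already has
      F = 0.25.

    ``missing_sire_rate``/``missing_dam_rate`` mask recorded parents
    *after* true inbreeding has been computed, emulating incomplete
    recording on each parent pathway; the defaults mirror the missing
    sire/dam pathway rates typical of a small performance-recorded
    tropical beef herd.
    """

    n_founders: int = 60
    n_generations: int = 6
    offspring_per_generation: int = 150
    mating_scheme: str = "random"
    prop_sires_used: float = 0.15
    missing_sire_rate: float = 0.27
    missing_dam_rate: float = 0.35
    birth_year_start: int = 2000
    years_per_generation: int = 3
    seed: int = 0

    def __post_init__(self):
        for r in (self.prop_sires_used, self.missing_sire_rate, self.missing_dam_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mating_scheme not in ("random", "assortative", "full_sib_lines"):
            raise ValueError(f"unknown mating_scheme {self.mating_scheme!r}")


@dataclass(frozen=True)
class SimGenomeConfig:
    """Genome geometry and founder-allele settings for gene dropping.

    Defaults give a 29-autosome map of ~2508 Mb total, the scale of the
    cattle autosomal genome; ``founder_maf`` is the (low, high) range
    of the per-locus founder allele frequency, drawn uniformly.
    """

    n_chromosomes: int = 29
    snp_per_chrom: int = 1054
    chrom_length_mb: float = 86.5
    founder_maf: tuple = (0.05, 0.5)
    cm_per_mb: float = 1.0
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length_mb <= 0 or self.snp_per_chrom < 1:
            raise ValueError("positive chromosome length and SNP count required")
        for r in (self.genotyping_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class SimPhenoConfig:
    """Phenotype simulation: y = mu + sex + year + beta1 * (100 F) + e.

    Scales follow routine beef recording: birth weight around 27 kg,
    weaning weight around 144 kg at 240 d.  ``beta1_*`` are kg per 1%
    inbreeding (negative = depression).  Recorded weaning weights are
    de-adjusted to the drawn age by inverting the linear-gain
    correction, so QC + adjustment recovers the 240-d value exactly.
    """

    mu_bw: float = 27.13
    mu_ww: float = 144.28
    sex_effect_bw: float = 1.2
    sex_effect_ww: float = 6.0
    year_sd_bw: float = 1.0
    year_sd_ww: float = 5.0
    beta1_bw: float = -0.103
    beta1_ww: float = -0.685
    residual_sd_bw: float = 4.0
    residual_sd_ww: float = 20.0
    prop_bw: float = 1.0
    prop_ww: float = 0.5
    ww_age_window: tuple = (200, 280)
    seed: int = 0


@dataclass
class SimulatedPedigree:
    """Observed pedigree (with masked parents), the fully recorded truth
    pedigree, and per-animal true inbreeding from the tabular method."""

    pedigree: Pedigree
    pedigree_true: Pedigree
    truth: pd.DataFrame


def _mate_random(rng, males, females, n_offspring, prop_sires, A=None, assort=False):
    n_sires = max(1, int(round(prop_sires * len(males))))
    sires = rng.choice(males, size=n_sires, replace=False)
    weights = rng.dirichlet(np.full(n_sires, 0.35))  # heavy sire-usage skew
    out = []
    for _ in range(n_offspring):
        s = int(rng.choice(sires, p=weights))
        if assort and A is not None:
            cand = rng.choice(females, size=min(5, len(females)), replace=False)
            d = int(cand[np.argmax(A[s, cand])])
        else:
            d = int(rng.choice(females))
        out.append((s, d))
    return out


def sim_pedigree(cfg: SimPedigreeConfig) -> SimulatedPedigree:
    """Simulate a multi-generation pedigree with known true inbreeding.

    True F is the diagonal of the tabular relationship matrix minus one,
    computed on the fully recorded pedigree *before* any parent masking,
    so observed-pedigree estimates can be compared against truth.
    """
    rng = np.random.default_rng(cfg.seed)
    ids: list = []
    sire: list = []
    dam: list = []
    year: list = []
    sex: list = []

    def add(s, d, y, x):
        i = len(ids)
        ids.append(f"A{i + 1:05d}")
        sire.append(s)
        dam.append(d)
        year.append(y)
        sex.append(x)
        return i

    need_A = cfg.mating_scheme == "assortative"
    # generous upper bound on the final size for the incremental A matrix
    if cfg.mating_scheme == "full_sib_lines":
        cap = cfg.n_founders + (cfg.n_generations + 1) * cfg.n_founders
    else:
        cap = cfg.n_founders + cfg.n_generations * cfg.offspring_per_generation
    A = np.zeros((cap, cap)) if need_A else None

    def add_tracked(s, d, y, x):
        i = add(s, d, y, x)
        if A is not None:
            if s is not None and d is not None:
                row = 0.5 * (A[s, :i] + A[d, :i])
                A[i, :i] = row
                A[:i, i] = row
                A[i, i] = 1.0 + 0.5 * A[s, d]
            else:
                A[i, i] = 1.0
        return i

    for k in range(cfg.n_founders):
        add_tracked(None, None, cfg.birth_year_start, "M" if k % 2 == 0 else "F")

    y = cfg.birth_year_start
    if cfg.mating_scheme == "full_sib_lines":
        males = [i for i in range(cfg.n_founders) if sex[i] == "M"]
        females = [i for i in range(cfg.n_founders) if sex[i] == "F"]
        lines = list(zip(males, females))
        if not lines:
            raise ValueError("full_sib_lines needs founders of both sexes")
        # initial founder cross creates the sib groups (not counted as a round)
        y += cfg.years_per_generation
        lines = [
            (add_tracked(s, d, y, "M"), add_tracked(s, d, y, "F"))
            for s, d in lines
        ]
        for _ in range(cfg.n_generations):
            y += cfg.years_per_generation
            lines = [
                (add_tracked(b, sis, y, "M"), add_tracked(b, sis, y, "F"))
                for b, sis in lines
            ]
    else:
        prev = list(range(cfg.n_founders))
        for _ in range(cfg.n_generations):
            males = [i for i in prev if sex[i] == "M"]
            females = [i for i in prev if sex[i] == "F"]
            if not males or not females:
                raise ValueError("no mating candidates of one sex; adjust the config")
            y += cfg.years_per_generation
            pairs = _mate_random(rng, males, females, cfg.offspring_per_generation,
                                 cfg.prop_sires_used, A,
                                 assort=cfg.mating_scheme == "assortative")
            cur = []
            for s, d in pairs:
                cur.append(add_tracked(s, d, y, "M" if rng.random() < 0.5 else "F"))
            prev = cur

    n = len(ids)
    ids_arr = np.array(ids, dtype=object)
    sire_arr = np.array([s if s is not None else -1 for s in sire], dtype=np.int64)
    dam_arr = np.array([d if d is not None else -1 for d in dam], dtype=np.int64)
    ped_true = Pedigree(ids_arr, sire_arr, dam_arr,
                        np.array(year, dtype=np.int64),
                        np.array(sex, dtype=object))
    f_true = np.diag(a_matrix(ped_true)) - 1.0
    truth = pd.DataFrame({"animal": ids_arr, "f_true": f_true,
                          "sire_true": sire_arr, "dam_true": dam_arr})

    obs_sire = sire_arr.copy()
    obs_dam = dam_arr.copy()
    if cfg.missing_sire_rate > 0:
        mask = (obs_sire >= 0) & (rng.random(n) < cfg.missing_sire_rate)
        obs_sire[mask] = -1
    if cfg.missing_dam_rate > 0:
        mask = (obs_dam >= 0) & (rng.random(n) < cfg.missing_dam_rate)
        obs_dam[mask] = -1
    ped_obs = Pedigree(ids_arr.copy(), obs_sire, obs_dam,
                       np.array(year, dtype=np.int64),
                       np.array(sex, dtype=object))
    return SimulatedPedigree(ped_obs, ped_true, truth)


def _make_map(rng, cfg: SimGenomeConfig) -> MarkerMap:
    chroms, positions, names = [], [], []
    L = int(cfg.chrom_length_mb * 1e6)
    for c in range(1, cfg.n_chromosomes + 1):
        pos = np.unique(rng.integers(1, L, size=int(cfg.snp_per_chrom * 1.3) + 8))
        while len(pos) < cfg.snp_per_chrom:
            pos = np.unique(np.concatenate([pos, rng.integers(1, L, size=cfg.snp_per_chrom)]))
        pos = np.sort(rng.choice(pos, size=cfg.snp_per_chrom, replace=False))
        chroms.append(np.full(cfg.snp_per_chrom, c))
        positions.append(pos)
        names.extend(f"chr{c}_snp{k + 1}" for k in range(cfg.snp_per_chrom))
    return MarkerMap(np.array(names, dtype=object),
                     np.concatenate(chroms), np.concatenate(positions))


def _switch_probs(mm: MarkerMap, cm_per_mb: float) -> np.ndarray:
    """Per-marker haplotype-switch probabilities (chromosome starts 0.5)."""
    d_morgan = np.diff(mm.pos_bp) / 1e6 * cm_per_mb / 100.0
    r = np.empty(mm.n)
    r[0] = 0.5
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    starts = np.flatnonzero(np.diff(mm.chrom) != 0) + 1
    r[starts] = 0.5  # chromosomes segregate independently
    return r


@dataclass
class SimulatedGenotypes:
    """Gene-dropped genotypes plus IBD bookkeeping.

    ``ibd_fraction`` is each animal's realized genome fraction where
    both haplotypes descend from the same founder haplotype — the
    realized (not expected) inbreeding.
    """

    gm: GenotypeMatrix
    mm: MarkerMap
    ibd_fraction: np.ndarray
    founder_freq: np.ndarray


def sim_genotypes(ped: Pedigree, cfg: SimGenomeConfig) -> SimulatedGenotypes:
    """Drop founder haplotypes through a pedigree.

    Founder haplotypes carry alleles drawn per locus from the founder
    allele frequency and a constant haplotype label used for IBD
    bookkeeping.  Each meiosis recombines the parent's two haplotypes
    by the Haldane switch process.  An unknown parent contributes a
    fresh, unrelated founder haplotype.  Genotyping error replaces a
    call with a random genotype; missingness sets it to ``-1``.
    """
    rng = np.random.default_rng(cfg.seed)
    mm = _make_map(rng, cfg)
    m = mm.n
    p = rng.uniform(cfg.founder_maf[0], cfg.founder_maf[1], size=m)
    rsw = _switch_probs(mm, cfg.cm_per_mb)
    n = ped.n
    hap = np.zeros((n, 2, m), dtype=np.int8)
    lab = np.zeros((n, 2, m), dtype=np.int32)
    next_label = 0
    for i in range(n):
        for side, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
            if parent < 0:
                hap[i, side] = rng.random(m) < p
                lab[i, side] = next_label
                next_label += 1
            else:
                phase = np.cumsum(rng.random(m) < rsw) & 1
                hap[i, side] = np.where(phase == 0, hap[parent, 0], hap[parent, 1])
                lab[i, side] = np.where(phase == 0, lab[parent, 0], lab[parent, 1])
    dos = (hap[:, 0, :] + hap[:, 1, :]).astype(np.int8)
    if cfg.genotyping_error_rate > 0:
        err = rng.random(dos.shape) < cfg.genotyping_error_rate
        dos[err] = rng.integers(0, 3, size=int(err.sum()), dtype=np.int8)
    if cfg.missing_rate > 0:
        dos[rng.random(dos.shape) < cfg.missing_rate] = MISSING
    ibd = (lab[:, 0, :] == lab[:, 1, :]).mean(axis=1)
    return SimulatedGenotypes(GenotypeMatrix(ped.ids.copy(), dos), mm, ibd, p)


def sim_wright_fisher(n_individuals: int, n_generations: int,
                      genome: SimGenomeConfig | None = None,
                      sample_n: int | None = None, seed: int = 0):
    """Discrete-generation Wright–Fisher population with recombination.

    A constant-size, random-mating diploid population (selfing
    excluded) is evolved for ``n_generations``; a random sample of
    ``sample_n`` final-generation individuals is returned as
    ``(GenotypeMatrix, MarkerMap)``.  Initial haplotype alleles are
    drawn from the genome config's founder allele frequency.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    genome = genome or SimGenomeConfig(n_chromosomes=20, snp_per_chrom=200,
                                       chrom_length_mb=100.0, founder_maf=(0.5, 0.5))
    rng = np.random.default_rng(seed)
    mm = _make_map(rng, genome)
    m = mm.n
    N = n_individuals
    p = rng.uniform(genome.founder_maf[0], genome.founder_maf[1], size=m)
    rsw = _switch_probs(mm, genome.cm_per_mb)
    hap = (rng.random((2 * N, m)) < p).astype(np.int8)
    for _ in range(n_generations):
        pa = rng.integers(0, N, size=N)
        pb = rng.integers(0, N, size=N)
        clash = pa == pb
        while clash.any():
            pb[clash] = rng.integers(0, N, size=int(clash.sum()))
            clash = pa == pb
        new = np.empty_like(hap)
        for side, par in ((0, pa), (1, pb)):
            phase = np.cumsum(rng.random((N, m)) < rsw[None, :], axis=1) & 1
            h0 = hap[2 * par]
            h1 = hap[2 * par + 1]
            new[side::2] = np.where(phase == 0, h0, h1)
        hap = new
    if sample_n is None:
        sample_n = N
    pick = rng.choice(N, size=min(sample_n, N), replace=False)
    dos = (hap[2 * pick] + hap[2 * pick + 1]).astype(np.int8)
    ids = np.array([f"WF{k + 1:04d}" for k in range(len(pick))], dtype=object)
    return GenotypeMatrix(ids, dos), mm


def sim_phenotypes(ped: Pedigree, F: np.ndarray, cfg: SimPhenoConfig) -> pd.DataFrame:
    """Simulate birth and weaning weights for animals with known parents.

    Only animals with both parents recorded receive phenotypes (as in
    routine performance recording); weaning-weight animals are a subset
    of the birth-weight ones so the 240-d adjustment can use the
    recorded birth weight.
    """
    rng = np.random.default_rng(cfg.seed)
    F = np.asarray(F, dtype=float)
    eligible = np.flatnonzero((ped.sire >= 0) & (ped.dam >= 0)
                              & (ped.birth_year >= 0)
                              & np.isin(ped.sex, ("M", "F")))
    years = sorted({int(y) for y in ped.birth_year[eligible]})
    year_eff_bw = {y: rng.normal(0.0, cfg.year_sd_bw) for y in years}
    year_eff_ww = {y: rng.normal(0.0, cfg.year_sd_ww) for y in years}
    n_bw = int(round(cfg.prop_bw * len(eligible)))
    bw_idx = rng.choice(eligible, size=n_bw, replace=False) if n_bw else np.array([], int)
    n_ww = int(round(cfg.prop_ww * len(eligible)))
    ww_idx = rng.choice(bw_idx, size=min(n_ww, len(bw_idx)), replace=False) if n_ww else np.array([], int)
    rows = []
    bw_vals = {}
    for i in bw_idx:
        sgn = 0.5 if ped.sex[i] == "M" else -0.5
        y = int(ped.birth_year[i])
        val = (cfg.mu_bw + sgn * cfg.sex_effect_bw + year_eff_bw[y]
               + cfg.beta1_bw * 100.0 * F[i] + rng.normal(0.0, cfg.residual_sd_bw))
        val = max(val, 0.5)
        bw_vals[i] = val
        rows.append({"animal_id": ped.ids[i], "trait": "birth_weight",
                     "value": val, "age_d": np.nan, "sex": ped.sex[i],
                     "birth_year": y})
    for i in ww_idx:
        sgn = 0.5 if ped.sex[i] == "M" else -0.5
        y = int(ped.birth_year[i])
        y240 = (cfg.mu_ww + sgn * cfg.sex_effect_ww + year_eff_ww[y]
                + cfg.beta1_ww * 100.0 * F[i] + rng.normal(0.0, cfg.residual_sd_ww))
        y240 = max(y240, 1.0)
        age = int(rng.integers(cfg.ww_age_window[0], cfg.ww_age_window[1] + 1))
        bw = bw_vals[i]
        recorded = bw + (y240 - bw) * age / 240.0  # inverse of the 240-d adjustment
        rows.append({"animal_id": ped.ids[i], "trait": "weaning_weight",
                     "value": max(recorded, 1.0), "age_d": float(age),
                     "sex": ped.sex[i], "birth_year": y})
    return pd.DataFrame(rows, columns=["animal_id", "trait", "value",
                                       "age_d", "sex", "birth_year"])
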