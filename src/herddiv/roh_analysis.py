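"""Runs of homozygosity (ROH) and heterozygosity (ROHet).

Detection uses the *consecutive* method: each animal's chromosome is
scanned SNP by SNP and a run grows while its composition rules hold,
without any sliding window.  Long ROH reflect recent inbreeding (little
recombination has broken the autozygous haplotype), short ROH ancient
inbreeding; ROHet marks regions of maintained heterozygosity, a
candidate signal of balancing selection.

Rules (defaults mirror common medium-density cattle-chip settings):

* ROH: >= 15 consecutive homozygous SNP spanning >= 1 Mb; heterozygous
  and missing calls are not allowed inside; inter-marker gaps > 1 Mb
  break a run.
* ROHet: >= 15 consecutive SNP spanning >= 250 kb, tolerating at most 3
  homozygous and 2 missing calls inside; same 1 Mb gap rule.  A run
  must start and end on a heterozygous SNP; the violation that exceeds
  a tolerance ends the run at the last heterozygous SNP.

Genome-wide inbreeding is ``F_ROH = L_ROH / L_AUT`` (run length summed
over autosomes divided by total autosome length) and per chromosome
``F_ROHCHR = L_ROH(chr) / L_CHR``.  Run coordinates are SNP-anchored:
1-based closed intervals from the first to the last SNP of the run,
length in Mb = (end - start)/1e6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MarkerMap

__all__ = [
    "RunConfig",
    "ROHSegment",
    "ROHSummary",
    "IslandResult",
    "detect_roh",
    "detect_rohet",
    "summarize_roh",
    "shared_roh",
    "snp_incidence",
    "find_islands",
    "segments_to_frame",
]


@dataclass(frozen=True)
class RunConfig:
    """Composition rules for a run scan.

    ``max_other_inside`` bounds the tolerated calls of the opposite
    state (heterozygotes inside a ROH; homozygotes inside a ROHet) and
    ``max_missing_inside`` the tolerated missing calls.
    """

    min_snp: int = 15
    min_len_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    max_other_inside: int = 0
    max_missing_inside: int = 0

    def __post_init__(self):
        for v in (self.min_snp, self.min_len_bp, self.max_gap_bp,
                  self.max_other_inside, self.max_missing_inside):
            if v < 0:
                raise ValueError("run-config values must be non-negative")

    @classmethod
    def roh_defaults(cls) -> "RunConfig":
        return cls(min_snp=15, min_len_bp=1_000_000, max_gap_bp=1_000_000,
                   max_other_inside=0, max_missing_inside=0)

    @classmethod
    def rohet_defaults(cls) -> "RunConfig":
        return cls(min_snp=15, min_len_bp=250_000, max_gap_bp=1_000_000,
                   max_other_inside=3, max_missing_inside=2)


@dataclass(frozen=True)
class ROHSegment:
    """A detected run: 1-based closed bp interval anchored on SNPs."""

    animal_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snp: int

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


def _scan_chromosome(target: np.ndarray, missing: np.ndarray,
                     pos: np.ndarray, cfg: RunConfig):
    """Consecutive scan of one chromosome.

    ``target`` flags the state defining the run (homozygous for ROH,
    heterozygous for ROHet); ``missing`` flags missing calls.  Yields
    (start_idx, end_idx) of qualifying runs; both ends are target SNPs.
    """
    m = len(pos)
    runs = []
    i = 0
    while i < m:
        if not target[i]:
            i += 1
            continue
        start = i
        last_t = i
        n_other = 0
        n_miss = 0
        j = i + 1
        resume = m
        while j < m:
            if pos[j] - pos[j - 1] > cfg.max_gap_bp:
                resume = j  # the SNP after the gap can start a new run
                break
            if target[j]:
                last_t = j
            elif missing[j]:
                n_miss += 1
                if n_miss > cfg.max_missing_inside:
                    resume = j + 1
                    break
            else:
                n_other += 1
                if n_other > cfg.max_other_inside:
                    resume = j + 1
                    break
            j += 1
        n_snp = last_t - start + 1
        if n_snp >= cfg.min_snp and pos[last_t] - pos[start] >= cfg.min_len_bp:
            runs.append((start, last_t))
        i = resume
    return runs


def _detect(gm: GenotypeMatrix, mm: MarkerMap, cfg: RunConfig, state: str):
    if gm.n_markers != mm.n:
        raise ValueError("genotypes and marker map are inconsistent")
    segments = []
    chrom_idx = {c: mm.chrom_indices(c) for c in mm.chromosomes()}
    for ai in range(gm.n_animals):
        row = gm.dosages[ai]
        for c, idx in chrom_idx.items():
            g = row[idx]
            pos = mm.pos_bp[idx]
            missing = g < 0
            if state == "hom":
                target = (g == 0) | (g == 2)
            else:
                target = g == 1
            for s, e in _scan_chromosome(target, missing, pos, cfg):
                segments.append(
                    ROHSegment(gm.ids[ai], int(c), int(pos[s]), int(pos[e]),
                               int(e - s + 1))
                )
    return segments


def detect_roh(gm: GenotypeMatrix, mm: MarkerMap,
               cfg: RunConfig | None = None) -> list[ROHSegment]:
    """Detect runs of homozygosity with the consecutive method."""
    return _detect(gm, mm, cfg or RunConfig.roh_defaults(), "hom")


def detect_rohet(gm: GenotypeMatrix, mm: MarkerMap,
                 cfg: RunConfig | None = None) -> list[ROHSegment]:
    """Detect heterozygosity-rich runs with the consecutive method."""
    return _detect(gm, mm, cfg or RunConfig.rohet_defaults(), "het")


LENGTH_CLASSES = ((1, 2), (2, 4), (4, 8), (8, 16), (16, np.inf))
FROH_THRESHOLDS = (1, 2, 4, 8, 16)


@dataclass
class ROHSummary:
    """Per-animal and population ROH accounting.

    ``per_animal`` columns: nROH, SROH (Mb), mean LROH (Mb) and FROH at
    each minimum-length threshold; ``froh_chr`` is animals x chromosome
    FROHCHR; ``class_counts``/``class_shares`` bin segments into the
    half-open length classes [1,2), [2,4), [4,8), [8,16), [16,inf) Mb.
    """

    per_animal: pd.DataFrame
    froh_chr: pd.DataFrame
    class_counts: dict
    class_shares: dict
    laut_mb: float


def summarize_roh(segments, mm: MarkerMap, animals=None,
                  laut_mode: str = "map", laut_mb: float | None = None) -> ROHSummary:
    """Summarize detected ROH.

    ``laut_mode="map"`` takes the autosome length from the map extents;
    ``laut_mode="constant"`` uses the supplied ``laut_mb`` (useful for
    replicating published denominators).  FROH at threshold x counts
    only segments of length >= x Mb.
    """
    if laut_mode == "map":
        laut = mm.laut_bp() / 1e6
    elif laut_mode == "constant":
        if laut_mb is None:
            raise ValueError("laut_mode='constant' requires laut_mb")
        laut = float(laut_mb)
    else:
        raise ValueError(f"unknown laut_mode {laut_mode!r}")
    if animals is None:
        animals = sorted({s.animal_id for s in segments})
    animals = list(animals)
    chroms = [int(c) for c in mm.chromosomes()]
    lchr_mb = {c: mm.chrom_length_bp(c) / 1e6 for c in chroms}
    idx = {a: k for k, a in enumerate(animals)}
    nroh = np.zeros(len(animals), dtype=int)
    sroh = np.zeros(len(animals))
    froh_t = {t: np.zeros(len(animals)) for t in FROH_THRESHOLDS}
    lchr_sum = np.zeros((len(animals), len(chroms)))
    cpos = {c: k for k, c in enumerate(chroms)}
    class_counts = {f"{lo}-{hi}Mb" if np.isfinite(hi) else f">{lo}Mb": 0
                    for lo, hi in LENGTH_CLASSES}
    keys = list(class_counts)
    for s in segments:
        if s.animal_id not in idx:
            continue
        k = idx[s.animal_id]
        L = s.length_mb
        nroh[k] += 1
        sroh[k] += L
        for t in FROH_THRESHOLDS:
            if L >= t:
                froh_t[t][k] += L
        if s.chrom in cpos:
            lchr_sum[k, cpos[s.chrom]] += L
        for key, (lo, hi) in zip(keys, LENGTH_CLASSES):
            if lo <= L < hi:
                class_counts[key] += 1
                break
    total = sum(class_counts.values())
    class_shares = {k: (100.0 * v / total if total else 0.0)
                    for k, v in class_counts.items()}
    per_animal = pd.DataFrame({"animal": animals, "nroh": nroh, "sroh_mb": sroh})
    with np.errstate(invalid="ignore"):
        per_animal["mean_lroh_mb"] = np.where(nroh > 0, sroh / np.maximum(nroh, 1), np.nan)
    for t in FROH_THRESHOLDS:
        per_animal[f"froh_gt{t}mb"] = froh_t[t] / laut
    froh_chr = pd.DataFrame(
        {f"chr{c}": lchr_sum[:, cpos[c]] / lchr_mb[c] if lchr_mb[c] > 0 else 0.0
         for c in chroms}
    )
    froh_chr.insert(0, "animal", animals)
    return ROHSummary(per_animal, froh_chr, class_counts, class_shares, laut)


def shared_roh(segments) -> pd.DataFrame:
    """Runs shared exactly: identical (chrom, start, end) in >= 2 animals.

    Returns a frame sorted by descending carrier count with columns
    chrom, start_bp, end_bp, n_carriers, carriers.
    """
    groups: dict = {}
    for s in segments:
        groups.setdefault((s.chrom, s.start_bp, s.end_bp), []).append(s.animal_id)
    rows = [
        {"chrom": c, "start_bp": a, "end_bp": b,
         "n_carriers": len(v), "carriers": ",".join(sorted(v))}
        for (c, a, b), v in groups.items() if len(v) >= 2
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                     "n_carriers", "carriers"])
    return df.sort_values(["n_carriers", "chrom", "start_bp"],
                          ascending=[False, True, True]).reset_index(drop=True)


def snp_incidence(segments, mm: MarkerMap, n_animals: int) -> np.ndarray:
    """Fraction of animals whose runs cover each SNP."""
    counts = np.zeros(mm.n)
    starts = {c: None for c in mm.chromosomes()}
    offsets = {}
    for c in mm.chromosomes():
        idx = mm.chrom_indices(c)
        offsets[int(c)] = (idx[0], mm.pos_bp[idx])
    for s in segments:
        if s.chrom not in offsets:
            continue
        off, pos = offsets[s.chrom]
        lo = np.searchsorted(pos, s.start_bp, side="left")
        hi = np.searchsorted(pos, s.end_bp, side="right")
        counts[off + lo: off + hi] += 1
    return counts / float(n_animals)


@dataclass
class IslandResult:
    """Per-SNP run incidence, the percentile threshold applied, and the
    maximal contiguous above-threshold stretches (islands)."""

    incidence: pd.DataFrame
    threshold: float
    percentile: float
    islands: pd.DataFrame


def find_islands(segments, mm: MarkerMap, n_animals: int,
                 percentile: float = 99.9,
                 max_gap_bp: int = 1_000_000) -> IslandResult:
    """Locate selection-signature islands from run incidence.

    The per-SNP incidence (carriers / animals) is thresholded at the
    given percentile of its own distribution; islands are maximal
    contiguous stretches of above-threshold SNPs that stay within one
    chromosome and never span an inter-marker gap larger than
    ``max_gap_bp``.
    """
    inc = snp_incidence(segments, mm, n_animals)
    inc_df = pd.DataFrame(
        {"snp_id": mm.snp_id, "chrom": mm.chrom, "pos_bp": mm.pos_bp,
         "incidence": inc}
    )
    cols = ["chrom", "start_bp", "end_bp", "n_snp", "mean_incidence"]
    if not np.any(inc > 0):
        warnings.warn("all-zero run incidence; no islands")
        return IslandResult(inc_df, np.nan, percentile,
                            pd.DataFrame(columns=cols))
    thr = float(np.percentile(inc, percentile))
    rows = []
    for c in mm.chromosomes():
        idx = mm.chrom_indices(c)
        pos = mm.pos_bp[idx]
        above = (inc[idx] >= thr) & (inc[idx] > 0)
        start = None
        for k in range(len(idx) + 1):
            boundary = (
                k == len(idx)
                or not above[k]
                or (start is not None and k > 0 and pos[k] - pos[k - 1] > max_gap_bp)
            )
            if start is not None and boundary:
                rows.append(
                    {"chrom": int(c), "start_bp": int(pos[start]),
                     "end_bp": int(pos[k - 1]), "n_snp": int(k - start),
                     "mean_incidence": float(inc[idx][start:k].mean())}
                )
                start = None
            if k < len(idx) and above[k] and start is None:
                start = k
    return IslandResult(inc_df, thr, percentile,
                        pd.DataFrame(rows, columns=cols))


def segments_to_frame(segments) -> pd.DataFrame:
    """BED-like table of runs: 1-based closed bp intervals."""
    return pd.DataFrame(
        [
            {"chrom": s.chrom, "start_bp": s.start_bp, "end_bp": s.end_bp,
             "animal": s.animal_id, "n_snp": s.n_snp, "length_mb": s.length_mb}
            for s in segments
        ],
        columns=["chrom", "start_bp", "end_bp", "animal", "n_snp", "length_mb"],
    )
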