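"""Linkage disequilibrium decay and historical effective population size.

LD between two loci at recombination distance ``c`` reflects the
effective population size roughly ``t = 1/(2c)`` generations ago:
tightly linked pairs carry old information, loosely linked pairs recent
information.  The pipeline

1. computes ``r^2`` — the squared Pearson correlation of unphased
   dosages — for all same-chromosome SNP pairs inside a distance
   window, binned by distance;
2. subtracts the finite-sample bias, ``r_adj^2 = r^2 - 1/(beta * n)``
   (``beta = 1`` for unphased data);
3. maps each bin's physical distance ``d`` (Morgans, 1 cM = 1 Mb by
   default) to a recombination rate via the Sved–Feldman function
   ``c = d (1 - d/2)`` and inverts the drift-recombination expectation
   ``E[r_adj^2] = 1 / (alpha + 4 N c)`` to
   ``Ne(t) = (1/(4c)) * (1/r_adj^2 - alpha)`` with ``alpha = 2``
   correcting for mutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MarkerMap

__all__ = ["LDConfig", "pairwise_r2", "adjust_r2", "ne_trajectory", "ld_ne_pipeline"]

_MAPPINGS = {
    "sved_feldman": lambda d: d * (1.0 - d / 2.0),
    "linear": lambda d: d,
    "haldane": lambda d: 0.5 * (1.0 - np.exp(-2.0 * d)),
}


@dataclass(frozen=True)
class LDConfig:
    """Distance window, bin geometry and adjustment constants.

    ``beta`` is the sampling-bias constant (1 for unphased genotype
    data), ``alpha`` the mutation correction in the drift expectation,
    and ``mb_per_cm`` the physical-to-genetic scaling (1 Mb per cM by
    default).  Bins are equal width in log10(distance): recent and
    distant generations are covered evenly.
    """

    min_dist_bp: int = 100_000
    max_dist_bp: int = 35_000_000
    n_bins: int = 30
    beta: float = 1.0
    alpha: float = 2.0
    mb_per_cm: float = 1.0
    mapping: str = "sved_feldman"

    def __post_init__(self):
        if self.min_dist_bp >= self.max_dist_bp:
            raise ValueError("min_dist_bp must be below max_dist_bp")
        if self.n_bins < 1 or self.beta <= 0:
            raise ValueError("n_bins >= 1 and beta > 0 required")
        if self.mapping not in _MAPPINGS:
            raise ValueError(f"unknown mapping {self.mapping!r}")

    def bin_edges(self) -> np.ndarray:
        return np.logspace(np.log10(self.min_dist_bp),
                           np.log10(self.max_dist_bp), self.n_bins + 1)

    def bp_to_morgan(self, d_bp) -> np.ndarray:
        # bp -> Mb -> cM -> Morgan
        return np.asarray(d_bp, dtype=float) / 1e6 / self.mb_per_cm / 100.0


def _pair_r2_complete_case(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 3:
        return np.nan
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def pairwise_r2(gm: GenotypeMatrix, mm: MarkerMap,
                cfg: LDConfig | None = None) -> pd.DataFrame:
    """Binned mean r^2 over same-chromosome SNP pairs.

    Pairs are restricted to distances in ``[min_dist_bp, max_dist_bp]``
    and assigned to log-spaced distance bins.  Pairs involving a locus
    monomorphic in the complete-case subset have an undefined
    correlation and are skipped (counted per bin).

    Returns one row per bin: mean distance, pair count, mean r^2 and
    skip count.
    """
    cfg = cfg or LDConfig()
    edges = cfg.bin_edges()
    nb = cfg.n_bins
    sum_r2 = np.zeros(nb)
    sum_d = np.zeros(nb)
    n_pairs = np.zeros(nb, dtype=np.int64)
    n_skipped = np.zeros(nb, dtype=np.int64)
    any_missing = bool((gm.dosages < 0).any())
    for c in mm.chromosomes():
        idx = mm.chrom_indices(c)
        pos = mm.pos_bp[idx].astype(np.int64)
        g = gm.dosages[:, idx]
        mlen = len(idx)
        if mlen < 2:
            continue
        if not any_missing:
            gf = g.astype(float)
            sd = gf.std(axis=0)
            mono = sd == 0.0
            gz = (gf - gf.mean(axis=0)) / np.where(mono, 1.0, sd)
            R = (gz.T @ gz) / gm.n_animals
            iu, ju = np.triu_indices(mlen, k=1)
            d = (pos[ju] - pos[iu]).astype(float)
            inwin = (d >= cfg.min_dist_bp) & (d <= cfg.max_dist_bp)
            iu, ju, d = iu[inwin], ju[inwin], d[inwin]
            r2 = R[iu, ju] ** 2
            bad = mono[iu] | mono[ju]
            b = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, nb - 1)
            np.add.at(n_skipped, b[bad], 1)
            b, r2, d = b[~bad], r2[~bad], d[~bad]
            np.add.at(sum_r2, b, r2)
            np.add.at(sum_d, b, d)
            np.add.at(n_pairs, b, 1)
        else:
            for a in range(mlen):
                hi = np.searchsorted(pos, pos[a] + cfg.max_dist_bp, side="right")
                for bcol in range(a + 1, hi):
                    d = float(pos[bcol] - pos[a])
                    if d < cfg.min_dist_bp:
                        continue
                    r2 = _pair_r2_complete_case(g[:, a], g[:, bcol])
                    bi = min(nb - 1, max(0, int(np.searchsorted(edges, d, side="right") - 1)))
                    if np.isnan(r2):
                        n_skipped[bi] += 1
                        continue
                    sum_r2[bi] += r2
                    sum_d[bi] += d
                    n_pairs[bi] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(n_pairs > 0, sum_r2 / np.maximum(n_pairs, 1), np.nan)
        mean_d = np.where(n_pairs > 0, sum_d / np.maximum(n_pairs, 1), np.nan)
    return pd.DataFrame(
        {"bin": np.arange(nb), "d_bp": mean_d, "n_pairs": n_pairs,
         "r2": mean_r2, "n_skipped": n_skipped}
    )


def adjust_r2(binned: pd.DataFrame, n_animals: int,
              cfg: LDConfig | None = None) -> pd.DataFrame:
    """Subtract the finite-sample bias 1/(beta*n) from each bin mean.

    Bins whose adjusted value is non-positive cannot be inverted for Ne
    and are flagged unusable.
    """
    cfg = cfg or LDConfig()
    if n_animals <= 1:
        raise ValueError("sample-size adjustment requires n > 1")
    out = binned.copy()
    out["r2_adj"] = out["r2"] - 1.0 / (cfg.beta * n_animals)
    out["usable"] = (out["r2_adj"] > 0.0) & (out["n_pairs"] > 0)
    return out


def ne_trajectory(adjusted: pd.DataFrame,
                  cfg: LDConfig | None = None) -> pd.DataFrame:
    """Historical Ne per distance bin.

    For each usable bin: ``c`` from the configured mapping of the mean
    distance in Morgans, ``t = 1/(2c)`` generations ago (reported raw
    and rounded), and ``Ne = (1/(4c)) * (1/r_adj^2 - alpha)``.  Bins
    where ``1/r_adj^2 <= alpha`` would give a non-positive Ne and are
    dropped with a warning.  Rows are sorted by t ascending (recent
    first).
    """
    cfg = cfg or LDConfig()
    mapping = _MAPPINGS[cfg.mapping]
    rows = adjusted[adjusted.get("usable", True) == True].copy()  # noqa: E712
    if rows.empty:
        warnings.warn("no usable LD bins for a Ne trajectory")
        return pd.DataFrame(columns=["bin", "d_bp", "d_morgan", "c", "t", "t_gen",
                                     "n_pairs", "r2", "r2_adj", "ne"])
    d_m = cfg.bp_to_morgan(rows["d_bp"].to_numpy())
    c = mapping(d_m)
    inv = 1.0 / rows["r2_adj"].to_numpy()
    ok = inv > cfg.alpha
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} bins with non-positive Ne")
    rows = rows.loc[ok]
    d_m, c, inv = d_m[ok], c[ok], inv[ok]
    t = 1.0 / (2.0 * c)
    ne = (inv - cfg.alpha) / (4.0 * c)
    out = pd.DataFrame(
        {"bin": rows["bin"].to_numpy(), "d_bp": rows["d_bp"].to_numpy(),
         "d_morgan": d_m, "c": c, "t": t,
         "t_gen": np.rint(t).astype(int), "n_pairs": rows["n_pairs"].to_numpy(),
         "r2": rows["r2"].to_numpy(), "r2_adj": rows["r2_adj"].to_numpy(),
         "ne": ne}
    )
    return out.sort_values("t").reset_index(drop=True)


def ld_ne_pipeline(gm: GenotypeMatrix, mm: MarkerMap,
                   cfg: LDConfig | None = None):
    """Convenience wrapper: r^2 bins -> bias adjustment -> Ne trajectory.

    Returns ``(binned_with_adjustment, trajectory)``.
    """
    cfg = cfg or LDConfig()
    binned = pairwise_r2(gm, mm, cfg)
    adj = adjust_r2(binned, gm.n_animals, cfg)
    return adj, ne_trajectory(adj, cfg)
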