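"""VanRaden genomic relationship matrix and GRM-based inbreeding.

``G = Z Z' / (2 * sum p_i (1 - p_i))`` with ``Z`` the centred gene
content (dosage minus ``2p``).  Genomic inbreeding is
``F_GRM = diag(G) - 1`` and may be negative for animals more
heterozygous than the reference allele frequencies imply.

With frequencies fixed at 0.5 (the robust choice when few animals are
genotyped, since observed frequencies are then poorly estimated), the
diagonal has the closed form ``G_ii = 2 * (homozygous fraction)`` and
``F_GRM = 1 - 2 * (heterozygous fraction)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix

__all__ = ["GRMResult", "build_grm", "write_grm"]


@dataclass
class GRMResult:
    ids: np.ndarray
    G: np.ndarray
    fgrm: np.ndarray
    freq_mode: str
    freqs: np.ndarray
    n_markers_used: int


def build_grm(gm: GenotypeMatrix, freq_mode: str = "fixed_half",
              freqs=None) -> GRMResult:
    """Build the genomic relationship matrix.

    Parameters
    ----------
    gm : GenotypeMatrix
        QC'd dosages; missing calls are imputed to ``2p`` (they
        contribute zero to ``Z``, the standard VanRaden treatment).
    freq_mode : {"fixed_half", "observed", "supplied"}
        Allele frequencies used for centring and scaling.  With
        ``observed``, monomorphic loci (p in {0, 1}) carry no variance
        and are dropped with a warning.
    freqs : array, optional
        Per-locus frequencies for ``freq_mode="supplied"``.
    """
    if gm.n_animals < 2 or gm.n_markers < 1:
        raise ValueError("GRM needs at least 2 animals and 1 marker")
    d = gm.dosages.astype(float)
    miss = d < 0
    if freq_mode == "fixed_half":
        p = np.full(gm.n_markers, 0.5)
    elif freq_mode == "observed":
        dm = np.ma.masked_array(d, mask=miss)
        p = (dm.mean(axis=0) / 2.0).filled(np.nan)
    elif freq_mode == "supplied":
        if freqs is None:
            raise ValueError("freq_mode='supplied' requires freqs")
        p = np.asarray(freqs, dtype=float)
        if p.shape != (gm.n_markers,):
            raise ValueError("freqs length must match marker count")
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} zero-variance loci from the GRM"
        )
        d, miss, p = d[:, usable], miss[:, usable], p[usable]
    if d.shape[1] == 0:
        raise ValueError("no usable loci for the GRM")
    Z = d - 2.0 * p
    Z[miss] = 0.0  # impute missing to 2p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return GRMResult(gm.ids, G, np.diag(G) - 1.0, freq_mode, p, d.shape[1])


def write_grm(res: GRMResult, matrix_path, ids_path) -> None:
    """Dense whitespace matrix plus an animal-id sidecar file."""
    np.savetxt(matrix_path, res.G, fmt="%.10g")
    with open(ids_path, "w") as fh:
        for a in res.ids:
            fh.write(f"{a}\n")
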