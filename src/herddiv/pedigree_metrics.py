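"""Pedigree-based diversity metrics.

Implements the classical pedigree-analysis toolkit for livestock
populations:

* **F** — the inbreeding coefficient, the probability that the two
  alleles at a locus are identical by descent, computed with the
  Meuwissen & Luo algorithm (equivalent to ``diag(A) - 1`` of the
  additive relationship matrix).
* **AR** — the relatedness coefficient: the animal's mean additive
  relationship to every animal in the pedigree, divided by two; the
  probability that a random allele from the population descends from
  the animal.
* **EqG** — equivalent complete generations, ``sum((1/2)^n)`` over all
  known ancestors, counting an ancestor once per distinct path of
  length ``n``.
* **PCI** — pedigree completeness: per ancestral generation ``d``, the
  mean proportion of the ``2^d`` ancestor slots that are filled.
* Generation intervals along the four parent-offspring selection paths
  (sire–sire, sire–dam, dam–sire, dam–dam), restricted to offspring
  that themselves reproduce.
* Realized effective population size from the individual rate of
  inbreeding ``dF_i = 1 - (1 - F_i)^(1/(EqG_i - 1))`` and
  ``Ne = 1 / (2 * mean(dF))``.
* Probabilities of gene origin: effective number of founders
  ``fe = 1 / sum(q_k^2)`` and of ancestors ``fa = 1 / sum(p_k^2)``
  (marginal contributions selected greedily), with ``fa <= fe``
  signalling bottlenecks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Pedigree

__all__ = [
    "inbreeding_meuwissen_luo",
    "a_matrix",
    "relatedness_ar",
    "equivalent_generations",
    "pedigree_completeness",
    "generation_intervals",
    "GenerationIntervalTable",
    "pooled_generation_interval",
    "realized_ne",
    "NeEstimate",
    "ReferencePopulation",
    "reference_population",
    "effective_founders",
    "effective_ancestors",
    "GeneOriginResult",
    "count_full_sibs",
    "compute_pedigree_metrics",
    "PedigreeMetrics",
]


def inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen & Luo algorithm.

    For each animal the algorithm traces its ancestor list once,
    accumulating path coefficients ``L`` and within-family variances
    ``D``; the diagonal of the relationship matrix is
    ``a_ii = sum_j L_j^2 D_j`` and ``F_i = a_ii - 1``.  Founders have
    ``F = 0`` and unknown parents contribute no relationship.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            continue  # founder: F = 0
        L[i] = 1.0
        aii = 0.0
        # ancestors always precede i in topological order
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            s, d = sire[j], dam[j]
            Fs = F[s] if s >= 0 else -1.0
            Fd = F[d] if d >= 0 else -1.0
            aii += lj * lj * (0.5 - 0.25 * (Fs + Fd))
            if s >= 0:
                L[s] += 0.5 * lj
            if d >= 0:
                L[d] += 0.5 * lj
            L[j] = 0.0
        F[i] = aii - 1.0
    return F


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Full additive (numerator) relationship matrix by the tabular method.

    ``a_ij = (a_i,sire(j) + a_i,dam(j)) / 2`` and
    ``a_jj = 1 + a_sire(j),dam(j) / 2``.  O(n^2) memory; intended for
    moderate pedigrees and as the oracle for the fast algorithms.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def relatedness_ar(ped: Pedigree) -> np.ndarray:
    """Relatedness coefficient AR_i = (1/(2n)) * sum_j a_ij.

    Computed in O(n) via the decomposition ``A = T D T'`` of the
    relationship matrix: the row sums are ``s = T (D (T' 1))``, where
    ``u = T' 1`` follows the child recursion
    ``u_j = 1 + 0.5 * sum_{c: j parent of c} u_c`` and ``s = T w``
    follows ``s_i = w_i + 0.5 s_sire + 0.5 s_dam``.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = inbreeding_meuwissen_luo(ped)
    u = np.ones(n)
    for i in range(n - 1, -1, -1):
        for p in (sire[i], dam[i]):
            if p >= 0:
                u[p] += 0.5 * u[i]
    Fs = np.where(sire >= 0, F[np.maximum(sire, 0)], -1.0)
    Fd = np.where(dam >= 0, F[np.maximum(dam, 0)], -1.0)
    D = 0.5 - 0.25 * (Fs + Fd)
    w = D * u
    s = np.zeros(n)
    for i in range(n):
        s[i] = w[i]
        if sire[i] >= 0:
            s[i] += 0.5 * s[sire[i]]
        if dam[i] >= 0:
            s[i] += 0.5 * s[dam[i]]
    return s / (2.0 * n)


def equivalent_generations(ped: Pedigree) -> np.ndarray:
    """Equivalent complete generations: EqG_i = sum over known-ancestor
    paths of (1/2)^length, via EqG_i = sum_{known parent p} 0.5 (1 + EqG_p)."""
    n = ped.n
    eqg = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                acc += 0.5 * (1.0 + eqg[p])
        eqg[i] = acc
    return eqg


def pedigree_completeness(ped: Pedigree, max_depth: int = 10,
                          subset: np.ndarray | None = None) -> pd.DataFrame:
    """Pedigree completeness index by ancestral generation.

    For generation ``d`` (1 = parents, 2 = grandparents, ...) the index
    is the mean over animals of (known ancestor slots at depth d) / 2^d,
    so an animal with three of four grandparents known scores 0.75 at
    depth 2.  ``subset`` restricts the averaged animals (boolean mask or
    index array over the pedigree).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    n = ped.n
    known = np.zeros((n, max_depth + 1))
    known[:, 0] = 1.0
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                known[i, 1:] += known[p, :-1]
    rows = np.arange(n) if subset is None else np.asarray(subset)
    depths = np.arange(1, max_depth + 1)
    pci = known[rows][:, 1:].mean(axis=0) / 2.0 ** depths
    return pd.DataFrame({"generation": depths, "pci": pci})


_PATHS = {("M", "M"): "sire-sire", ("M", "F"): "sire-dam",
          ("F", "M"): "dam-sire", ("F", "F"): "dam-dam"}


@dataclass
class GenerationIntervalTable:
    """Generation-interval summary per selection path plus the pooled value.

    ``table`` holds one row per path (n, mean years, SE) and a pooled
    row computed at the record level, i.e. the count-weighted mean of
    the path means.
    """

    table: pd.DataFrame
    records: pd.DataFrame
    n_excluded_unknown_sex: int = 0

    @property
    def pooled_mean(self) -> float:
        return float(self.table.loc[self.table["path"] == "pooled", "mean_years"].iloc[0])


def pooled_generation_interval(path_means, path_counts) -> float:
    """Record-level (count-weighted) pooled generation interval."""
    m = np.asarray(path_means, dtype=float)
    c = np.asarray(path_counts, dtype=float)
    return float(np.sum(m * c) / np.sum(c))


def generation_intervals(ped: Pedigree, subset: np.ndarray | None = None) -> GenerationIntervalTable:
    """Generation intervals along the four selection paths.

    Each record is a parent's age (years) at the birth of an offspring
    that itself has progeny (kept for reproduction); the path is
    determined by parent sex x offspring sex.  Offspring of unknown sex
    are excluded and counted.  ``subset`` restricts the offspring
    considered (indices into the pedigree).
    """
    n = ped.n
    has_progeny = np.zeros(n, dtype=bool)
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                has_progeny[p] = True
    rows = np.arange(n) if subset is None else np.asarray(subset)
    recs = []
    n_unknown_sex = 0
    for o in rows:
        if not has_progeny[o] or ped.birth_year[o] < 0:
            continue
        if ped.sex[o] not in ("M", "F"):
            n_unknown_sex += 1
            continue
        for p in (ped.sire[o], ped.dam[o]):
            if p < 0 or ped.birth_year[p] < 0 or ped.sex[p] not in ("M", "F"):
                continue
            recs.append(
                {
                    "path": _PATHS[(ped.sex[p], ped.sex[o])],
                    "age_years": float(ped.birth_year[o] - ped.birth_year[p]),
                }
            )
    rec_df = pd.DataFrame(recs, columns=["path", "age_years"])
    out = []
    for path in ("sire-sire", "sire-dam", "dam-sire", "dam-dam"):
        vals = rec_df.loc[rec_df["path"] == path, "age_years"]
        if len(vals):
            out.append({"path": path, "n": len(vals), "mean_years": vals.mean(),
                        "se_years": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan})
        else:
            out.append({"path": path, "n": 0, "mean_years": np.nan, "se_years": np.nan})
    vals = rec_df["age_years"]
    out.append({
        "path": "pooled",
        "n": len(vals),
        "mean_years": vals.mean() if len(vals) else np.nan,
        "se_years": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
    })
    return GenerationIntervalTable(pd.DataFrame(out), rec_df, n_unknown_sex)


@dataclass
class NeEstimate:
    """Realized effective population size with a delta-method SE."""

    ne: float
    se: float
    ci_low: float
    ci_high: float
    mean_dF: float
    dF: np.ndarray = field(repr=False)
    n_used: int = 0
    n_excluded: int = 0


def realized_ne(F: np.ndarray, eqg: np.ndarray, z: float = 1.96) -> NeEstimate:
    """Realized Ne from the individual rate of inbreeding.

    ``dF_i = 1 - (1 - F_i)^(1/(EqG_i - 1))`` for animals with
    ``EqG_i > 1`` (others are excluded: the exponent is degenerate);
    ``Ne = 1 / (2 mean(dF))``.  The SE follows by the delta method:
    ``SE(Ne) = SD(dF)/sqrt(N) / (2 mean(dF)^2)`` and the confidence
    interval is ``Ne +/- z * SE``.
    """
    F = np.asarray(F, dtype=float)
    eqg = np.asarray(eqg, dtype=float)
    dF = np.full(F.shape, np.nan)
    ok = eqg > 1.0
    dF[ok] = 1.0 - (1.0 - F[ok]) ** (1.0 / (eqg[ok] - 1.0))
    vals = dF[ok]
    n_used = int(ok.sum())
    mean_dF = float(vals.mean()) if n_used else np.nan
    if not n_used or mean_dF <= 0.0:
        warnings.warn("mean dF is zero; realized Ne is infinite")
        return NeEstimate(np.inf, np.nan, np.nan, np.nan, mean_dF, dF,
                          n_used, int((~ok).sum()))
    ne = 1.0 / (2.0 * mean_dF)
    se_mean = float(vals.std(ddof=1)) / np.sqrt(n_used) if n_used > 1 else np.nan
    se = se_mean / (2.0 * mean_dF**2)
    return NeEstimate(ne, se, ne - z * se, ne + z * se, mean_dF, dF,
                      n_used, int((~ok).sum()))


@dataclass
class ReferencePopulation:
    """Animals born inside a birth-year window [start, end]."""

    start_year: int
    end_year: int
    indices: np.ndarray

    @property
    def n(self) -> int:
        return len(self.indices)


def reference_population(ped: Pedigree, start_year: int | None = None,
                         end_year: int | None = None,
                         window_years: int | None = None) -> ReferencePopulation:
    """Select a reference cohort by birth year.

    With no explicit window, the default is the last ``ceil(pooled GI)``
    years of the pedigree — the animals born within roughly one
    generation of the most recent birth year.
    """
    years = ped.birth_year
    known = years[years >= 0]
    if known.size == 0:
        raise ValueError("pedigree carries no birth years")
    last = int(known.max())
    if end_year is None:
        end_year = last
    if start_year is None:
        if window_years is None:
            gi = generation_intervals(ped).pooled_mean
            window_years = int(np.ceil(gi)) if np.isfinite(gi) else 1
        start_year = end_year - window_years + 1
    idx = np.flatnonzero((years >= start_year) & (years <= end_year))
    return ReferencePopulation(start_year, end_year, idx)


@dataclass
class GeneOriginResult:
    """Probabilities of gene origin for a reference cohort.

    ``contributions`` maps founder/ancestor label -> expected
    proportional contribution; phantom slots for half-known parentage
    are labelled ``"phantom:<animal>:<slot>"``.
    """

    contributions: dict
    effective_number: float
    selected_order: list = field(default_factory=list)
    n_50pct: int | None = None
    total_explained: float = 1.0


def _ref_indices(ped: Pedigree, ref) -> np.ndarray:
    if ref is None:
        return np.arange(ped.n)
    if isinstance(ref, ReferencePopulation):
        return ref.indices
    return np.asarray(ref)


def effective_founders(ped: Pedigree, ref=None) -> GeneOriginResult:
    """Effective number of founders fe = 1 / sum(q_k^2).

    ``q_k`` is the expected proportional contribution of founder ``k``
    to the reference cohort, obtained by passing half of each animal's
    weight to each parent line; a missing parent slot of a non-founder
    becomes a phantom founder.  Contributions sum to one.
    """
    idx = _ref_indices(ped, ref)
    if idx.size == 0:
        raise ValueError("empty reference population")
    n = ped.n
    w = np.zeros(n)
    w[idx] = 1.0 / idx.size
    contrib: dict = {}
    for i in range(n - 1, -1, -1):
        if w[i] == 0.0:
            continue
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            contrib[ped.ids[i]] = contrib.get(ped.ids[i], 0.0) + w[i]
            continue
        for p, slot in ((s, "sire"), (d, "dam")):
            if p >= 0:
                w[p] += 0.5 * w[i]
            else:
                key = f"phantom:{ped.ids[i]}:{slot}"
                contrib[key] = contrib.get(key, 0.0) + 0.5 * w[i]
    q = np.array(list(contrib.values()))
    fe = 1.0 / float(np.sum(q**2))
    return GeneOriginResult(contrib, fe)


def effective_ancestors(ped: Pedigree, ref=None, tol: float = 1e-9,
                        max_ancestors: int | None = None) -> GeneOriginResult:
    """Effective number of ancestors fa = 1 / sum(p_k^2) (greedy selection).

    Iteratively selects the ancestor with the largest *marginal*
    expected contribution to the reference cohort — the probability
    that a random reference gene's line of descent passes through the
    candidate while avoiding every previously selected ancestor, so
    each gene is credited exactly once, to the earliest-selected node
    on its path.  Two ingredients per round: reference weight is
    propagated upwards but stops at any selected ancestor (paths
    blocked *below* the candidate), and the result is multiplied by the
    probability that the ancestral path continuing *above* the
    candidate never meets a selected ancestor.  Phantom founders stand
    in for half-known parentage so the gene pool matches
    :func:`effective_founders` and ``fa <= fe``.

    Also reports the number of ancestors (in selection order) that
    jointly explain at least half of the gene pool.
    """
    idx = _ref_indices(ped, ref)
    if idx.size == 0:
        raise ValueError("empty reference population")
    n = ped.n
    selected: dict = {}
    order: list = []
    phantom_selected: set = set()
    explained = 0.0
    cap = max_ancestors if max_ancestors is not None else n + 2 * n
    sel_mask = np.zeros(n, dtype=bool)
    while explained < 1.0 - tol and len(order) < cap:
        w = np.zeros(n)
        w[idx] += 1.0 / idx.size
        phantom_w: dict = {}
        for i in range(n - 1, -1, -1):
            if w[i] == 0.0 or sel_mask[i]:
                continue
            s, d = ped.sire[i], ped.dam[i]
            if s < 0 and d < 0:
                continue  # weight rests on this (unselected) founder
            for p, slot in ((s, "sire"), (d, "dam")):
                if p >= 0:
                    if not sel_mask[p]:
                        w[p] += 0.5 * w[i]
                    # weight reaching a selected ancestor is already explained
                else:
                    key = f"phantom:{ped.ids[i]}:{slot}"
                    if key not in phantom_selected:
                        phantom_w[key] = phantom_w.get(key, 0.0) + 0.5 * w[i]
        # P(upward path from x avoids the selected set); parents precede
        # children, so a single forward pass suffices
        avoid = np.ones(n)
        for i in range(n):
            if sel_mask[i]:
                avoid[i] = 0.0
                continue
            s, d = ped.sire[i], ped.dam[i]
            if s < 0 and d < 0:
                avoid[i] = 1.0
                continue
            acc = 0.0
            for p, slot in ((s, "sire"), (d, "dam")):
                if p >= 0:
                    acc += 0.5 * avoid[p]
                else:
                    key = f"phantom:{ped.ids[i]}:{slot}"
                    acc += 0.5 * (0.0 if key in phantom_selected else 1.0)
            avoid[i] = acc
        w = w * avoid
        w[sel_mask] = 0.0
        best_i = int(np.argmax(w)) if n else -1
        best_w = w[best_i] if n else 0.0
        best_ph, best_ph_w = None, 0.0
        if phantom_w:
            best_ph = max(phantom_w, key=lambda k: (phantom_w[k], k))
            best_ph_w = phantom_w[best_ph]
        if max(best_w, best_ph_w) <= tol:
            break
        if best_w >= best_ph_w:
            sel_mask[best_i] = True
            label, p_k = ped.ids[best_i], float(best_w)
        else:
            phantom_selected.add(best_ph)
            label, p_k = best_ph, float(best_ph_w)
        selected[label] = p_k
        order.append((label, p_k))
        explained += p_k
    p = np.array([v for _, v in order])
    fa = 1.0 / float(np.sum(p**2))
    csum = np.cumsum(p)
    hit = np.flatnonzero(csum >= 0.5)
    n50 = int(hit[0] + 1) if hit.size else None
    return GeneOriginResult(selected, fa, order, n50, float(explained))


def count_full_sibs(ped: Pedigree) -> int:
    """Number of animals belonging to a full-sib group (both parents
    shared with at least one other animal)."""
    pairs: dict = {}
    for i in range(ped.n):
        if ped.sire[i] >= 0 and ped.dam[i] >= 0:
            pairs.setdefault((ped.sire[i], ped.dam[i]), []).append(i)
    return sum(len(v) for v in pairs.values() if len(v) >= 2)


@dataclass
class PedigreeMetrics:
    """Bundle of all pedigree metrics for a run (per-animal + population)."""

    per_animal: pd.DataFrame
    pci_total: pd.DataFrame
    pci_reference: pd.DataFrame
    gi_total: GenerationIntervalTable
    gi_reference: GenerationIntervalTable
    ne: NeEstimate
    fe_total: GeneOriginResult
    fa_total: GeneOriginResult
    fe_reference: GeneOriginResult
    fa_reference: GeneOriginResult
    reference: ReferencePopulation
    n_full_sibs: int = 0

    def population_summary(self) -> dict:
        ref = self.reference
        return {
            "n_animals": int(len(self.per_animal)),
            "reference_window": [int(ref.start_year), int(ref.end_year)],
            "n_reference": int(ref.n),
            "mean_F_pct": float(self.per_animal["F"].mean() * 100),
            "mean_AR_pct": float(self.per_animal["AR"].mean() * 100),
            "mean_EqG": float(self.per_animal["EqG"].mean()),
            "gi_pooled_total_years": self.gi_total.pooled_mean,
            "gi_pooled_reference_years": self.gi_reference.pooled_mean,
            "ne_realized": self.ne.ne,
            "ne_se": self.ne.se,
            "ne_ci": [self.ne.ci_low, self.ne.ci_high],
            "fe_total": self.fe_total.effective_number,
            "fa_total": self.fa_total.effective_number,
            "fa_fe_ratio_total": self.fa_total.effective_number / self.fe_total.effective_number,
            "fe_reference": self.fe_reference.effective_number,
            "fa_reference": self.fa_reference.effective_number,
            "fa_fe_ratio_reference": self.fa_reference.effective_number / self.fe_reference.effective_number,
            "n_ancestors_50pct_total": self.fa_total.n_50pct,
            "n_ancestors_50pct_reference": self.fa_reference.n_50pct,
            "n_full_sibs": int(self.n_full_sibs),
        }


def compute_pedigree_metrics(ped: Pedigree, ref: ReferencePopulation | None = None,
                             max_depth: int = 10) -> PedigreeMetrics:
    """Run the full pedigree analysis: per-animal F/AR/EqG/dF plus
    population-level completeness, generation intervals, realized Ne and
    probabilities of gene origin for the whole pedigree and a reference
    cohort (default: last ~one generation interval of birth years)."""
    F = inbreeding_meuwissen_luo(ped)
    ar = relatedness_ar(ped)
    eqg = equivalent_generations(ped)
    ne = realized_ne(F, eqg)
    if ref is None:
        ref = reference_population(ped)
    per_animal = pd.DataFrame(
        {"animal": ped.ids, "F": F, "AR": ar, "EqG": eqg, "dF": ne.dF}
    )
    return PedigreeMetrics(
        per_animal=per_animal,
        pci_total=pedigree_completeness(ped, max_depth),
        pci_reference=pedigree_completeness(ped, max_depth, subset=ref.indices),
        gi_total=generation_intervals(ped),
        gi_reference=generation_intervals(ped, subset=ref.indices),
        ne=ne,
        fe_total=effective_founders(ped),
        fa_total=effective_ancestors(ped),
        fe_reference=effective_founders(ped, ref),
        fa_reference=effective_ancestors(ped, ref),
        reference=ref,
        n_full_sibs=count_full_sibs(ped),
    )
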