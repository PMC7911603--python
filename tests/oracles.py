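"""Independent oracle implementations used only by the test suite.

Each oracle deliberately uses a different mechanism from the library
code it checks (path enumeration instead of recursion, window
enumeration instead of a state machine, normal equations instead of a
fitted model object, enumeration instead of a recurrence), so that
agreement is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------- pedigree

def eqg_paths(ped, i: int) -> float:
    """Equivalent generations by explicit DFS over all ancestor paths."""
    total = 0.0
    stack = [(i, 0)]
    while stack:
        node, depth = stack.pop()
        for p in (ped.sire[node], ped.dam[node]):
            if p >= 0:
                total += 0.5 ** (depth + 1)
                stack.append((p, depth + 1))
    return total


def known_ancestor_slots(ped, i: int, depth: int) -> int:
    """Number of filled ancestor slots at a given depth, by frontier walk."""
    frontier = [i]
    for _ in range(depth):
        nxt = []
        for node in frontier:
            for p in (ped.sire[node], ped.dam[node]):
                if p >= 0:
                    nxt.append(p)
        frontier = nxt
    return len(frontier)


def _upward_paths(ped, i: int):
    """All (node-tuple, probability) ancestral paths from animal i.

    A path steps to each known parent with probability 1/2 and
    terminates at a founder or at a phantom terminal for an unknown
    parent slot of a non-founder.  Terminals are encoded as the last
    element: an int index (founder) or a phantom key string.
    """
    s, d = ped.sire[i], ped.dam[i]
    if s < 0 and d < 0:
        yield (i,), 1.0
        return
    for p, slot in ((s, "sire"), (d, "dam")):
        if p >= 0:
            for nodes, pr in _upward_paths(ped, p):
                yield (i,) + nodes, 0.5 * pr
        else:
            yield (i, f"phantom:{ped.ids[i]}:{slot}"), 0.5


def fa_greedy_paths(ped, ref_indices=None, rounds=None):
    """Effective number of ancestors by explicit path enumeration.

    At each round, every candidate's marginal contribution is the total
    probability of reference ancestral paths that pass through it while
    avoiding every already-selected node.  Only feasible for tiny
    pedigrees.  Returns (selection order [(label, p)], fa).
    """
    n = ped.n
    idx = np.arange(n) if ref_indices is None else np.asarray(ref_indices)
    all_paths = []
    for i in idx:
        for nodes, pr in _upward_paths(ped, int(i)):
            labelled = tuple(
                nd if isinstance(nd, str) else ped.ids[nd] for nd in nodes
            )
            all_paths.append((labelled, pr / len(idx)))
    candidates = sorted({nd for nodes, _ in all_paths for nd in nodes})
    selected: list = []
    sel_set: set = set()
    total = 0.0
    cap = rounds if rounds is not None else len(candidates)
    while total < 1.0 - 1e-12 and len(selected) < cap:
        best, best_w = None, -1.0
        for cand in candidates:
            if cand in sel_set:
                continue
            w = sum(pr for nodes, pr in all_paths
                    if cand in nodes and not any(nd in sel_set for nd in nodes))
            if w > best_w:
                best, best_w = cand, w
        if best is None or best_w <= 1e-12:
            break
        selected.append((best, best_w))
        sel_set.add(best)
        total += best_w
    fa = 1.0 / sum(p * p for _, p in selected)
    return selected, fa


def founder_contributions_gene_drop(ped, ref_indices=None, n_reps=100_000,
                                    seed=0) -> dict:
    """Monte-Carlo founder contributions by single-locus gene dropping.

    Drops one biallelic origin label down the pedigree ``n_reps`` times
    (vectorized across replicates) and reports, per founder/phantom,
    the mean fraction of reference-cohort alleles descending from it.
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    idx = np.arange(n) if ref_indices is None else np.asarray(ref_indices)
    orig = np.zeros((n, 2, n_reps), dtype=np.int32)
    labels: dict = {}
    nxt = 0
    rows = np.arange(n_reps)
    for i in range(n):
        founder = ped.sire[i] < 0 and ped.dam[i] < 0
        for side, par in ((0, ped.sire[i]), (1, ped.dam[i])):
            if par < 0:
                key = ped.ids[i] if founder else (
                    f"phantom:{ped.ids[i]}:" + ("sire" if side == 0 else "dam"))
                if key not in labels:
                    labels[key] = nxt
                    nxt += 1
                orig[i, side, :] = labels[key]
            else:
                pick = rng.integers(0, 2, n_reps)
                orig[i, side, :] = orig[par, pick, rows]
    ref_alleles = orig[idx]  # (ref, 2, reps)
    return {k: float((ref_alleles == v).mean()) for k, v in labels.items()}


# -------------------------------------------------------------------- runs

def roh_windows(geno: np.ndarray, pos: np.ndarray, min_snp: int,
                min_len_bp: int, max_gap_bp: int):
    """Strict homozygous runs by block splitting (no state machine).

    Splits the marker sequence at every heterozygous or missing call
    and at every oversized gap with numpy set operations; each
    remaining block is a maximal valid window, kept if it satisfies
    the SNP-count and span thresholds.
    """
    m = len(pos)
    hom = (geno == 0) | (geno == 2)
    bad = np.flatnonzero(~hom)
    gap_after = np.flatnonzero(np.diff(pos) > max_gap_bp)  # break between k, k+1
    cut = np.zeros(m + 1, dtype=bool)
    cut[0] = cut[m] = True
    cut[bad] = True
    cut[bad + 1] = True
    cut[gap_after + 1] = True
    edges = np.flatnonzero(cut)
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a == 0 or not hom[a]:
            continue
        s, e = int(a), int(b - 1)
        if not hom[s:e + 1].all():
            continue
        if e - s + 1 >= min_snp and pos[e] - pos[s] >= min_len_bp:
            out.append((s, e))
    return out


def rohet_windows(geno: np.ndarray, pos: np.ndarray, min_snp: int,
                  min_len_bp: int, max_gap_bp: int, max_hom: int,
                  max_missing: int):
    """Tolerant heterozygous runs by longest-valid-window search.

    From each candidate start, the longest window that starts and ends
    on a heterozygote, keeps every gap within bounds and tolerates at
    most ``max_hom`` homozygous and ``max_missing`` missing interior
    calls is found by re-validating each candidate end from scratch
    (window validity is monotone in the end position, so the ascending
    search can stop at the first irrecoverable violation); scanning
    resumes at the next heterozygote after the window.
    """
    m = len(pos)
    het = geno == 1
    miss = geno < 0

    def valid(i, e):
        if not het[i] or not het[e]:
            return False
        nh = nm = 0
        for k in range(i + 1, e + 1):
            if pos[k] - pos[k - 1] > max_gap_bp:
                return False
            if miss[k]:
                nm += 1
            elif not het[k]:
                nh += 1
            if nh > max_hom or nm > max_missing:
                return False
        return True

    def dead(i, e):
        # no window [i, e'] with e' >= e can be valid
        if e > i and pos[e] - pos[e - 1] > max_gap_bp:
            return True
        nh = sum(1 for k in range(i + 1, e + 1) if not miss[k] and not het[k])
        nm = sum(1 for k in range(i + 1, e + 1) if miss[k])
        return nh > max_hom or nm > max_missing

    out = []
    i = 0
    while i < m:
        if not het[i]:
            i += 1
            continue
        best = i
        for e in range(i + 1, m):
            if dead(i, e):
                break
            if valid(i, e):
                best = e
        if best - i + 1 >= min_snp and pos[best] - pos[i] >= min_len_bp:
            out.append((i, best))
        nxt = best + 1
        while nxt < m and not het[nxt]:
            nxt += 1
        i = nxt
    return out


# -------------------------------------------------------------- statistics

def hwe_enumeration(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE p-value by direct enumeration with log-factorials.

    Conditional on the allele counts, P(h heterozygotes) is
    proportional to the multinomial coefficient times 2^h; the p-value
    sums probabilities not exceeding the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)

    def logw(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        return (h * math.log(2.0) - math.lgamma(hr + 1)
                - math.lgamma(h + 1) - math.lgamma(hc + 1))

    hs = list(range(rare % 2, rare + 1, 2))
    lw = np.array([logw(h) for h in hs])
    w = np.exp(lw - lw.max())
    probs = w / w.sum()
    p_obs = probs[hs.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def ols_normal_equations(pt: pd.DataFrame, f_pct: pd.Series):
    """Depression regression by explicit normal equations.

    Builds the dummy design by hand, solves X'X b = X'y with
    ``numpy.linalg.lstsq`` and derives SE and two-sided p for the
    inbreeding slope from the residual variance.  Returns
    (beta1, se, p_value).
    """
    df = pt.copy()
    df["F_pct"] = df["animal_id"].map(f_pct) * 100.0
    df = df.dropna(subset=["F_pct"])
    y = df["value"].to_numpy(float)
    cols = [np.ones(len(df))]
    for lv in sorted(df["sex"].unique())[1:]:
        cols.append((df["sex"] == lv).to_numpy(float))
    years = sorted(df["birth_year"].astype(int).unique())
    for lv in years[1:]:
        cols.append((df["birth_year"].astype(int) == lv).to_numpy(float))
    cols.append(df["F_pct"].to_numpy(float))
    X = np.column_stack(cols)
    b, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    dof = len(y) - rank
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[-1, -1])
    tval = b[-1] / se
    p = 2.0 * stats.t.sf(abs(tval), dof)
    return float(b[-1]), float(se), float(p)
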