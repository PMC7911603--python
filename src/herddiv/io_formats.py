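"""File formats and genotype quality control.

Readers and writers for the three flat-file inputs of the pipeline —
pedigree CSV/TSV, PLINK-style PED/MAP genotypes, and a phenotype CSV —
plus the marker/animal quality-control step (call rate, minor allele
frequency, Hardy–Weinberg exact test, autosome filter).

Conventions
-----------
* Genotypes are stored as minor-allele dosages in {0, 1, 2}; missing
  calls are coded ``-1``.
* Base-pair positions are 1-based and intervals are closed
  ``[start_bp, end_bp]``; lengths in Mb are ``(end - start) / 1e6``.
* Unknown-parent tokens default to ``{"0", "", "NA"}`` and are
  configurable in :func:`read_pedigree`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "MarkerMap",
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "PedigreeError",
    "FormatError",
    "read_pedigree",
    "write_pedigree",
    "read_plink_pedmap",
    "write_plink_pedmap",
    "read_phenotypes",
    "write_phenotypes",
    "qc_genotypes",
    "hwe_exact_pvalue",
]

MISSING = -1
UNKNOWN_YEAR = -1
DEFAULT_UNKNOWN_TOKENS = ("0", "", "NA")

_SEX_MAP = {"m": "M", "1": "M", "male": "M", "f": "F", "2": "F", "female": "F"}


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, duplicate ids)."""


class FormatError(ValueError):
    """Raised for malformed input files."""


def _normalize_sex(tok) -> str:
    if tok is None:
        return "U"
    return _SEX_MAP.get(str(tok).strip().lower(), "U")


@dataclass
class Pedigree:
    """A validated pedigree in topological order (parents before offspring).

    Attributes
    ----------
    ids : ndarray of str
        Animal identifiers, unique, topologically ordered.
    sire, dam : ndarray of int
        Index of the parent in ``ids`` or ``-1`` if unknown.
    birth_year : ndarray of int
        Birth year, or ``-1`` if unknown.
    sex : ndarray of str
        One of ``'M'``, ``'F'``, ``'U'``.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=object)
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate animal ids")
        # topological invariant: parents precede offspring
        for i in range(self.n):
            for p in (self.sire[i], self.dam[i]):
                if p >= i:
                    raise PedigreeError(
                        f"pedigree not topologically ordered at {self.ids[i]!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def founder_mask(self) -> np.ndarray:
        """Animals with both parents unknown."""
        return (self.sire < 0) & (self.dam < 0)

    @classmethod
    def from_records(cls, records, unknown_tokens=DEFAULT_UNKNOWN_TOKENS) -> "Pedigree":
        """Build a pedigree from (animal, sire, dam, birth_year, sex) tuples.

        Unknown-parent tokens are normalized, parents without their own
        record are promoted to founders, and records are topologically
        sorted.  A cycle raises :class:`PedigreeError` naming the cycle.
        """
        unk = {str(t) for t in unknown_tokens}

        def clean(tok):
            if tok is None:
                return None
            s = str(tok).strip()
            if s in unk or s.lower() in ("nan", "none", "na"):
                return None
            return s

        ids, sire_id, dam_id, years, sexes = [], {}, {}, {}, {}
        seen = set()
        for rec in records:
            rec = tuple(rec) + (None,) * (5 - len(rec))
            a, s, d, y, x = rec[:5]
            a = str(a).strip()
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen.add(a)
            ids.append(a)
            sire_id[a] = clean(s)
            dam_id[a] = clean(d)
            try:
                years[a] = int(float(y)) if clean(y) is not None else UNKNOWN_YEAR
            except (TypeError, ValueError):
                years[a] = UNKNOWN_YEAR
            sexes[a] = _normalize_sex(x)
        # promote named parents without a record of their own to founders
        for a in list(ids):
            for p, psex in ((sire_id[a], "M"), (dam_id[a], "F")):
                if p is not None and p not in seen:
                    seen.add(p)
                    ids.append(p)
                    sire_id[p] = None
                    dam_id[p] = None
                    years[p] = UNKNOWN_YEAR
                    sexes[p] = psex
        order = cls._topological_order(ids, sire_id, dam_id)
        pos = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire = np.full(n, MISSING, dtype=np.int64)
        dam = np.full(n, MISSING, dtype=np.int64)
        by = np.full(n, UNKNOWN_YEAR, dtype=np.int64)
        sx = np.empty(n, dtype=object)
        for i, a in enumerate(order):
            if sire_id[a] is not None:
                sire[i] = pos[sire_id[a]]
            if dam_id[a] is not None:
                dam[i] = pos[dam_id[a]]
            by[i] = years[a]
            sx[i] = sexes[a]
        return cls(np.array(order, dtype=object), sire, dam, by, sx)

    @staticmethod
    def _topological_order(ids, sire_id, dam_id):
        # Kahn's algorithm, stable w.r.t. input order; leftover nodes form a cycle.
        children = {a: [] for a in ids}
        indeg = {a: 0 for a in ids}
        for a in ids:
            for p in (sire_id[a], dam_id[a]):
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        queue = [a for a in ids if indeg[a] == 0]
        order = []
        qi = 0
        while qi < len(queue):
            a = queue[qi]
            qi += 1
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(ids):
            remaining = [a for a in ids if indeg[a] > 0]
            cycle = Pedigree._find_cycle(remaining, sire_id, dam_id)
            raise PedigreeError(f"pedigree cycle detected: {' -> '.join(cycle)}")
        return order

    @staticmethod
    def _find_cycle(nodes, sire_id, dam_id):
        node_set = set(nodes)
        start = nodes[0]
        path, seen = [start], {start}
        cur = start
        while True:
            nxt = None
            for p in (sire_id[cur], dam_id[cur]):
                if p in node_set:
                    nxt = p
                    break
            if nxt is None:
                return path
            if nxt in seen:
                return path[path.index(nxt):] + [nxt]
            path.append(nxt)
            seen.add(nxt)
            cur = nxt

    def to_frame(self) -> pd.DataFrame:
        """Export as a DataFrame with '0' for unknown parents/years."""
        sire_ids = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], "0")
        dam_ids = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], "0")
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sire_ids,
                "dam": dam_ids,
                "birth_year": np.where(self.birth_year >= 0, self.birth_year, 0),
                "sex": self.sex,
            }
        )


def read_pedigree(path, unknown_tokens=DEFAULT_UNKNOWN_TOKENS, columns=None) -> Pedigree:
    """Read a pedigree CSV/TSV into a validated :class:`Pedigree`.

    The file may carry a header (columns identified by name: animal/id,
    sire, dam, birth_year/year, sex) or be positional in that order.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    named = {}
    aliases = {
        "animal": ("animal", "id", "animal_id"),
        "sire": ("sire", "father", "sire_id"),
        "dam": ("dam", "mother", "dam_id"),
        "birth_year": ("birth_year", "year", "yob"),
        "sex": ("sex",),
    }
    if columns is not None:
        named = {k: v for k, v in zip(("animal", "sire", "dam", "birth_year", "sex"), columns)}
    else:
        for key, names in aliases.items():
            for nm in names:
                if nm in cols:
                    named[key] = df.columns[cols.index(nm)]
                    break
    if "animal" not in named:  # no recognizable header: positional, no header row
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, header=None)
        df.columns = ["animal", "sire", "dam", "birth_year", "sex"][: df.shape[1]]
        named = {c: c for c in df.columns}
    recs = []
    for _, row in df.iterrows():
        recs.append(
            (
                row[named["animal"]],
                row.get(named.get("sire")),
                row.get(named.get("dam")),
                row.get(named.get("birth_year")) if "birth_year" in named else None,
                row.get(named.get("sex")) if "sex" in named else None,
            )
        )
    return Pedigree.from_records(recs, unknown_tokens=unknown_tokens)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


@dataclass
class MarkerMap:
    """SNP map: id, chromosome (1..29 autosomes for cattle) and bp position.

    Markers must be sorted by (chrom, pos) with strictly increasing
    positions within a chromosome; the constructor enforces this.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if len(self.chrom) != len(self.pos_bp) or len(self.chrom) != len(self.snp_id):
            raise FormatError("marker map column lengths differ")
        key = self.chrom.astype(np.int64) * 10**10 + self.pos_bp
        if np.any(np.diff(key) <= 0):
            raise FormatError(
                "marker map must be sorted by (chrom, pos) with strictly "
                "increasing positions within each chromosome"
            )

    @property
    def n(self) -> int:
        return len(self.snp_id)

    def chromosomes(self):
        return np.unique(self.chrom)

    def chrom_indices(self, c) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def chrom_length_bp(self, c) -> int:
        """Chromosome length = span between first and last mapped SNP."""
        idx = self.chrom_indices(c)
        return int(self.pos_bp[idx[-1]] - self.pos_bp[idx[0]])

    def laut_bp(self) -> int:
        """Total mapped autosome length (sum of per-chromosome spans)."""
        return int(sum(self.chrom_length_bp(c) for c in self.chromosomes()))

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(self.snp_id[idx], self.chrom[idx], self.pos_bp[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "chrom": self.chrom, "pos_bp": self.pos_bp}
        )


@dataclass
class GenotypeMatrix:
    """Animals x SNP minor-allele dosages; ``-1`` marks a missing call."""

    ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.ids):
            raise FormatError("dosage matrix shape inconsistent with animal ids")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def marker_call_rate(self) -> np.ndarray:
        return (self.dosages >= 0).mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return (self.dosages >= 0).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Observed minor allele frequency per marker (post-missing)."""
        d = np.ma.masked_less(self.dosages.astype(float), 0)
        p = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def het_fraction(self) -> np.ndarray:
        """Per-animal fraction of heterozygous calls among non-missing ones."""
        called = self.dosages >= 0
        het = self.dosages == 1
        with np.errstate(invalid="ignore"):
            return het.sum(axis=1) / called.sum(axis=1)

    def subset_markers(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids, self.dosages[:, idx])

    def subset_animals(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids[idx], self.dosages[idx, :])


def read_plink_pedmap(ped_path, map_path):
    """Read whitespace-delimited PLINK PED/MAP text files.

    PED columns: FID, IID, sire, dam, sex, phenotype, then two allele
    tokens per SNP; a ``0`` allele marks a missing call.  Allele pairs
    are converted to dosages by counting the minor allele per column
    (ties at frequency 0.5 broken by allele lexical order; a column with
    a single observed allele codes 0 everywhere).

    Returns ``(GenotypeMatrix, MarkerMap)`` with markers sorted by
    (chrom, pos) and dosage columns permuted accordingly.
    """
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": np.int64, "snp_id": str, "cm": float, "pos_bp": np.int64},
    )
    m = len(mp)
    ids, rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} columns, got {len(parts)}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    if not rows:
        raise FormatError(f"{ped_path}: no genotype rows")
    al = np.array(rows, dtype=object)
    a1 = al[:, 0::2]
    a2 = al[:, 1::2]
    n = len(ids)
    dos = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        c1, c2 = a1[:, j], a2[:, j]
        miss = (c1 == "0") | (c2 == "0")
        obs = np.concatenate([c1[~miss], c2[~miss]])
        if obs.size:
            alleles, counts = np.unique(obs.astype(str), return_counts=True)
            if len(alleles) >= 2:
                # minor = least frequent; ties broken lexically (alleles sorted)
                minor = alleles[np.argmin(counts)]
                d = (c1 == minor).astype(np.int8) + (c2 == minor).astype(np.int8)
                d[miss] = MISSING
                dos[:, j] = d
            else:
                dos[~miss, j] = 0
    order = np.lexsort((mp["pos_bp"].to_numpy(), mp["chrom"].to_numpy()))
    mm = MarkerMap(
        mp["snp_id"].to_numpy()[order],
        mp["chrom"].to_numpy()[order],
        mp["pos_bp"].to_numpy()[order],
    )
    return GenotypeMatrix(np.array(ids, dtype=object), dos[:, order]), mm


def write_plink_pedmap(gm: GenotypeMatrix, mm: MarkerMap, ped_path, map_path,
                       alleles=("A", "B")) -> None:
    """Write genotypes as PLINK PED/MAP text.

    The dosage-counted allele is written as ``alleles[0]`` and the other
    as ``alleles[1]``; missing calls become ``0 0``.  Reading the file
    back yields the minor-allele recoding of the written dosages (the
    identity whenever per-column dosage frequency is <= 0.5).
    """
    a, b = alleles
    with open(map_path, "w") as fh:
        for j in range(mm.n):
            fh.write(f"{mm.chrom[j]}\t{mm.snp_id[j]}\t0\t{mm.pos_bp[j]}\n")
    pair = {2: f"{a} {a}", 1: f"{a} {b}", 0: f"{b} {b}", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i in range(gm.n_animals):
            geno = " ".join(pair[int(d)] for d in gm.dosages[i])
            fh.write(f"FAM {gm.ids[i]} 0 0 0 -9 {geno}\n")


PHENO_COLUMNS = ["animal_id", "trait", "value", "age_d", "sex", "birth_year"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype CSV (animal_id, trait, value, age_d, sex, birth_year).

    Validates that values are positive and that weaning-weight records
    carry an age.
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype file lacks columns: {missing}")
    df = df[PHENO_COLUMNS].copy()
    df["value"] = df["value"].astype(float)
    if (df["value"] <= 0).any():
        raise FormatError("phenotype values must be positive")
    ww = df["trait"] == "weaning_weight"
    if df.loc[ww, "age_d"].isna().any():
        raise FormatError("weaning_weight records require age_d")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PHENO_COLUMNS].to_csv(path, index=False)


@dataclass
class QCThresholds:
    """Marker/animal quality-control thresholds.

    ``min_call_rate`` applies to markers and, as ``min_animal_call_rate``
    (same default), to animals.  Markers are kept when call rate >=
    threshold, MAF is strictly greater than ``min_maf``, and the
    Hardy–Weinberg exact-test p-value exceeds ``hwe_alpha``.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    autosomes_only: bool = True
    min_animal_call_rate: float = 0.95
    n_autosomes: int = 29

    def __post_init__(self):
        for f in (self.min_call_rate, self.min_maf, self.min_animal_call_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("QC fractions must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-criterion removal counts from :func:`qc_genotypes`."""

    n_animals_in: int = 0
    n_markers_in: int = 0
    removed_non_autosomal: int = 0
    removed_animals_call_rate: int = 0
    removed_markers_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_animals_out: int = 0
    n_markers_out: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def hwe_exact_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy–Weinberg equilibrium test p-value (mid-p off).

    Two-sided exact test conditioning on the observed allele counts:
    the p-value sums the probabilities of all heterozygote counts whose
    conditional probability does not exceed that of the observed count.
    """
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # normalize so 'rare' is the minor allele count
        rare = 2 * n - rare
    probs = np.zeros(rare + 1)
    # start at an interior het count and fill by recurrence
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(mid, rare)
    probs[mid] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / (4 (hr+1)(hc+1))
    h = mid
    hr = (rare - mid) // 2
    hc = n - mid - hr
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h -= 2
        hr += 1
        hc += 1
    h = mid
    hr = (rare - mid) // 2
    hc = n - mid - hr
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hr * hc / ((h + 2) * (h + 1))
        h += 2
        hr -= 1
        hc -= 1
    total = probs.sum()
    obs = n_het if n_het <= rare else None
    if obs is None:
        return 1.0
    p_obs = probs[obs]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum() / total
    return float(min(1.0, p))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[col >= 0]
        n_het = int((col == 1).sum())
        n0 = int((col == 0).sum())
        n2 = int((col == 2).sum())
        n_hom_rare, n_hom_common = (n2, n0) if n2 <= n0 else (n0, n2)
        out[j] = hwe_exact_pvalue(n_het, n_hom_rare, n_hom_common)
    return out


def qc_genotypes(gm: GenotypeMatrix, mm: MarkerMap, th: QCThresholds | None = None):
    """Apply marker and animal quality control.

    Order of application is fixed: autosome filter -> animal call rate
    -> marker call rate -> MAF -> HWE.  Returns the filtered
    ``(GenotypeMatrix, MarkerMap, QCReport)``.  Removing every marker is
    a hard error.
    """
    if th is None:
        th = QCThresholds()
    if gm.n_markers != mm.n:
        raise FormatError("genotype matrix and marker map are inconsistent")
    rep = QCReport(
        n_animals_in=gm.n_animals,
        n_markers_in=gm.n_markers,
        thresholds={
            "min_call_rate": th.min_call_rate,
            "min_maf": th.min_maf,
            "hwe_alpha": th.hwe_alpha,
            "autosomes_only": th.autosomes_only,
            "min_animal_call_rate": th.min_animal_call_rate,
        },
    )
    if th.autosomes_only:
        keep = (mm.chrom >= 1) & (mm.chrom <= th.n_autosomes)
        rep.removed_non_autosomal = int((~keep).sum())
        gm = gm.subset_markers(keep)
        mm = mm.subset(keep)
    acr = gm.animal_call_rate()
    keep_a = acr >= th.min_animal_call_rate
    rep.removed_animals_call_rate = int((~keep_a).sum())
    gm = gm.subset_animals(keep_a)

    cr = gm.marker_call_rate()
    keep = cr >= th.min_call_rate
    rep.removed_markers_call_rate = int((~keep).sum())
    gm = gm.subset_markers(keep)
    mm = mm.subset(keep)

    maf = gm.maf()
    keep = np.nan_to_num(maf, nan=0.0) > th.min_maf
    rep.removed_maf = int((~keep).sum())
    gm = gm.subset_markers(keep)
    mm = mm.subset(keep)

    if gm.n_markers:
        pv = _hwe_pvalues(gm.dosages)
        keep = pv > th.hwe_alpha
        rep.removed_hwe = int((~keep).sum())
        gm = gm.subset_markers(keep)
        mm = mm.subset(keep)

    rep.n_animals_out = gm.n_animals
    rep.n_markers_out = gm.n_markers
    if gm.n_markers == 0:
        raise FormatError("quality control removed every marker")
    return gm, mm, rep
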