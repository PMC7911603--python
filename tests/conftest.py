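import numpy as np
import pytest

from herddiv.io_formats import Pedigree, GenotypeMatrix, MarkerMap


@pytest.fixture
def trio_ped():
    """Unrelated sire S and dam D with one child C."""
    return Pedigree.from_records(
        [("S", "0", "0", 2000, "M"), ("D", "0", "0", 2000, "F"),
         ("C", "S", "D", 2006, "M")]
    )


@pytest.fixture
def fullsib_child_ped():
    """Child of two full sibs whose parents are unrelated founders."""
    return Pedigree.from_records(
        [("P1", "0", "0", None, "M"), ("P2", "0", "0", None, "F"),
         ("A", "P1", "P2", None, "M"), ("B", "P1", "P2", None, "F"),
         ("X", "A", "B", None, "M")]
    )


def make_random_pedigree(seed: int, n: int) -> Pedigree:
    """Arbitrary sex-consistent random pedigree of n animals.

    Early animals are founders; later ones draw each parent from the
    appropriate-sex predecessors or leave it unknown.
    """
    rng = np.random.default_rng(seed)
    recs = []
    sexes = []
    n_founders = max(4, n // 8)
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        sexes.append(sex)
        if i < n_founders:
            recs.append((f"A{i}", "0", "0", 1990 + i // 10, sex))
            continue
        males = [j for j in range(i) if sexes[j] == "M"]
        females = [j for j in range(i) if sexes[j] == "F"]
        sire = f"A{rng.choice(males)}" if males and rng.random() < 0.85 else "0"
        dam = f"A{rng.choice(females)}" if females and rng.random() < 0.8 else "0"
        recs.append((f"A{i}", sire, dam, 1990 + i // 10, sex))
    return Pedigree.from_records(recs)


def make_random_genotypes(seed: int, n_animals: int = 8, n_snp: int = 400,
                          p_het: float = 0.3, p_missing: float = 0.05,
                          mean_spacing_bp: int = 120_000):
    """Random genotypes on one chromosome with irregular marker spacing.

    Composition is chosen so that both homozygous and heterozygous runs
    occur and oversized gaps appear occasionally.
    """
    rng = np.random.default_rng(seed)
    gaps = rng.exponential(mean_spacing_bp, size=n_snp).astype(np.int64) + 1
    pos = np.cumsum(gaps)
    mm = MarkerMap(np.array([f"s{i}" for i in range(n_snp)], dtype=object),
                   np.ones(n_snp, dtype=np.int64), pos)
    u = rng.random((n_animals, n_snp))
    dos = np.where(u < p_het, 1, np.where(rng.random((n_animals, n_snp)) < 0.5, 0, 2))
    dos = dos.astype(np.int8)
    dos[rng.random((n_animals, n_snp)) < p_missing] = -1
    gm = GenotypeMatrix(np.array([f"an{i}" for i in range(n_animals)], dtype=object),
                        dos)
    return gm, mm
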