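import numpy as np
import pytest

from herddiv.io_formats import GenotypeMatrix, MarkerMap
from herddiv.roh_analysis import (
    RunConfig, ROHSegment, detect_roh, detect_rohet, summarize_roh,
    shared_roh, find_islands, segments_to_frame,
)
from herddiv.synthetic_data import (
    SimPedigreeConfig, SimGenomeConfig, sim_pedigree, sim_genotypes,
)

import oracles
from conftest import make_random_genotypes


def _single(genos, positions, chrom=1):
    d = np.asarray([genos], dtype=np.int8)
    pos = np.asarray(positions, dtype=np.int64)
    mm = MarkerMap(np.array([f"s{i}" for i in range(len(pos))], dtype=object),
                   np.full(len(pos), chrom, dtype=np.int64), pos)
    return GenotypeMatrix(np.array(["x"], dtype=object), d), mm


class TestDetectROH:
    def test_all_het_chromosome_empty(self):
        gm, mm = _single([1] * 40, np.arange(40) * 100_000 + 1)
        assert detect_roh(gm, mm) == []

    def test_constructed_single_segment(self):
        # 20 homozygous SNP spanning ~1.5 Mb, flanked by heterozygotes
        genos = [1, 1] + [0] * 20 + [1, 1]
        pos = [1, 50_000] + list(100_000 + np.arange(20) * 79_000) + [1_800_000, 1_900_000]
        gm, mm = _single(genos, pos)
        segs = detect_roh(gm, mm)
        assert len(segs) == 1
        s = segs[0]
        assert s.n_snp == 20
        assert (s.start_bp, s.end_bp) == (100_000, 100_000 + 19 * 79_000)

    def test_too_few_snp_rejected(self):
        # 14 homozygous SNP spanning 2 Mb: fails the count threshold
        genos = [1] + [2] * 14 + [1]
        pos = [1] + list(100_000 + np.arange(14) * 154_000) + [2_500_000]
        gm, mm = _single(genos, pos)
        assert detect_roh(gm, mm) == []

    def test_missing_breaks_run(self):
        genos = [0] * 10 + [-1] + [0] * 10
        pos = list(np.arange(21) * 100_000 + 1)
        gm, mm = _single(genos, pos)
        assert detect_roh(gm, mm) == []  # neither side qualifies alone

    def test_gap_splits_run(self):
        # 30 homozygous SNP with one 1.2 Mb interior gap; each side must
        # qualify independently (left side: 15 SNP / 1.4 Mb; right: 15 / 1.4)
        pos = list(np.arange(15) * 100_000 + 1)
        pos += list(pos[-1] + 1_200_000 + np.arange(15) * 100_000)
        gm, mm = _single([2] * 30, pos)
        segs = detect_roh(gm, mm)
        assert len(segs) == 2
        assert all(s.n_snp == 15 for s in segs)

    def test_matches_window_enumeration_on_random_data(self):
        cfg = RunConfig(min_snp=5, min_len_bp=300_000, max_gap_bp=500_000)
        for seed in range(20):
            gm, mm = make_random_genotypes(seed, n_animals=10, n_snp=500,
                                           p_het=0.25, p_missing=0.04,
                                           mean_spacing_bp=120_000)
            segs = detect_roh(gm, mm, cfg)
            got = {(s.animal_id, s.start_bp, s.end_bp, s.n_snp) for s in segs}
            exp = set()
            for ai in range(gm.n_animals):
                for a, b in oracles.roh_windows(gm.dosages[ai], mm.pos_bp,
                                                cfg.min_snp, cfg.min_len_bp,
                                                cfg.max_gap_bp):
                    exp.add((gm.ids[ai], int(mm.pos_bp[a]), int(mm.pos_bp[b]),
                             b - a + 1))
            assert got == exp


class TestDetectROHet:
    def test_fully_homozygous_empty(self):
        gm, mm = _single([0, 2] * 20, np.arange(40) * 50_000 + 1)
        assert detect_rohet(gm, mm) == []

    def test_fifteen_het_over_300kb(self):
        gm, mm = _single([15 * [1]][0], np.arange(15) * 21_500 + 1)
        segs = detect_rohet(gm, mm)
        assert len(segs) == 1 and segs[0].n_snp == 15

    def test_fourth_interior_homozygote_breaks(self):
        # 20 het with 4 interleaved homozygotes: the 4th ends the run at
        # the previous het, leaving too few SNPs on either side to qualify
        genos = [1] * 5 + [0] + [1] * 2 + [0] + [1] * 2 + [0] + [1] * 2 + [0] + [1] * 9
        pos = np.arange(len(genos)) * 30_000 + 1
        gm, mm = _single(genos, pos)
        # first run spans SNPs 0..13 (14 SNP, 3 tolerated homozygotes) and
        # stops at the 4th; the trailing 9 het never reach min_snp
        cfg = RunConfig(min_snp=15, min_len_bp=250_000, max_gap_bp=1_000_000,
                        max_other_inside=3, max_missing_inside=2)
        assert detect_rohet(gm, mm, cfg) == []
        cfg2 = RunConfig(min_snp=14, min_len_bp=250_000, max_gap_bp=1_000_000,
                         max_other_inside=3, max_missing_inside=2)
        segs2 = detect_rohet(gm, mm, cfg2)
        assert len(segs2) == 1
        assert segs2[0].n_snp == 14  # ends on the last het before the 4th hom
        assert segs2[0].end_bp == int(pos[13])

    def test_run_anchored_on_heterozygotes(self):
        genos = [0] + [1] * 15 + [0, 0]
        pos = np.arange(18) * 25_000 + 1
        gm, mm = _single(genos, pos)
        segs = detect_rohet(gm, mm)
        assert len(segs) == 1
        assert segs[0].start_bp == int(pos[1]) and segs[0].end_bp == int(pos[15])

    def test_matches_longest_window_oracle_on_random_data(self):
        cfg = RunConfig(min_snp=5, min_len_bp=150_000, max_gap_bp=500_000,
                        max_other_inside=3, max_missing_inside=2)
        for seed in range(20):
            gm, mm = make_random_genotypes(100 + seed, n_animals=10, n_snp=400,
                                           p_het=0.45, p_missing=0.05,
                                           mean_spacing_bp=80_000)
            segs = detect_rohet(gm, mm, cfg)
            got = {(s.animal_id, s.start_bp, s.end_bp) for s in segs}
            exp = set()
            for ai in range(gm.n_animals):
                for a, b in oracles.rohet_windows(
                        gm.dosages[ai], mm.pos_bp, cfg.min_snp, cfg.min_len_bp,
                        cfg.max_gap_bp, cfg.max_other_inside, cfg.max_missing_inside):
                    exp.add((gm.ids[ai], int(mm.pos_bp[a]), int(mm.pos_bp[b])))
            assert got == exp


def _map_for(chrom_mb=100.0, n=1000):
    pos = np.linspace(1, chrom_mb * 1e6, n).astype(np.int64)
    return MarkerMap(np.array([f"s{i}" for i in range(n)], dtype=object),
                     np.ones(n, dtype=np.int64), pos)


class TestSummaries:
    def test_no_segments_all_zero(self):
        mm = _map_for()
        summ = summarize_roh([], mm, animals=["a"])
        row = summ.per_animal.iloc[0]
        assert row["nroh"] == 0
        for t in (1, 2, 4, 8, 16):
            assert row[f"froh_gt{t}mb"] == 0.0

    def test_exact_froh_with_constant_laut(self):
        mm = _map_for()
        seg = ROHSegment("a", 1, 1_000_000, 1_000_000 + int(25.0777e6), 100)
        summ = summarize_roh([seg], mm, animals=["a"], laut_mode="constant",
                             laut_mb=2507.77)
        assert summ.per_animal["froh_gt1mb"].iloc[0] == pytest.approx(0.01)
        assert summ.laut_mb == 2507.77

    def test_class_bins_half_open(self):
        mm = _map_for()
        segs = [ROHSegment("a", 1, 1, 1 + 2_000_000, 30),   # exactly 2 Mb
                ROHSegment("a", 1, 1, 1 + 1_500_000, 20),
                ROHSegment("a", 1, 1, 1 + 17_000_000, 200)]
        summ = summarize_roh(segs, mm, animals=["a"])
        assert summ.class_counts["2-4Mb"] == 1
        assert summ.class_counts["1-2Mb"] == 1
        assert summ.class_counts[">16Mb"] == 1

    def test_froh_threshold_monotonicity_and_config_nesting(self):
        sim = sim_pedigree(SimPedigreeConfig(
            n_founders=20, n_generations=6, offspring_per_generation=30,
            missing_sire_rate=0, missing_dam_rate=0, seed=3))
        geno = sim_genotypes(sim.pedigree_true, SimGenomeConfig(
            n_chromosomes=6, snp_per_chrom=500, chrom_length_mb=50,
            founder_maf=(0.5, 0.5), seed=4))
        base = RunConfig.roh_defaults()
        segs = detect_roh(geno.gm, geno.mm, base)
        summ = summarize_roh(segs, geno.mm, animals=geno.gm.ids)
        pa = summ.per_animal
        for lo, hi in [(1, 2), (2, 4), (4, 8), (8, 16)]:
            assert (pa[f"froh_gt{hi}mb"] <= pa[f"froh_gt{lo}mb"] + 1e-15).all()
        assert sum(summ.class_counts.values()) == len(segs)
        # raising thresholds never increases run counts or totals
        import dataclasses
        for tighter in (dataclasses.replace(base, min_snp=25),
                        dataclasses.replace(base, min_len_bp=2_000_000)):
            segs2 = detect_roh(geno.gm, geno.mm, tighter)
            summ2 = summarize_roh(segs2, geno.mm, animals=geno.gm.ids)
            assert len(segs2) <= len(segs)
            assert (summ2.per_animal["nroh"] <= pa["nroh"]).all()
            assert (summ2.per_animal["sroh_mb"] <= pa["sroh_mb"] + 1e-12).all()

    def test_nroh_sroh_strongly_correlated(self):
        sim = sim_pedigree(SimPedigreeConfig(
            n_founders=24, n_generations=7, offspring_per_generation=30,
            missing_sire_rate=0, missing_dam_rate=0, seed=6))
        geno = sim_genotypes(sim.pedigree_true, SimGenomeConfig(
            n_chromosomes=8, snp_per_chrom=500, chrom_length_mb=50,
            founder_maf=(0.5, 0.5), seed=7))
        summ = summarize_roh(detect_roh(geno.gm, geno.mm), geno.mm,
                             animals=geno.gm.ids)
        pa = summ.per_animal
        r = np.corrcoef(pa["nroh"], pa["sroh_mb"])[0, 1]
        assert r > 0.8

    def test_fullsib_offspring_more_autozygous_than_outbred(self):
        pvals = []
        from scipy import stats
        for seed in range(3):
            sim = sim_pedigree(SimPedigreeConfig(
                n_founders=40, n_generations=1, offspring_per_generation=40,
                mating_scheme="full_sib_lines",
                missing_sire_rate=0, missing_dam_rate=0, seed=seed))
            geno = sim_genotypes(sim.pedigree_true, SimGenomeConfig(
                n_chromosomes=10, snp_per_chrom=400, chrom_length_mb=40,
                founder_maf=(0.5, 0.5), seed=100 + seed))
            F = sim.truth["f_true"].to_numpy()
            summ = summarize_roh(detect_roh(geno.gm, geno.mm), geno.mm,
                                 animals=geno.gm.ids)
            froh = summ.per_animal["froh_gt1mb"].to_numpy()
            res = stats.mannwhitneyu(froh[F >= 0.25], froh[F == 0.0],
                                     alternative="greater")
            pvals.append(res.pvalue)
        assert all(p < 0.01 for p in pvals)


class TestSharedROH:
    def test_identical_segments_grouped(self):
        segs = [ROHSegment("a", 1, 100, 2_000_100, 20),
                ROHSegment("b", 1, 100, 2_000_100, 20),
                ROHSegment("c", 1, 200, 2_000_100, 20)]
        shared = shared_roh(segs)
        assert len(shared) == 1
        assert shared["n_carriers"].iloc[0] == 2
        assert shared["carriers"].iloc[0] == "a,b"

    def test_dropped_ibd_haplotype_recovered(self):
        # nine carriers of one founder haplotype share the exact same run
        segs = []
        for k in range(9):
            segs.append(ROHSegment(f"c{k}", 2, 130_000, 2_360_000, 25))
        for k in range(4):
            segs.append(ROHSegment(f"o{k}", 2, 130_000 + k + 1, 2_360_000, 25))
        top = shared_roh(segs).iloc[0]
        assert top["n_carriers"] == 9


class TestIslands:
    def test_single_run_incidence(self):
        mm = _map_for(n=100)
        segs = [ROHSegment("a", 1, int(mm.pos_bp[10]), int(mm.pos_bp[29]), 20)]
        res = find_islands(segs, mm, n_animals=10, percentile=90)
        inc = res.incidence["incidence"].to_numpy()
        assert np.allclose(inc[10:30], 0.1)
        assert inc[:10].sum() == 0 and inc[30:].sum() == 0

    def test_constructed_island_recovered(self):
        mm = _map_for(chrom_mb=2.0, n=2000)  # 1 kb spacing, no gap breaks
        segs = [ROHSegment("bg", 1, int(mm.pos_bp[0]), int(mm.pos_bp[-1]), 2000)]
        for k in range(8):
            segs.append(ROHSegment(f"c{k}", 1, int(mm.pos_bp[1000]),
                                   int(mm.pos_bp[1019]), 20))
        res = find_islands(segs, mm, n_animals=10, percentile=99)
        assert len(res.islands) == 1
        isl = res.islands.iloc[0]
        assert isl["start_bp"] == mm.pos_bp[1000] and isl["end_bp"] == mm.pos_bp[1019]
        assert isl["n_snp"] == 20

    def test_all_zero_incidence_warns_empty(self):
        mm = _map_for(n=50)
        with pytest.warns(UserWarning, match="incidence"):
            res = find_islands([], mm, n_animals=5)
        assert res.islands.empty

    def test_sweep_region_detected_from_simulation(self):
        # force a shared homozygous sweep: all animals homozygous for the
        # same alleles over a 3 Mb interval of chromosome 1
        gm, mm = make_random_genotypes(3, n_animals=12, n_snp=800, p_het=0.45,
                                       p_missing=0.0, mean_spacing_bp=60_000)
        lo = np.searchsorted(mm.pos_bp, 10_000_000)
        hi = np.searchsorted(mm.pos_bp, 13_000_000)
        gm.dosages[:, lo:hi] = 2
        segs = detect_roh(gm, mm)
        res = find_islands(segs, mm, n_animals=gm.n_animals, percentile=99)
        assert len(res.islands) >= 1
        isl = res.islands.iloc[0]
        assert isl["start_bp"] >= 9_000_000 and isl["end_bp"] <= 14_000_000


def test_segments_frame_layout():
    segs = [ROHSegment("a", 3, 100, 1_500_100, 18)]
    df = segments_to_frame(segs)
    assert list(df.columns) == ["chrom", "start_bp", "end_bp", "animal",
                                "n_snp", "length_mb"]
    assert df["length_mb"].iloc[0] == pytest.approx(1.5)
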