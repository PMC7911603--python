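# herddiv

Pedigree and genomic diversity analysis for small, closed livestock
populations — built around the questions a breed association with a few
thousand recorded animals and a few dozen genotyped ones actually asks:
*How inbred is the herd? How fast is diversity being lost? Which few
ancestors dominate the gene pool? What is the effective population
size, now and historically? And what is inbreeding costing in weight at
birth and weaning?*

The package implements the standard analysis chain for this setting
(typified by a tropical beef herd genotyped on a medium-density
~50 K SNP chip) and, because such datasets are usually confidential,
ships first-class synthetic-data generators with known ground truth so
every stage is testable end to end.

## What it computes

**Pedigree metrics** (`herddiv.pedigree_metrics`)

- Inbreeding `F` via the Meuwissen–Luo algorithm (≡ `diag(A) − 1` of the
  additive relationship matrix `A`), and the relatedness coefficient
  `AR_i = (1/2n) Σ_j a_ij` in O(n) via the `A = T D T'` decomposition.
- Pedigree depth (equivalent complete generations
  `EqG = Σ (1/2)^path`), completeness per ancestral generation, and
  generation intervals on the four selection paths with record-level
  pooling.
- Realized effective population size from the individual rate of
  inbreeding `ΔF_i = 1 − (1 − F_i)^{1/(EqG_i − 1)}`,
  `Ne = 1/(2·mean ΔF)`, with a delta-method SE and 95% CI.
- Probabilities of gene origin: effective number of founders
  `fe = 1/Σq_k²` and of ancestors `fa = 1/Σp_k²` (Boichard's greedy
  marginal contributions); `fa/fe < 1` flags bottlenecks.

**Genomic inbreeding** (`grm_inbreeding`, `roh_analysis`)

- VanRaden GRM `G = ZZ'/(2Σp(1−p))` with frequencies fixed at 0.5 (the
  robust choice for small genotyped subsets) or observed;
  `F_GRM = diag(G) − 1`.
- Runs of homozygosity by the consecutive method (≥15 SNP, ≥1 Mb, no
  het/missing inside, gaps ≤1 Mb), length classes, `F_ROH = L_ROH/L_AUT`
  genome-wide and per chromosome, exactly-shared segments, plus
  heterozygosity-rich runs (ROHet) and incidence-percentile islands as
  selection-signature scans.

**LD and historical Ne** (`ld_ne`) — binned `r²` decay, finite-sample
adjustment `r²_adj = r² − 1/(βn)`, Sved–Feldman mapping
`c = d(1 − d/2)` and inversion `Ne(t) = (4c)⁻¹(1/r²_adj − α)` at
`t = 1/(2c)` generations ago.

**Inbreeding depression** (`inbreeding_depression`) — phenotype QC
(240 ± 45 d weaning-age window, 240-d linear-gain adjustment, ±3 SD
filter) and OLS of weight on `F` (as %) with sex and birth-year fixed
effects.

**Synthetic data** (`synthetic_data`) — pedigree simulation (random /
kinship-assortative / full-sib-line matings, skewed sire usage,
maskable parent recording), gene dropping of founder haplotypes with
Haldane recombination and IBD bookkeeping, a Wright–Fisher forward
simulator, and phenotype generation with known depression effects.

## Worked example

Simulate a herd-like dataset (1280 animals over six generations, 80
founders, 10–15% missing parent records, 29 autosomes × 400 SNP) and
run every stage:

```bash
herddiv all --out-dir demo --seed 42 --preset herd-like
```

`demo/population_summary.json` (abridged):

```json
{
  "n_animals": 1280,
  "mean_F_pct": 3.11,
  "mean_AR_pct": 3.61,
  "ne_realized": 23.5,
  "ne_ci": [21.0, 26.0],
  "fe_reference": 24.8,
  "fa_reference": 13.7,
  "fa_fe_ratio_reference": 0.55,
  "n_ancestors_50pct_reference": 5
}
```

Mean pedigree inbreeding is 3.1%; the realized Ne of ~24 is well below
the commonly cited sustainability threshold of 50, and the reference
cohort's `fa/fe = 0.55` (five ancestors already explain half the gene
pool) shows a strong bottleneck — exactly the signature a heavily used
sire line leaves.

`demo/depression.csv` (the fit of weight on each inbreeding measure):

```
trait,measure,beta1_kg_per_pct,se,p_value,n
birth_weight,FPED,-0.065,0.025,0.0090,1197
weaning_weight,FPED,-0.369,0.177,0.0373,599
birth_weight,FGRM,-0.091,0.027,0.0007,1197
weaning_weight,FGRM,-0.641,0.185,0.0006,599
```

Each extra 1% of inbreeding costs ~0.07–0.09 kg at birth and
~0.4–0.6 kg at weaning in this simulation (true effects −0.103 and
−0.685 kg/% on true inbreeding; the pedigree-based estimate is
attenuated because 10–15% of parent records were masked — the genomic
measures, which need no pedigree, recover more of the signal).

Individual stages are available as subcommands (`ped-metrics`, `grm`,
`roh`, `rohet`, `islands`, `ld-ne`, `depression`, `simulate`) operating
on pedigree CSV, PLINK PED/MAP and phenotype CSV files; `manifest.json`
records config, seed, timings and sha256 digests of every output.

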