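# Methods

This note records the models implemented, the numerical and design
choices made where a choice was genuinely open, and what the synthetic
data do and do not establish about behaviour on real herds.

## Pedigree model and metrics

A pedigree is a directed acyclic parent map with optional birth years
and sexes. Loading normalizes unknown-parent tokens (default
`{"0", "", "NA"}`, configurable), promotes parents without their own
row to founders, topologically sorts records, and fails hard on cycles
(naming one) and duplicate ids. All downstream recursions rely on the
topological order.

**Inbreeding.** `F` comes from the Meuwissen–Luo ancestor-tracing
algorithm; the full tabular relationship matrix is kept as an
independent O(n²) construction and the two agree to < 1e-10 on random
pedigrees up to 500 animals (asserted in tests). Unknown parents
contribute no relationship; founders have `F = 0`.

**Relatedness.** The verbal definition of AR — the chance that a
random allele from the whole pedigree descends from the animal — is
operationalized as the animal's mean additive relationship to all `n`
animals divided by two, `AR_i = (1/2n) Σ_j a_ij`, which puts it on the
same percent scale as `F`. It is computed in O(n) through
`A = T D T'` (child-sum recursion for `T'1`, gene-flow recursion for
the final row sums), again checked against the explicit matrix.

**Equivalent generations** counts every distinct ancestral path:
`EqG_i = Σ_paths (1/2)^len`. An ancestor reachable through two paths
contributes twice, which is what makes `EqG = 1` exactly when both
parents (only) are known, and `EqG = 2` when parents and all four
grandparents are known.

**Completeness** at depth `d` is the filled fraction of the `2^d`
ancestor slots, averaged over the cohort (three known grandparents →
0.75 at depth 2).

**Generation intervals** use only offspring that themselves have
progeny ("kept for reproduction"); each record is a parent age at such
an offspring's birth, assigned to sire–sire/sire–dam/dam–sire/dam–dam
by parent and offspring sex. The *pooled* value is the record-level
mean, i.e. the count-weighted mean of path means — with unbalanced
path counts this differs from the equal-weight average of the four
paths and is the convention that reproduces published pooled values
from path tables. Offspring of unknown sex cannot be assigned a path;
they are excluded and counted.

**Realized Ne.** `ΔF_i = 1 − (1 − F_i)^{1/(EqG_i − 1)}` is undefined
or degenerate for `EqG ≤ 1`; such animals are excluded from the mean
and the exclusion count is reported. `Ne = 1/(2·mean ΔF)`. No
closed-form SE exists for this estimator in common use, so the SE is
obtained by the delta method from the standard error of the mean ΔF:
`SE(Ne) = SD(ΔF)/√N · 1/(2·mean ΔF²)`, giving the symmetric
`Ne ± 1.96·SE` interval. If every ΔF is zero the estimate is reported
as infinite with a warning.

**Probabilities of gene origin.** Founder contributions `q_k` are
computed by passing half of each animal's reference weight to each
parent line; a missing parent slot of a non-founder becomes a phantom
founder, so `Σq_k = 1` and `fe = 1/Σq_k²` always refers to the full
gene pool. The effective number of ancestors uses greedy marginal
contributions: at each round the candidate maximizing the probability
that a random reference gene's line of descent passes through it
*while avoiding every previously selected ancestor* is chosen. This is
computed as (blocked upward weight) × (probability the continuation
above the candidate avoids the selected set), which makes the selected
`p_k` an exact partition of the gene pool (each gene credited to the
earliest-selected node on its path); the implementation agrees exactly
with a brute-force path-enumeration greedy on small pedigrees.
`n_ancestors_50pct` is the count, in selection order, reaching a
cumulative 0.5.

*Known limitation:* the greedy is a heuristic for the most-explanatory
ancestor ordering, and on small, fully recorded pedigrees without
bottlenecks (where `fa ≈ fe`) it can end up with marginal
contributions slightly *less* concentrated than the founder partition,
so `fa` can exceed `fe` by up to a couple of percent. Under realistic
recording — incomplete parentage and skewed sire usage, which the
generator defaults emulate — `fa ≤ fe` holds with clear margins.

The default reference cohort is the animals born in the last
`⌈pooled GI⌉` years of the pedigree (a one-generation window);
explicit year windows can be given instead.

## Genotypes, QC and the GRM

Genotypes are minor-allele dosages in {0, 1, 2} with −1 for missing;
PED/MAP text is parsed by counting the per-column minor allele
(frequency ties broken by allele lexical order; a column with a single
observed allele codes 0). Positions are 1-based; intervals are closed;
lengths in Mb are `(end − start)/1e6`. Chromosome length is the span
between the first and last mapped SNP, and `L_AUT` their sum.

QC applies, in fixed order: autosome filter (any chromosome code
outside 1..29 is non-autosomal) → animal call rate ≥ 0.95 → marker
call rate ≥ 0.95 → MAF strictly > 0.01 → Hardy–Weinberg exact test
p > 1e-6. The HWE statistic is the standard exact test (mid-p off),
implemented by the numerically stable recurrence and verified against
direct enumeration. One call-rate threshold is applied to both animals
and markers. QC is idempotent by construction.

The GRM follows VanRaden: `Z = dosage − 2p`, missing imputed to `2p`
(zero contribution — deterministic and consistent with the
denominator, unlike pairwise deletion), `G = ZZ'/(2Σp(1−p))`,
`F_GRM = diag(G) − 1`. The default fixes `p = 0.5`, appropriate when
the genotyped subset is too small to estimate frequencies; the
diagonal then has the closed form `F_GRM = 1 − 2·(het fraction)` on
complete data, asserted to 1e-12. Note that fixed-0.5 frequencies
calibrate `F_GRM ≈ 0` to a founder heterozygosity of 0.5: populations
founded at lower MAF shift the whole distribution upward, which is why
comparisons should be within-cohort. Observed-frequency mode drops
monomorphic loci with a warning.

## Runs of homozygosity and heterozygosity

Both scans use the consecutive method: no windows, a single
left-to-right pass per animal and chromosome. A ROH run breaks at any
heterozygote, any missing call, or any inter-marker gap > 1 Mb, and is
reported when it has ≥ 15 SNP spanning ≥ 1 Mb. ROHet runs (≥ 15 SNP,
≥ 250 kb) tolerate at most 3 homozygous and 2 missing interior calls;
the call that exceeds a tolerance ends the run at the last
heterozygous SNP, runs can neither start nor end on a tolerated call,
and scanning resumes after the violating SNP. Run coordinates are
SNP-anchored (first to last SNP of the run). These semantics are
deterministic and were fixed once; the test suite checks them against
independent window-enumeration oracles (exhaustive maximal-window
enumeration for strict ROH, longest-valid-window search for ROHet) on
hundreds of random fixtures.

Length classes are half-open — [1,2), [2,4), [4,8), [8,16), [16,∞) Mb,
a segment of exactly 2 Mb falling in 2–4 — and `F_ROH` at threshold
`x` sums only segments ≥ x Mb, so the thresholds are monotone by
construction. `L_AUT` defaults to the map extents, with a constant
override for replicating published denominators. Shared ("specific")
ROH are groups with byte-identical (chrom, start, end). Islands
threshold the per-SNP run incidence (carriers/animals) at a percentile
of its own distribution (default 99.9, exposed as a parameter) and may
not span a gap larger than the run gap limit.

## LD decay and historical Ne

`r²` is the squared Pearson correlation of dosages over animals
complete at both loci (pairwise deletion; unbiased at the low
missingness that survives QC), for same-chromosome pairs at distances
in [100 kb, 35 Mb], accumulated in 30 equal-width log10-distance bins —
log spacing covers recent (long-distance) and ancient (short-distance)
time depths evenly. Pairs with a monomorphic locus are skipped and
counted. The sampling bias is removed as `r²_adj = r² − 1/(βn)` with
β = 1 for unphased genotypes. Physical distance maps to recombination
rate via Sved–Feldman `c = d(1 − d/2)` (Morgans; 1 cM = 1 Mb by
default), with linear and Haldane mappings available. Each usable bin
is inverted through the drift–recombination expectation
`E[r²_adj] = 1/(α + 4Nc)` with α = 2 (mutation correction):
`Ne(t) = (4c)⁻¹(1/r²_adj − α)` at `t = 1/(2c)` generations ago
(reported raw and rounded). Bins with `1/r²_adj ≤ α` are dropped with
a warning. Feeding the expectation back through the estimator returns
`N` to 1e-9, and a Wright–Fisher population of census size 100
(20 chromosomes × 200 SNP, 200 generations of burn-in, 50 sampled
animals) yields a median recent-bin estimate within [60, 160] over ten
seeds.

## Phenotype QC and the depression model

Weaning records are windowed to 240 ± 45 d, adjusted to 240 d by the
linear-gain correction `WW240 = BW + ((WW − BW)/age)·240` (falling back
to `WW·240/age` when the animal has no birth-weight record; the
formula used is recorded in the output metadata), and then filtered
once at ±3 SD of the adjusted values; birth weights get the single
±3 SD pass only. The window-then-adjust-then-filter order is fixed and
documented here because the alternative order is equally defensible.

The model is `y = μ + sex + birth_year + β₁·F + e`, fitted by OLS
(statsmodels) with `F` carried as a percentage so `β₁` is kg per 1%
inbreeding. Birth-year classes with a single record are pooled into
one level before fitting (rank-deficiency guard, logged on the fit).
An independent normal-equations solve reproduces the estimates to
1e-8. At a design of ~1300 records with residual SD 4 kg, a true
β₁ = −0.1 kg/% is recovered to ±0.01 with 95% CI coverage inside
[0.92, 0.98] over 200 replicates; the same effect at ~50 records is
non-significant in the large majority of replicates — the expected
power collapse at genotyped-subset sample sizes.

## Synthetic data: what it emulates and what it does not

The pedigree generator produces discrete generations with a sire
bottleneck (a small, Dirichlet-skew-weighted subset of males sires each
cohort; default 15% of available males), uniform dam usage, and
post-hoc masking of recorded parents (defaults 27% of sires, 35% of
dams — the incomplete-recording pattern of a performance-recorded
tropical herd). True inbreeding is computed on the full pedigree by
the tabular method *before* masking, so observed-pedigree
underestimation can be quantified. The `full_sib_lines` scheme pairs
founders once to create sib groups (a setup round not counted in
`n_generations`) and then mates brother × sister each round, so its
first generated round already has F = 0.25.

Genotypes are gene-dropped: founder haplotypes drawn per locus from a
uniform founder-MAF range (default 0.05–0.5; 0.5 exactly where
pedigree-genomic agreement is being tested), meioses modelled as a
Markov switch process with Haldane probabilities at 1 cM/Mb, and
constant per-haplotype origin labels giving realized IBD ground truth.
Defaults: 29 autosomes × 1054 SNP on 86.5 Mb chromosomes — ~2508 Mb
and ~82 kb spacing, the scale of a bovine medium-density chip. Marker
density matters: at several-fold sparser maps the 15-SNP minimum
implies multi-Mb runs and random gaps > 1 Mb shred them, so `F_ROH`
under-covers realized IBD; at chip-like density the `F_ROH`-on-IBD
regression slope is ≈ 1.

Phenotypes follow `y = μ + sex + year + β₁·(100F) + e` with
birth/weaning means, effect sizes and residual scales set to
beef-recording magnitudes; recorded weaning weights are de-adjusted to
the drawn age by the inverse of the 240-d correction, so the QC
pipeline reconstructs the generating value exactly when the residual
is zero.

Not emulated: overlapping generations, selection on phenotype,
genotyping error correlated with probe chemistry, map errors,
pedigree-recording *errors* (only omissions), mutation, and population
admixture. Passing tests therefore demonstrate internal consistency
and correct mathematics under drift-dominated neutral inheritance, not
robustness to those real-data pathologies.

## Reproducibility and problem sizes

Every generator takes an explicit integer seed and is bit-reproducible;
the pipeline manifest records config, seed, timings and sha256 digests,
and a re-run with the same seed is byte-identical (asserted). The test
suite and the acceptance script size their simulations to run in a few
minutes on one CPU: oracle checks use pedigrees up to 500 animals and
fixtures up to a few hundred SNP; recovery checks use a ~1360-animal
design with 200 phenotype replicates and ten Wright–Fisher seeds at
N = 100. These sizes were chosen as the smallest at which the checked
statistics are stable, and they are stated here so larger replications
can scale them up.
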