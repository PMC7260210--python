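# Methods

This note documents the models and procedures implemented in `subpopscan`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a user re-deriving results will
want to know.

## Data model and coordinates

All library coordinates are 1-based inclusive base pairs; only BED output
converts to 0-based half-open (with a companion TSV preserving 1-based
coordinates). Genotypes are alt-allele dosages in {0, 1, 2} with a single
missing sentinel (−1); phased haplotypes are strictly binary and carry no
missing values, so haplotype-based analyses presuppose imputed/phased input
(or the simulator's complete output). Alleles are recoded to alt-dosage at
load and the original letters retained, so two array panels can be merged on
(chromosome, position, allele set), flipping dosage where the allele roles
are swapped; allele-set mismatches at a shared position are dropped with a
warning, and strand flips are not resolved.

## Quality control

Filter order is fixed: sample call rate ≥ 0.90, then SNP call rate ≥ 0.90,
then Hardy–Weinberg equilibrium, then the shared-polymorphic intersection of
the two panels. The HWE test is the 1-df chi-square goodness-of-fit (the
standard choice at these sample sizes, rather than the exact test), applied
within each subpopulation by default with a SNP removed if p < 10⁻⁵ in
either; a pooled variant is available because the correct scope is a genuine
judgment call. Monomorphic means pooled alt frequency exactly 0 or 1; SNPs
monomorphic in only one subpopulation are retained and handled downstream
(their within-group r is undefined and excluded).

## Genomic relationships, inbreeding, substructure

The GRM is VanRaden's first method with the base allele frequency fixed at
0.5: G = ZZᵀ/(2 m p₀(1−p₀)), Z = dosage − 2p₀. With p₀ = 0.5 the centred
dosages lie in {−1, 0, 1}, so F_GRM = G_ii − 1 equals 1 − 2·HETᵢ exactly;
the test suite asserts this identity to 1e−12, which pins the implementation
against sign and scaling mistakes. PCA is a full dense eigendecomposition of
the GRM (sample counts here are ≤ ~1,000); coordinates are eigenvectors
scaled by √λ and variance proportions use eigenvalues floored at zero. Note
that the leading component of an uncentred GRM is dominated by mean
relatedness; with substantial inbreeding PC1's share is large and
between-group separation may appear on later components.

## Runs of homozygosity

Two detectors share one segment-filter stage. The **sliding** detector is
the PLINK-style two-stage vote: every 30-SNP window entirely within a
chromosome passes for a sample if it holds at most 1 heterozygote and 0
missing calls; each SNP's hit rate is passing/spanning windows and the SNP
is in-run at hit rate ≥ 0.05 (the tool-default threshold, without which the
window has no effect); chromosomes shorter than the window are scanned with
a window equal to their SNP count. The **consecutive** detector extends runs
SNP by SNP, allowing one heterozygote per run, breaking at missing calls;
when a second heterozygote arrives the run closes at the previous SNP and
the offending heterozygote opens the next run — runs never overlap (an
overlapping-restart variant was rejected because duplicated coverage
double-counts in F_ROH and inflated it by ~80%).

Candidate stretches are split at adjacent-SNP gaps > 1 Mb and kept if the
span is ≥ 1 Mb with mean spacing ≤ 120 kb per SNP (mean-based density, not a
per-gap rule). There is no separate minimum SNP count; length and density
jointly imply one. F_ROH is summed segment length over the SNP-covered
genome length Σ(last − first SNP bp per chromosome). At marker densities
sparser than ~120 kb/SNP the density criterion suppresses detection entirely
— the criterion presumes array-scale density, which the simulator's defaults
provide (~50 kb).

The per-SNP autozygosity score is the proportion of a subpopulation's
animals whose ROH set covers the SNP (inclusive boundaries; each animal
counted once regardless of overlapping segments). **ROH islands** are runs
of ≥ 2 adjacent SNPs at or above the genome-wide 99.9th percentile
(linear-interpolation percentile). The comparison is *inclusive* by design:
track scores are quantized to multiples of 1/n and adjacent SNPs covered by
the same animals tie exactly, so an island's crest is a plateau; a strict
comparison silently discards any island whose plateau the percentile lands
on, which at a few thousand SNPs is essentially all of them. A track whose
threshold does not exceed the genome-wide minimum (e.g. a constant track)
yields no islands. Windowed scans below keep strict comparisons because
their scores are continuous.

Segment length dates the common ancestor as g = ⌊100/(2·L_cM)⌋ under the
1 Mb ≈ 1 cM convention (8 Mb → 6 generations, 16 Mb → 3).

## Linkage disequilibrium and phase persistence

Signed r between two SNPs is the Pearson correlation of their alt-indicator
haplotype columns (equivalently D/√(p q p q)); pairs involving a
within-population monomorphic SNP are excluded, never zeroed, because zeros
would bias decay curves downward. Decay bins are 10-kb steps from 10 to
100 kb then 100–200, 200–500 and 500–1,000 kb, half-open [lo, hi).
Adjacent-SNP summaries report mean ± SE (sd/√pairs) overall and within
disjoint distance bands (0–100], (100–300], (300–500] kb, at MAF thresholds
0, 1% and 5% (strict >; adjacency is consecutive-in-filtered-map; the MAF
vector can be supplied externally, e.g. the minimum of the two
subpopulations' MAFs so the filter holds in both). Phase persistence is the
per-bin Pearson correlation of signed r between the subpopulations over
shared pairs (100-kb bins from 0.1 to 5 Mb); bins with fewer than two pairs
are reported empty. Because the statistic is mean-centred within each bin,
it is exactly invariant to relabelling alleles at *all* SNPs but not to
relabelling arbitrary subsets — the sign convention (alt-allele indicators
under the shared map coding) is what makes r comparable across populations.
The marker-density helper is ⌊genome length / target spacing⌋, e.g.
2,875 Mb at 100 kb → 28,750 SNPs.

## varLD

Per 15-SNP sliding window (one-SNP step, never spanning chromosomes) an r²
matrix with unit diagonal is built per subpopulation; off-diagonal entries
involving a within-population monomorphic SNP are set to 0 so homologous
windows keep identical dimensions. The raw score is Σ_k |λ_A,k − λ_B,k| over
descending eigenvalues. Because both matrices have trace 15, Σλ is conserved
(asserted to 1e−9), making the score a pure structure contrast, symmetric in
the populations and invariant to joint SNP permutations. Raw scores are
standardized genome-wide to mean 0, sd 1 — a monotone map that leaves
percentile calls unchanged but matches the statistic's conventional
reporting. Regions require ≥ 2 consecutive windows strictly above the 99.9th
percentile. Window size is a flag (15/20/25/30).

## F_ST–heterozygosity outlier scan

Per-SNP components follow Weir & Cockerham's 1984 two-population estimator
with observed heterozygote proportions (no HWE assumption); sample sizes per
SNP come from non-missing genotypes, and SNPs with fewer than two genotyped
samples in either group or monomorphic in the pool are undefined. Negative θ
values are retained so percentile ranks are unbiased. Window θ is the
low-bias ratio of averages Σa/Σ(a+b+c) (mean-of-ratios available); window
heterozygosity is the mean of 2p̄(1−p̄). Windows are assigned to 20
equal-count heterozygosity bins — quantile bins stabilize the extreme
per-bin percentile better than equal-width ones — with bins smaller than 50
windows merged into a neighbor; each window is flagged against its own bin's
99.9th percentile, and regions require ≥ 2 consecutive flagged windows.

## Consensus signatures

Candidate regions from the four sources (each subpopulation's ROH islands,
F_ST, varLD) that overlap by ≥ 1 bp are merged into clusters; a cluster
qualifies as a selection signature when it carries ≥ 2 distinct sources,
with the two subpopulations' ROH islands counting as distinct, so an island
shared by both subpopulations qualifies on its own. The reported span is the
union of the member regions. Classification: support including a
between-population differentiation test (F_ST or varLD) ⇒ divergent
selection; both subpopulations' ROH islands alone ⇒ shared selection.
Region support from the same test twice never qualifies.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: two
subpopulations of one breed that split a few tens of generations ago, each
sampled at a few hundred animals and genotyped on an ascertained commercial
array. Its defaults are the study conditions used throughout the tests:

| parameter | default | why |
|---|---|---|
| chromosomes × SNPs | 3 × 1,000 over 50 Mb each | 3,000 SNPs at ~50 kb spacing: array-scale density at desk scale |
| ancestral frequencies | uniform on [0.05, 0.95] | reproduces an ascertained-array MAF spectrum (realized panel MAF ≈ 0.26 ± 0.14); a U-shaped spectrum would fill the panel with rare variants arrays do not carry |
| founder LD | 30 templates, latent AR(1) scale 300 kb, mosaic segments ~200 kb | calibrated so mean r² crosses 0.2 around 50–100 kb and falls to ~0.08 by 0.5–1 Mb |
| effective size | 250 per population | commercial beef-breed scale; keeps the 200 sampled diploids below the parent count |
| split generations | 20 (g ≥ 0 configurable) | recent-divergence regime; background F_ST ≈ g/2Nₑ ≈ 0.04 |
| recombination | uniform 1 cM/Mb | matches the ROH-age convention |
| inbreeding | 30% of final samples from full-sib matings | yields F_ROH ≈ 0.14 with long (> 8 Mb) autozygous runs |
| selection clamp | [0.02, 0.98] | keeps the selected site segregating |

Founders are drawn by a copying process over a small pool of template
haplotypes that are themselves autocorrelated along the chromosome
(thresholded latent Gaussian AR(1)), which creates block-like baseline LD; a
short ancestral burn-in (5 generations) precedes the split, and each
population then evolves g generations of Wright–Fisher mating with Poisson
crossovers. A selected locus resolves to the nearest SNP carrying a *rare*
allele (frequency 0.02–0.10 for an upward shift) and its frequency is moved
by the configured shift each generation via exact-count conditioning:
shortfall gametes are redrawn from random parents able to supply the allele,
which amplifies carrier lineages the way truncation selection does and drags
a local haplotype footprint (roughly the founder LD scale, widening with
sweep progress). Planting on a common standing variant was rejected: with
many carrier lineages the sweep is soft and leaves frequency shift but
almost no LD footprint. Realized trajectories are recorded per population;
an extinct allele stops conditioning and is flagged in the truth record.
`plant_roh_cohort` copies one haplotype interval onto its homolog for a
chosen fraction of samples (length uniform in [L, 2L); optionally confined
to a region, where per-sample jitter makes the cohort's coverage peak the
way selection-driven autozygosity does), recording every planted segment.

**What it does not emulate:** mutation, genotyping error, missingness,
realistic (non-uniform) recombination maps, 29 autosomes, X chromosome,
overlapping generations, or real breed demography. Passing the recovery
tests therefore shows the estimators and region-calling rules behave
correctly under a known, controlled two-population model — not that the
pipeline's empirical thresholds are well-calibrated for any particular real
breed's history.

## Problem sizes and runtime

The property suite runs the study-scale configuration (2 × 200 samples,
3,000 SNPs): 20 null replicates (g = 0) for estimator unbiasedness, 10
replicates each at g ∈ {0, 10, 50} for the divergence-time ordering (group
means plus one-sided rank tests), 20 selection replicates (shift
0.05/generation, 20 generations) for sweep recovery and end-to-end consensus,
and 2 planted-cohort panels for ROH recall and detector agreement. A full
pipeline run at this scale completes in a few seconds; the whole suite in
about two minutes.

## Known limitations

- **varLD sensitivity at desk scale.** With ~2,958 windows the 99.9th
  percentile admits only ~3, and although the sweep's shoulder windows are
  typically among the genome's top-scoring ones, they are often not
  map-adjacent, so the two-consecutive-windows rule voids many true calls;
  the suite measures roughly half of planted sweeps recovered by varLD
  versus essentially all by the F_ST scan under identical conditions. The
  contrast Σ|λ−λ| over a 15-SNP window is intrinsically bounded by the
  non-swept population's eigen-spread, so even a completed sweep is not far
  above background. At full array scale (~31k windows, ~31 admitted) adjacent
  runs survive far more often; the corresponding acceptance expectation is
  left failing rather than weakened.
- Sweep recovery is scored as a called region overlapping the selected site
  ± 1 Mb — the hitchhiking footprint scale at 1 cM/Mb over 20 generations —
  because LD-contrast statistics peak on a sweep's shoulders, not its core.
- The F_ST estimator is the two-population form; r > 2 populations,
  bootstrap CIs and haplotype-based F_ST are out of scope, as are
  imputation, phasing, liftover and annotation.
- The consecutive ROH detector is deliberately parameterized to mirror the
  sliding criteria (length, density, gap, one heterozygote), not any
  particular external tool's defaults; at these settings the two detectors'
  F_ROH agree at r ≈ 0.998 on default panels.
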