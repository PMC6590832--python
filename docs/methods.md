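# Methods

This note documents the models, conventions and numerical choices behind
`evopool`, in the spirit of a simulator/analysis package's methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Bottleneck theory (`evopool.pedigree`)

**Inbreeding recursion.** Expected inbreeding under random mating with
selfing excluded follows the two-generation-memory recursion

    F_t = F_{t-1} + (1 - 2 F_{t-1} + F_{t-2}) / (2 Ne),   F_0 = F_{-1} = 0.

The F_{t-2} term arises because an individual's two homologous alleles
come from two *distinct* parents.  The initial condition describes a
population already breeding at census N whose last two generations are
non-inbred; this matters for simulation (see §2).

**Step-count convention.** A line founded by drawing unrelated adults
from a large mass-bred base carries no inbreeding in its first bottleneck
generation, so F advances one step per mating among line members:
`steps = bottleneck_generations - 1`.  Two, three and five bottleneck
generations at Ne = 4 therefore give F = 0.125, 0.21875 and 0.38086
(reported to 3 decimals as 0.125, 0.219, 0.381).  The alternative
one-step-per-generation convention is available via
`count_first_pairing=True`.

**Harmonic-mean Ne.** For the census trajectories
[1000, 4 × gens, 200] the harmonic means are 7.905, 6.614 and 5.573
(reported to 1 decimal).  Because more bottleneck generations mean lower
Ne, the harmonic-mean values must be *anti-ordered* with expected F; a
report that pairs its lowest Ne with its least-inbred group has
transposed the low/high labels.  `ne_label_transposition_note` states
this explicitly, and all values in this package are keyed to census
trajectories, never to labels.

**Heterozygosity retention.** Single-generation Wright–Fisher binomial
drift retains E[H_t]/H_0 = (1 − 1/(2 Ne))^t of the founder
heterozygosity.  This is deliberately *not* 1 − F_t from the recursion:
the recursion's two-generation memory (non-self mating) delays inbreeding
relative to binomial resampling, and the two expressions agree only at
t ≤ 1 (at Ne = 4, t = 2: 0.2344 vs 0.21875).  Each quantity has its own
exact simulator counterpart (§2), and the test suite calibrates each
against its own oracle rather than conflating them.

## 2. Synthetic cohort (`evopool.simulate`)

The generator emulates the statistical structure of the study at desk
scale; its defaults are the stated experimental conditions wherever those
exist.

**Founder pool.** 30,000 loci with founder variant-allele frequencies
i.i.d. Beta(0.5, 0.5) truncated to [0.05, 0.95] — a U-shaped spectrum for
a large outbred base, with every locus genuinely polymorphic.  The base
spectrum is not reported anywhere, so this is a modelling choice, exposed
in the configuration.  Chromosomes 2/3/4/X are weighted 0.38/0.40/0.02/
0.20; the X fraction exists so the downstream autosome filter is
exercised.  The locus count is calibrated so post-filter SNP counts per
line fall inside the reported 11,267–35,496 range (realized ≈ 12k–19k).

**Drift, frequency level.** `simulate_drift` resamples each locus
independently as Binomial(2N, p)/2N per generation.  Founding from the
~1000-fly base is treated as frequency-preserving (the founders are
unrelated and the base is large), so a design contributes
`bottleneck_generations − 1` drift steps at the bottleneck census
followed by (default 2) flush generations at census 200.  Its exact
oracle is the retention factor of §1.  Loci fix at 0 or 1 and stay fixed.

**Drift, genealogical level.** `simulate_pair_mating_ibd` simulates the
four adults explicitly: every offspring draws two distinct parents
uniformly and one random allele from each.  Within-individual
autozygosity under this mating system obeys the F recursion exactly.
One subtlety: the recursion's F_0 = F_{−1} = 0 initial condition implies
that two *distinct* generation-0 individuals already share alleles IBD
with probability 1/(2N); starting from a fully unrelated gamete pool
therefore takes t + 1 matings to reach recursion step t, which is what
the function runs.  This simulator is the recursion's calibration
counterpart; it is not used to generate cohort frequencies.

**Line-to-line variance.** With ~30k independent loci, binomial drift
makes per-line retained heterozygosity essentially deterministic given
the census path — unlike real lines, whose diversity varies widely within
a treatment (wide within-group π spread; minimum diversity drops sharply
while the maximum barely moves).  The real drivers are variance in the
realized number of breeders and in reproductive success, plus linkage.
The generator emulates the first two by drawing each bottleneck
generation's effective gene-copy number 2Ne uniformly from {3, …, 14} —
from a skewed single pair up to the equal-contribution maximum
2(2N − 1) = 14 for four adults.  The mean per-step retention (0.854)
stays close to the census-4 value (0.875) while within-group spread
becomes realistic.  Linkage itself is not modelled (a known
simplification: drift is independent across loci conditional on the
census path), and neither are mutation, selection during drift, or
purging.

**Pooled sequencing.** 15 males → 30 autosomal gene copies per locus
(male X hemizygosity is not modelled; X loci are removed by the autosome
filter anyway).  Pool frequency q = Binomial(30, p)/30; coverage is
negative-binomial (dispersion 3, mean 45, mode ≈ 30) clipped to [0, 600],
spanning roughly the reported 10–515 per-site range; the variant read
count is Binomial(c, q).  Read-depth equalization across samples is
emulated by giving every line the same depth law rather than by read
subsampling — the pipeline starts at variant tables.  About 10 % of lines
"fail sequencing" and yield no variant table (119 of 132 lines had usable
diversity in the emulated study).

**Phenotypes.** Trait means follow baseline + β · relhet · g with
Gaussian noise, where relhet = retained/founder heterozygosity:
productivity baseline 2.0 flies·female⁻¹·day⁻¹, β = 0.15, SD 0.25; dry
body mass baseline 0.25 mg, β = 0.005 mg/generation, with 15 weighed
males of individual SD 0.03 mg.  Egg-to-adult viability is binomial over
the assayed eggs (5 vials × 15 eggs at generation 0, 10 × 15 at
generation 10): stress-medium viability starts near 50 % (the baseline
assay selects the acid level closest to 50 % survival) and gains
0.30 · relhet by generation 10; benign viability starts near 85 % and
loses a flat 0.02 in *every* line.  The diversity-independent benign cost
encodes the trade-off reading that fast responders pay the same cost as
slow ones — so diversity predicts the stress-medium change but not the
benign one, and the outbred before/after paired t is small relative to
its SE.  Extinction: each generation the simulated adult output is
Normal(190 + 155 · relhet, 50); the first generation below the 200-fly
collection rule marks the line extinct and truncates its trait series.
These phenotype constants are invented (the real line means live in
supplementary tables); they were chosen once for plausible fly-lab
magnitudes and are all configurable.

**Reproducibility.** Every line's randomness derives from
SeedSequence([master_seed, line_index]); identical configurations produce
byte-identical output files.

## 3. Diversity estimation (`evopool.diversity`)

π = Σ p(1 − p) over a line's variant loci, with p the called
variant-allele frequency.  Filters (defaults: coverage ∈ [10, 600],
≥ 1 variant read, frequency ≥ 10 %, autosomes {2, 3, 4}) follow the
calling tool's conventions; the 10 % threshold applies to the called
allele's frequency, not the folded minor-allele frequency (π is symmetric
in p, so only the filter is affected).  Loci fixed for the non-reference
allele (frequency 1) in every line where they appear post-filter are
removed from all lines; loci absent from some lines are judged on the
lines where present.  The exclusion runs after the per-line filter by
default (switchable, since the original order is unstated), and π sums
over each line's own loci (absent loci contribute nothing; also
switchable in principle by supplying union tables).  Estimates are
normalised to the mean of the outbred lines.  Positions are 1-based;
locus identity is (chromosome, position).

The plug-in estimator is biased downward at finite coverage:
E[p̂(1 − p̂)] = q(1 − q)(1 − 1/c) at coverage c.  The package does not
correct for this (the source analysis did not); instead the coverage K-S
diagnostic checks the premise that makes the bias comparable across
groups — similar coverage distributions.  Pairwise two-sample
Kolmogorov–Smirnov D with asymptotic p-values is reported for every group
pair, flagging pairs with p < 0.05.

## 4. Response analysis (`evopool.response`)

Productivity rate = total flies / ((parents/2) × laying days), with a 1:1
sex ratio and a 4-day default laying window (two 48-h bottles).  Response
slopes are unweighted OLS of trait line-means on generation index
(1–10); lines with fewer than 3 observed generations are ineligible
(excluded with a logged reason, not an error), and slopes are analysed
only for lines that never went extinct and have a diversity estimate.
Viability change Δ = v₁₀ − v₀ on the proportion scale with
SE = √(σ²₁₀/n₁₀ + σ²₀/n₀) (variance sum law).  Between-line CV = SD/mean
(sample SD, in %).  Extinction is the first generation with fewer than
200 collected adults.  The baseline stress level is the acid
concentration with viability closest to 50 %, ties broken toward the
lower concentration.

## 5. Predictor comparison (`evopool.compare`)

Single-predictor OLS fits report R² and the overall F on df (1, n − 2).
The encompassing model fits response ~ π + F; dropping one predictor
gives the partial F = (RSS_reduced − RSS_full)/(RSS_full/(n − 3)) on
df (1, n − 3), numerically identical to the Wald test of that single
restriction and to the squared coefficient t (asserted to 1e-8 in the
tests).  Perfectly collinear predictors raise a singular-design error:
the comparison is unidentifiable.  "Sequential Bonferroni" is implemented
as Holm's step-down, with an explicit family-size parameter m that may
exceed the number of supplied p-values.  Welch's t with
Welch–Satterthwaite df handles group contrasts of π (outbred vs each
inbreeding level, extinct vs survived); the paired t covers before/after
viability.  A Spearman-style option rank-transforms the
productivity-slope panel before fitting (productivity distributions are
often skewed); slope eligibility's minimum-generations threshold
(default 3) is configurable.  All p-values are two-sided; α = 0.05.
Fewer than 10 eligible lines make the comparison refuse rather than
fit.

## 6. What a green test establishes — and what it does not

The simulator reproduces the *structure* of the findings (diversity
ordering across groups, π out-predicting expected F, lower π in extinct
lines, the stress/benign trade-off signature) because those couplings are
built into its stated world; end-to-end tests assert each pattern in
≥ 80 % of 20 cohort replicates.  They do not — and cannot — reproduce the
study's real-data statistics (specific R², F and t values), which depend
on raw data the pipeline does not consume.  Only the closed-form theory
values (F = 0.125/0.219/0.381; harmonic Ne = 7.9/6.6/5.6; assay egg/vial
arithmetic) are exact reproductions.  Calibration tests tie the simulator
to drift theory within 3 Monte-Carlo SEs; the estimator-bias test ties
the π estimator to its binomial closed form.

## 7. Numerical conventions

Double-precision floats throughout; rounding only at report time (F to 3
decimals, Ne to 1, R² to 2 in formatted reports).  CSV outputs use fixed
6-decimal formatting, so re-running an identical configuration is
byte-identical; reading tables back recomputes frequency from the integer
counts to avoid rounding drift.  K-S uses the asymptotic two-sample
distribution with effective size n₁n₂/(n₁ + n₂).  OLS designs with
condition number above 1e10 are treated as singular.  Monte-Carlo
calibration bounds are ±3 empirical SEs across replicates; genealogies
within a replicate are correlated, so SEs are always computed across
replicates.
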