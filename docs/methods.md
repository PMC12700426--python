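# Methods

This note documents the models, defaults and numerical choices behind
`sostempo`, and what the synthetic data do and do not emulate.

## Differential expression

Counts are modelled as negative binomial with the mean/dispersion
parameterisation Var = μ + φμ². Normalisation is median-of-ratios against a
per-gene geometric-mean pseudo-reference (genes with a zero in any sample
are excluded from the reference), with factors rescaled to geometric mean 1.
This replaces TMM deliberately: it is fully specified in a few lines,
testable by hand, and behaves identically on data without strong
composition bias.

A single common dispersion is estimated by method of moments on
size-factor-normalised counts — per gene, pooled within-group variance s²
and overall mean μ̄ give φ_g = (s² − μ̄)/μ̄², and φ is the median over
informative genes clipped at 0. Tagwise empirical-Bayes shrinkage is out of
scope; at the replicate numbers simulated here (2–4) a common dispersion is
the smallest estimator that keeps the exact test calibrated (the type-I
test in the acceptance suite checks exactly this).

The two-group test conditions on the total of the integer pseudo-counts:
with group sums S_a + S_b = N, each sum is NB with mean proportional to its
replicate number and dispersion φ divided by it, and the two-sided p-value
aggregates all splits whose joint probability does not exceed the observed
one (minimum-likelihood convention, the same convention as the classic
binomial exact test, to which the statistic reduces at φ = 0). Pseudo-counts
are scaled to the *median* sample's library before rounding; this keeps the
typical sample unrounded and makes p-values exactly invariant when an
unrelated sample's library is rescaled. Comparisons are exact by
construction; the test suite pins them to an independent enumeration oracle
at |Δp| < 1e-12.

Induction calls use log2FC = log2((m_t + 0.5)/(m_r + 0.5)) on mean
normalised counts (pseudo-count 0.5 keeps zero-count genes finite) with the
strict thresholds log2FC > 1, p < 0.01, BH-FDR < 0.1. Strictness matters: a
gene at exactly log2FC = 1 is *not* induced.

## Regulon and temporal classes

Membership is the conjunction of the three expression criteria and
promoter-level LexA binding. Binding is decided by the promoter
peak-height rule — the smoothed rpm maximum inside the promoter window
(200 up/75 down of the CDS start) must clear a threshold (default: 3× the
genome-wide median of the smoothed track). The ±100 bp summit-to-gene
assignment rule is implemented and exposed (`chipcov.assign_summits`, with a
`start`/`span` anchor option) for sigma-factor-style analyses where it is
the appropriate convention, but it is not used for the LexA-binding
criterion: operators legitimately sit up to ~150 bp upstream, and a
start-anchored ±100 bp cut would censor them.

Overrides (genes deleted in the repressor-deletion strain, whose coverage
there is degenerate) are explicit inputs that force the derepression
criterion with a recorded reason — never hard-coded names.

TUs collapse over an input TU map (operon prediction is out of scope); the
promoter gene is the TU's first gene in transcription direction. A TU is
early when any member gene is induced at 20 min, late when induction
appears only at 40 min, and the 20-min call uses the identical threshold
triple as the 40-min call.

## LexA-box discovery and features

Discovery replaces a general motif finder with a dyad-seeded OOPS-EM,
which is fully specified and therefore testable: (1) enumerate windows
matching GTTC-N_k-GTTC, k ∈ [5, 9], allowing ≤ 1 mismatch per half-site, on
both strands; (2) build a PWM of the modal dyad length from the seeds
(pseudocount 0.25 per base; background = the promoters' base composition,
symmetrised between strands so that discovery commutes with
reverse-complementing the input); (3) refine by one-occurrence-per-sequence
EM until the relative log-likelihood gain falls below 1e-4 (≤ 50
iterations; the objective is monotone and tested as such); (4) report the
best site per promoter, or none where the best log₂-odds score is below
the floor (default 6; on the synthetic data planted operators score ≈ 29
while the best windows of operator-free random promoters stay below ≈ 16,
so any floor in between separates them).

Box features use coding-strand coordinates with the CDS start at 0:
`distance_to_cds` is the gap between the box 3′ end and the CDS start
(0 = immediately adjacent; negative down to −75 for boxes overlapping the
CDS), the spacer is the N_k core between half-sites, and spacer GC is
(G+C)/k. Sequence PCA one-hot encodes the boxes (4L columns),
column-centres and applies SVD; variance fractions are normalised squared
singular values, and an all-identical box set is reported as degenerate
rather than an error. Group comparisons use Student's unpaired t (pooled
variance) or Mann–Whitney U — exact by full enumeration over group
assignments with midranks when the smaller group has ≤ 8 observations
(ties included, so identical groups give p = 1), normal approximation with
continuity correction otherwise.

## ChIP coverage

Tracks are per-bp over the circular genome. rpm = value × 1e6/total reads;
smoothing is circular convolution with a unit-mass Gaussian truncated at
4σ (mass conservation is tested), so normalisation and smoothing commute.
Summits are circular local maxima above a height threshold, greedily
thinned to a minimum separation in descending height order. Meta-profiles
report two anchored blocks (±flank around CDS start and around CDS end,
minus-strand genes flipped) because CDS lengths vary.

## Single-cell kinetics

The logistic model has four parameters — baseline b, amplitude A, rate r,
midpoint t₀ — because pre-damage reporter fluorescence is nonzero.
Fitting is bounded nonlinear least squares (b, A ≥ 0, r ∈ (0, 10]) with
deterministic initialisation (b = min, A = range, t₀ = half-rise time, r
from the 25–75% rise span) plus four perturbed restarts from a fixed seed;
the best SSE wins. R² ≤ 0.95 flags the fit unconverged, which gates T_ind
(configurable). The doubling threshold uses the *observed* mean at t = 0,
not the fitted baseline, so T_ind is anchored to the data:

    T_ind = t₀ − (1/r) · ln(A/(2F₀ − b) − 1),   valid when b < 2F₀ < b + A.

Populations whose plateau never doubles the initial mean are censored with
an explicit reason and report the time of the observed maximum instead
(flagged); 2F₀ ≤ b with positive amplitude reports the T_ind = 0 boundary.
CV is the sample standard deviation (n−1) over the mean of the final-frame
area-normalised intensities.

## Promoter strength

β_max is proxied by the derepression log2FC (repressor deletion vs wild
type, no damage) at gene level, summarised per TU by its promoter gene.
Basal RPKM uses CDS length (not TU length; a config option records the
alternative). Origin distance is the shortest arc between the CDS start
and the configured ori. Pearson r is reported with r², a 95% CI on r via
the Fisher z-transform, and a two-sided t-test p; both r and r² are
reported because a CI is only well-defined on r.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis relies
on, at desk scale: a 300 kb circular genome carrying 200 non-overlapping
genes (600–1200 bp; ~30% in 2–3-gene operons; ≥ 250 bp between TUs), 40 of
them SOS (whole TUs, so co-transcribed genes share induction), 55% early.
Early TUs draw β (log2 derepression) from U(3.5, 5), late from U(2, 3) —
strictly separated so recovery questions are well-posed. Counts are NB
(φ = 0.05, basal mean 100, 3 replicates, lognormal library factors,
σ = 0.15) with means: basal everywhere for non-SOS genes and for SOS genes
in untreated wild type and in Δ*recA*; basal·(1 + (2^β − 1)·g(t)) in
damaged wild type with induction fractions g(t) of 0.8/1.0 (early, 20/40
min) and 0.1/0.7 (late) — chosen so early genes cross the DE thresholds at
20 min and late genes only at 40; and basal·2^β in the repressor deletion.
One operator sampled from a strong dyad PWM (half-site base probability
0.97, flat 7-bp spacer) is written into each SOS promoter at a
strand-aware offset drawn from −150..−30 relative to the CDS start.
Coverage is Poisson background (λ = 2/bp) plus a Gaussian read pile
(Poisson total ≈ 2000 reads, SD 40 bp) over every planted box.

Reporter kinetics: repressor decays as L(t) = L0·e^(−k_c·t) (L0 = 100,
k_c = 0.05/min, so half-repression at ≈ 46 min), promoter activity is
Hill-type a = β_cell/(1 + (L/K_d)^h) (K_d = 10, h = 2), and the reporter
integrates dF/dt = a − δF (δ = 0.02/min) by explicit Euler (dt = 0.1 min;
a closed-form oracle in the sharp-switch limit bounds the integration
error at < 1%) from the pre-damage steady state. Per-cell strength is
lognormal around β_max (CV 0.3); observed traces are (F + background)
with 5% multiplicative noise, sampled every 5 min for 6 h, with a slowly
growing area channel; the default normalisation divides intensity by area
at each frame. The β-independent background term (autofluorescence,
200 a.u.) is what makes T_ind informative about promoter strength: without
it the doubling time of a linear reporter would cancel β entirely.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level artefacts (mapping bias, multimapping,
batch effects), composition bias between libraries (which would stress the
normalisation), tagwise dispersion variation, operator sequences that
diverge systematically between early and late genes (planted boxes are
exchangeable by design, mirroring the study's null result rather than
testing it), ChIP input/background structure, photobleaching, cell-cycle
or growth-rate coupling of expression, and recovery kinetics after the
damage peak. The kinetic model is a stand-in that captures the
strength-orders-timing relationship, not a fitted model of any measured
induction curve.

## Numerical choices and degenerate inputs

0-based, half-open, circular coordinates everywhere; minus-strand CDS
starts are at `end − 1`. Exact-test joint probabilities are compared in
log space with an absolute 1e-12 slack so that symmetric ties are included
deterministically. All-identical replicate counts clip φ to 0; an
all-identical box set yields a degenerate PCA; flat traces yield an
unconverged fit and censoring rather than an error. A master seed
deterministically derives independent per-stage streams
(`numpy.random.SeedSequence.spawn`), so every output of a run — including
figure-free summary JSON and file checksums in the manifest — is
reproducible bit for bit.

## Problem sizes

Default analyses run on the 200-gene/40-SOS genome, with 100 cells per
reporter population and 20-seed replication for the recovery statistics;
the null-calibration check uses 2000 genes × 10 seeds. These sizes give
the recovery and calibration statistics enough resolution (binomial SEs of
a few tenths of a percent) while keeping a full run to seconds.

## Known limitations

The exact test is conditionally exact but slightly conservative at small
totals; the common dispersion underfits data with gene-specific
overdispersion; EM discovery assumes exactly one operator per promoter
(multi-box promoters keep their best-scoring box, consistent with the
~97% single-box rate reported for this regulon); summit calling is a
threshold/local-maxima caller, not a model-based peak caller, and merges
peaks closer than the separation parameter; per-cell (as opposed to
population-mean) induction-time fitting is out of scope.
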