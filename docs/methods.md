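# Methods

`stressatlas` implements the analysis chain of a combined abiotic-stress
expression atlas: seven single stresses — (C)old, (D)arkness, (H)eat,
(L)ight, (M)annitol, (N)itrogen deficiency, (S)alt — their 18 feasible
pairwise combinations (cold/heat and darkness/light are mutually exclusive,
heat/light is lethal), and two untreated control batches (F and L), three
replicates each: 27 conditions, 81 RNA-seq samples.  This note records the
models, the defaults and their rationale, the numerical choices, and what
the synthetic validation does and does not establish.

## Differential expression and consolidation

DE statistics are *consumed*, not estimated: the pipeline expects one
(gene, log2fc, BH-adjusted p) table per condition per control batch.  A
gene is a DEG in a condition only when padj < 0.05 and |log2fc| > 1 against
**both** controls, with strict inequalities (a gene exactly at a threshold
is not called).  Genes missing from one contrast are treated as non-DE
there, which is conservative for the intersection.  "Modeling genes" for
network inference are DEGs in more than five of the 25 stress conditions.

## Combined-stress set metrics

For combined condition `xy` with per-direction DEG sets Sx, Sy (first and
second letter) and Sxy:

* similarity = |Sx ∩ Sy| / |Sx ∪ Sy| (Jaccard; 0 when both empty);
* suppression = |Sx \ Sxy|/|Sx| − |Sy \ Sxy|/|Sy| — the fraction of the
  first stress's response lost in the combination minus the fraction of the
  second's.  +1 means Sy suppressed Sx entirely; the sign convention was
  checked against the worked example in which darkness (second letter)
  suppresses part of the cold response, giving a positive value;
* novelty = |Sxy \ (Sx ∪ Sy)| / |Sxy| (0 when Sxy empty).

The loss fractions are normalized by the single-stress set sizes (not the
union); every undefined ratio contributes 0, so the ranges [0,1], [−1,1],
[0,1] hold degenerately.  Only verbal range/interpretation statements pin
these formulas down, so the reconstruction is validated against brute-force
element counting over random set triples in the test suite.

## Pathway activity

Functional bins are MapMan-style dot-separated codes (Mercator X4 tables),
analysed at the second level by default.  For one condition and direction,
the permutation test draws |DEG set| genes uniformly from the annotated
universe (all annotated genes in the expression matrix — not all DEGs)
`n_perm` = 1000 times; empirical p = (1 + #{permuted count ≥ observed}) /
(n_perm + 1), BH-corrected **within condition × direction** (the scope of
the correction is a design choice; a global correction over the whole
matrix would be the alternative).  The hypergeometric tail probability is
reported alongside, since the two tests estimate the same quantity and the
agreement is a useful diagnostic.  Bins are classified U / UD / D / N from
the two directions at padj < 0.05.  The condition × bin matrix is ordered
by average-linkage hierarchical clustering on Jaccard distances between
binary significance profiles (up-bits and down-bits concatenated); linkage
method is our choice (unspecified upstream), and labels are sorted before
clustering so leaf order is deterministic.  A bin responds *robustly* to a
stress group (all conditions containing the stress letter) when it is
significant in the same direction in more than 70% of the group.

The empirical p is mildly conservative when the count statistic takes few
values (ties inflate the ≥ count); the calibration study therefore uses
large bins and draws (count sd ≈ 15), where the p-value lattice is fine
and the null distribution is indistinguishable from uniform at 500
replicates.  With small bins the test stays valid but conservative.

## Network inference

One ElasticNet model per modeling gene (response) per dataset.  Eight
datasets: seven stress-specific slices (all conditions whose code contains
the stress letter — darkness has 6 × 3 = 18 samples, heat and light 15,
the media stresses 21 — no controls) and ALL (81 samples).  Values are
log2(TPM+1), z-scored per gene within each slice (per-slice rather than
global scaling keeps each dataset's model selfcontained); predictors are
the differentially expressed TFs among the responses, and a TF never
predicts itself.  Genes constant within a slice are dropped from it.

The objective is squared loss / 2n + strength · (mix·‖β‖₁ +
(1−mix)/2·‖β‖₂²).  Grids: mix 0.1–0.9 step 0.1; strength 0, 0.001, 0.01,
0.05, 0.1, 0.5, 1, 1.5, 2, 10, 100, with strength 0 an ordinary
least-squares fall-back (minimum-norm on rank-deficient slices).  The grid
names deliberately separate the L1/L2 *mixing fraction* from the overall
*penalty strength*; selection minimizes mean cross-validated MSE
(3-fold for stress slices, 5-fold for ALL; folds are contiguous blocks of a
seeded shuffle), with ties broken toward the smaller strength, then the
smaller mix.  The chosen pair is refit on the full slice and R² is
computed in-sample on the refit — the filter (R² > 0.8, strict) applies to
models, not CV scores.  The union of the seven stress-specific networks
(nonzero coefficients of kept models) is the working network; ALL is kept
separately for comparison.

High-confidence GRN: within each model a TF's *relative coefficient* is
|β_tf| / Σ|β|; per (TF, target) the maximum across datasets is taken, and
per target the argmax TF is the single regulator (lexicographically
smallest TF on ties).  Sign consistency across the supporting datasets
classifies the TF as activator (all positive), repressor (all negative),
or ambiguous.

An identifiability caveat the synthetic experiments make explicit: under a
noiseless additive model the 25 stress-condition profiles span at most a
7-dimensional space, so at most seven TF profiles are linearly independent
— recovery can only be exact when the planted TF panel respects that rank
(the noiseless end-to-end checks use one TF per stress), and coefficients
are identified in standardized units (planted coefficient × TF profile sd).

## TF regulatory network

A TF responds robustly to a stress group when it is a DEG with consistent
direction in more than 70% of the group's conditions (group sizes: C 6,
D 6, H 5, L 5, M 7, N 7, S 7).  Across groups a TF's status is up, down, or
ambiguous (robust in both directions somewhere); TFs with no robust
response are treated as ambiguous for edge classification.  TF→TF edges
take the maximum absolute relative coefficient across datasets as weight
and sign consistency of that pair's coefficients as mode.  An edge is
*expected* when an activator's source and target share direction or a
repressor's differ; anything involving an ambiguous status or mode is
ambiguous and excluded from both numerator and denominator of the
expected-edge ratio (this keeps the ratio well defined; whether ambiguous
edges belong in the denominator is not decidable from the method's verbal
description).  The global cut-off sweeps |coefficient| thresholds from 0 to
the maximum in 0.01 steps, keeps edges at or above the threshold, and
returns the threshold maximizing expected/(expected+unexpected), ties
toward the smaller threshold (which retains more connected TFs).  The
number of TFs retaining at least one edge is reported with the ratio.

TF→bin links: a robust TF is linked to a robust bin when its
high-confidence targets cover at least 5% of the bin's genes in the
universe; the link is classified with the same expected/unexpected rule,
using the TF's prevailing mode (majority over its high-confidence edges;
ambiguous on ties) and the bin's robust direction.

## Cross-species comparison

Inferred edges are translated to orthogroup→orthogroup tuples through a
per-species gene→family map (unmapped edges dropped and counted,
duplicates collapsed) and compared with a curated reference network by
Jaccard index.  Significance: the reference's target column is permuted
(1000×) holding regulators fixed — the simplest re-pairing scheme; a full
independent permutation of both columns is available behind a flag — and
p = (1 + #{JI ≥ observed}) / 1001.  Family-level conservation per stress:
families (restricted to those present in both species) containing at least
one DEG, direction-agnostic (the direction split is not specified for this
test; pooling is our choice), compared by JI against a null that shuffles
each species' gene→family assignment.

## The additive model

For gene g and stress pair, Sxy = b0 + bx·Sx + by·Sy fitted by OLS (numpy
least squares with an explicit rank check; collinear designs raise an error
with the condition number).  Two granularities: the *global averaged* fit
pools the 9-category cells (gene status down/nc/up in Sx and in Sy, from
the consolidated single-stress DEG calls; cell means of Sx, Sy, Sxy;
empty cells excluded; cells unweighted by gene count) over the focal
stresses; the *per-stress* fits use raw per-gene values pooled over one
focal stress's combinations, and the descending order of their Sx
coefficients is the dominance ranking (alphabetical on ties, flagged).
Per-gene log2fc for a condition is the mean of the vs-F and vs-L contrast
estimates; genes absent from a combination's table are dropped from that
combination.

Orientation: the generator defines (b0, bx, by) per combined code with bx
multiplying the first letter's vector.  The headline analysis assigns each
combination to both of its stresses' focal groups (Sx = focal; 63 cells),
which mixes bx and by when they differ; the `first-letter` orientation
(each combination counted once, Sx = first letter) matches the generative
model and is the one under which planted coefficients are identified, so
parameter-recovery experiments use it.  Outcome classification per gene:
higher / lower / within the range of the two single-stress responses.

## Synthetic data generator

The generator is the testbed for everything above.  Defaults: 2000 target
genes, 50 TFs, TF→target edge density 0.02 (≈ 2000 planted edges),
activator fraction 0.7, activator coefficients U(0.5, 1.5) (negated for
repressors), per-stress activation of disjoint TF blocks (overlap
configurable) with signed magnitudes U(2.5, 4.5) — strong direct responses
of a few log2 units, the regime in which stress regulons are reported —
additive coefficients (−0.04, 0.61, 0.69) for every combination, log2fc
noise sd 0.5.  Single-stress log2fc = planted coefficient matrix ×
activation + Normal(0, noise_sd); combined log2fc applies the additive
formula to the *realized* (noisy) single-stress vectors and adds fresh
noise, so the additive relation is exact at noise 0 and the downstream OLS
is a correctly specified regression rather than an errors-in-variables
problem.  Expression: per-gene log-normal baselines (median 100 TPM, log2
sd 1.5), condition mean = baseline × 2^log2fc, replicates ×
2^Normal(0, dispersion) with dispersion 0.25; both control batches are
drawn from the same distribution.  DE tables use a per-gene Welch t-test
on log2(TPM+1) with BH correction — a deliberately simple stand-in for a
count-based negative-binomial model, sufficient because only the
thresholding/consolidation logic consumes the tables.  The per-gene noise
model of real RNA-seq is not log-normal at low counts; pseudocount-1
attenuation of log2fc estimates for weakly expressed genes is a known
artefact of the stand-in.  One global seed fans out to stage seeds by
fixed offsets (truth +1, log2fc +2, expression +3, annotations +4,
orthology +5, modulo 2³¹).

What passing synthetic tests shows: the estimators recover what they are
pointed at under the generator's assumptions (linear propagation, additive
mixing, log-normal noise, independent replicates).  What they do not show:
robustness to batch effects beyond the two-control design, count-level
noise, unmeasured regulators, or non-additive stress interactions.

## Problem sizes

Tests and the acceptance report run desk-scale versions chosen as the
smallest sizes at which each property is identified: 400-target atlases
for end-to-end runs; 500 noiseless and 20 × 25 noisy planted regressions
(n = 100, 50 TFs) for recovery; 50 seeds at 2000 genes for additive
coefficient recovery, plus 200/2000/20000-gene ladders for the 1/√n RMSE
scaling; 500 replicates × 199 permutations for calibration.
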