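# Methods

## The screening procedure

The pipeline analyses a four-group factorial rescue design: young controls
(YC), aged controls (AC), and aged animals under short-term (ST) or
long-term (LT) restorative treatment, six arrays per group, on an unlogged
RMA-style intensity scale. Its question is two-staged: which genes change
with aging (AC vs YC), and which of those changes the treatment counters
(ST/LT vs AC, opposite in sign to the aging change).

### Prefilter

A gene is *present* when its unlogged intensity is at least
`min_intensity` (default 40) on at least `min_arrays` (default 4) arrays
anywhere in the study. The rule is deliberately group-agnostic; missing
values count as below threshold. When annotation is required, unannotated
probes are dropped and duplicate annotations are collapsed to the probe
with the highest mean signal. The collapse rule is this package's choice —
reasonable alternatives (longest probe, median signal) exist and would
retain slightly different universes; the choice only affects which probe
represents a gene, not whether the gene is testable.

### Outlier masking

Within each group, values more than `outlier_sd` (default 2) sample SDs
from the group mean become missing. The pass is single: mean and SD include
every point (including the candidate outlier), all candidates are masked
simultaneously, and the rule is not reapplied — this avoids
order-dependence and runaway trimming. A structural fact worth knowing:
in a sample of n points the largest attainable |x − x̄|/s is (n−1)/√n,
which is ≈ 2.041 at n = 6. A 2-SD rule at n = 6 therefore only ever
removes a single point sitting essentially alone against five tight
replicates; on well-behaved (e.g. normal) data it is nearly inert.

### ANOVA and protected LSD

Each gene gets an unbalanced one-way fixed-effects ANOVA over its retained
values (groups failing `min_group_n` = 2 render the gene *untestable*, a
reported outcome rather than a silent drop). Pairwise contrasts use
Fisher's LSD with the pooled mean square error:

t = (x̄ᵢ − x̄ⱼ) / √(MSE·(1/nᵢ + 1/nⱼ)),   two-sided p on the residual df,

*protected* by the omnibus test: a contrast is significant only if its own
p ≤ α **and** the ANOVA p ≤ α (α = 0.05 everywhere). Degenerate inputs are
flagged, not hidden: zero within-group variance with unequal means gives
F = ∞, p = 0 with a `degenerate` flag; identical groups give F = 0, p = 1.

Multiple testing is summarized by the ratio estimator
FDR = (α · n_tested) / n_significant — the screen's historical convention,
not a Benjamini–Hochberg adjustment — reported as not-applicable when
nothing is significant. Note this estimator applied to a screen of 14,828
genes with 3,502 significant gives 0.21; published summaries of such
screens sometimes print lower values computed by other (unstated) means.

### Template classification

For an aging-dependent gene (ANOVA and protected YC–AC contrast both
significant), the aging direction is sign(x̄_AC − x̄_YC), and the
significant rescue arms (ST–AC, LT–AC) decide the template:

| aging | no significant arm | all arms opposite aging | any arm with aging |
|-------|--------------------|-------------------------|--------------------|
| down  | I                  | II                      | ANOMALOUS          |
| up    | III                | IV                      | ANOMALOUS          |

Conflicting arms (one countering, one exacerbating) are ANOMALOUS: the
countered templates are reserved for genes whose every significant arm
opposes aging. Genes failing the omnibus test are NOT_SIGNIFICANT; genes
passing it but not the YC–AC contrast are NOT_AGING. The labels partition
every tested gene. A zero mean difference alongside a significant contrast
cannot occur under exact arithmetic (t would be 0); if it ever arose from
pathological input the gene would remain in the non-template class rather
than receive an arbitrary direction.

### Monte Carlo null

The chance expectation for each template is estimated by rerunning the
identical procedure — ANOVA, protected LSD, template assignment — on
freshly drawn i.i.d. standard-normal values (genes × 4 groups × n),
tallying template counts, and averaging over iterations (default 1000,
matching the procedure's convention; the estimate's SE shrinks as
1/√iterations). Under the null the groups are exchangeable, so the choice
of distribution is immaterial to the rejection rates; normals are used and
stated. Outlier masking is omitted in the null by default (it is nearly
inert at n = 6, see above; a flag can enable it). Observed counts are then
expressed as observed/expected folds with exact one-sided binomial tails
(n = n_genes, p₀ = expected/n_genes); a zero expectation floors p₀ at
1/(n_genes · iterations), the simulation's resolution, and reports the
fold as infinite.

**What the null actually looks like.** The screen's conditional structure
makes the *countered* templates the favored chance outcome. For a null
gene, P(ANOVA p ≤ .05) ≈ 0.05 and P(aging-dependent) ≈ 0.020 — the omnibus
and contrast events are strongly positively correlated, so the joint is
far above 0.05² = 0.0025. Conditional on being a chance "aging-dependent"
gene, the AC mean is extreme, and because AC enters both the aging
contrast (YC–AC) and the rescue contrasts (arm–AC), the arms regress
toward the mean: ≈ 55% of chance aging-dependent genes acquire a
significant arm *opposite* the apparent aging direction. At 14,828 genes
this yields expected counts of roughly 165 for II+IV versus roughly 133
for I+III (anomalous chance patterns are rare, ≈ 0.01%). Fold-over-chance
claims for countered templates are therefore intrinsically harder to
sustain than for unchanged templates, and a screen's headline folds should
be read with this asymmetry in mind. These expectations are recomputed,
not quoted, by `scripts/acceptance.py` and the acceptance test suite.

The same correlation structure bounds the screen's specificity: ≈ 2% of
pure-noise genes end up in *some* template (≈ 1.1% in II/IV), a floor set
by the protected-contrast joint probability, not by implementation error.

### Concordance, overlap, enrichment

Over the rescue-sensitive genes (II + IV + ANOMALOUS), the ST/LT direction
concordance is the share of genes with sign(x̄_ST − x̄_AC) =
sign(x̄_LT − x̄_AC) (zero differences excluded with a reported count),
tested against 0.5 with the exact one-sided binomial tail; effect-size
agreement is Pearson's r between log2(x̄_LT/x̄_AC) and log2(x̄_ST/x̄_AC),
computed from group means of unlogged intensities. The ST/LT list overlap
is compared with the independence expectation n_ST·n_LT/N over the
aging-dependent universe, again with an exact binomial tail — the
construction is stated because published overlap p-values rarely pin down
their universe.

Enrichment uses the EASE score: the one-tailed hypergeometric
(Fisher's exact) upper tail with the list–category overlap decremented by
one, P(X ≥ max(h−1, 0)) — conservative by construction (EASE ≥ Fisher
always, and a single-gene overlap can never score). Category membership is
counted within the filtered background only; categories are *retained*
when h > 3 and EASE p ≤ 0.05. Raw EASE scores are reported (with a
Benjamini–Hochberg column for information only); no redundancy clustering
of overlapping categories is attempted, so the single most significant
category among near-duplicates is not automatically deduplicated.

## The synthetic-data generator

`SimulationDesign` defaults emulate the real screen: 14,828 genes, 6
arrays per group; log-normal baselines (ln-scale mean 5.3, SD 1.1) giving
unlogged intensities spanning tens to thousands with ≈ 5–10% of genes
below the presence threshold; multiplicative within-group noise
(SD = cv · mean, cv = 0.08, matching SEMs roughly proportional to means at
this scale); ≈ 15% aging-dependent genes split evenly up/down with effects
of 3 within-group SDs; rescue arms split ST-only/LT-only/both/none as
0.08/0.22/0.07/0.63 (the observed ordering: LT-only most common); full
restoration (rescued arm mean = YC + (1 − restore)·(AC − YC) with
restore = 1); and a 0.2% exacerbated class whose rescue arms move a further
half effect-size beyond AC. Truth labels record *planted* means — a gene
planted as countered but missed by the screen counts against recovery, so
recovery metrics must condition on effect size. In the noise-free limit
(cv = 0) the effect unit falls back to 10% of baseline so planted structure
remains visible; draws are floored at a tiny positive epsilon to keep the
unlogged-scale invariant (unreachable at default cv). Gene sets are
generated by weighted sampling (weight = enrichment factor for the target
class, ∞ restricts to the class), giving planted-positive and calibrated-
negative fixtures for the enrichment stage.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated expression between genes (each gene is
independent); sub-threshold treatment response in "non-rescued" arms (they
sit exactly at AC, so the planted ST/LT fold-change correlation is far
weaker than in real data, where both arms respond to some degree in almost
every sensitive gene); batch/spatial artifacts; heavy-tailed noise; and
probe-level effects (the generator emits one row per gene, post-collapse).

## Problem sizes and determinism

Tests run the planted benchmark at 2,000 genes (recovery of planted
countered genes ≥ 90% is met with margin at the 3-SD effect size) and
null-calibration checks at 10,000 genes; the chance-expectation
computation runs at the full 14,828-gene scale with 150 iterations in the
test suite and 1000 in `scripts/acceptance.py` — the quantity being a mean
count, 150 iterations already put its Monte Carlo SE near 1 gene. Every
stochastic component takes an explicit integer seed (numpy `default_rng`);
identical seeds give bit-identical matrices, expectations, and output
files. Reported percentages round half away from zero at fixed precision
(integer percent for headline ratios, one decimal for concordance), so
formatted reports are byte-stable across platforms.

## Known limitations

- The presence filter's duplicate-annotation collapse is one defensible
  rule among several; universes from other tools may differ by a few
  percent.
- The ratio-estimator FDR is reported because it is this screen's
  convention; it is coarser than step-up procedures and can exceed 1.
- The null calibration of the protected contrasts assumes exchangeable
  groups; real arrays with batch structure violate this, and the Monte
  Carlo null (fresh random numbers, not label permutations) does not
  capture such structure.
- EASE scores are reported per category without topology-aware
  deduplication of overlapping gene sets.
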