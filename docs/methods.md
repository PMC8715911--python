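# Methods

## The classification problem

A stream reach belongs to one of three flow-duration classes — ephemeral,
intermittent, perennial — defined operationally from daily flow records:
perennial if strictly fewer than 5% of recorded days are zero-flow,
ephemeral if strictly fewer than 5% are flowing, intermittent otherwise.
The strict inequalities make the rule a partition: exactly 5% on either
side is intermittent, and because the two fractions sum to one the
perennial and ephemeral conditions cannot both hold. Records shorter than
a month are rejected rather than classified.

The field method must decide the class from a single visit, so it may also
return two hedged outcomes: *At least intermittent* (ALI — confidently not
ephemeral, without resolving intermittent vs perennial) and *Need more
information* (NMI — abstention).

## The beta field method

The shipped method is a lookup table over five categorical indicators:
hydrophytic plant species (none / 1–2 / ≥3), aquatic invertebrate abundance
(none / 1–19 / ≥20 individuals, tallies capped at 10 per morphotaxon), EPT
taxa (absent/present), algae (absent/present), and a single-indicator flag
(live fish observed, or algal cover ≥ 10%). Two combinations are
structurally inadmissible — EPT taxa without invertebrate evidence, and the
algal-cover single indicator with algae absent — leaving 60 of the raw 72
combinations. The table ships as versioned CSV data inside the package
(`sdamaw/data/beta_classification_table.csv`) rather than code, so any
correction against the typeset publication is a reviewable one-line diff.
Two cells of the published table are ambiguous under some renderings of its
blank-cell carry-over convention (hydrophytes none, invertebrates present,
EPT absent, algae present, no single indicator); we encode them as NMI,
the column-aligned reading.

Single indicators only ever upgrade: an Ephemeral or NMI outcome becomes
ALI when a single indicator is present; Intermittent, Perennial and ALI
outcomes are never changed, and no override can produce Ephemeral.

## The development pipeline

The framework that produced the table is implemented end to end and runs on
any visits × metrics table.

**Metric computation.** Raw indicator records become ~45 numeric metrics:
capped-tally abundances and family richness for invertebrate groups (EPT,
mayflies, perennial-indicator taxa, non-insects, GOLD, OCH), relative forms
as group/total with 0/0 defined as 0 (an empty sample carries no
compositional signal), ordinal protocol scores passed through, shading as
the mean of densiometer readings, and hydrology/geomorphology counts and
percentages. Metrics that directly measure water presence (surface and
subsurface flow extent, water-in-channel score, soil moisture, isolated
pools, seeps) carry a `direct_water` flag so models can be built with or
without them; geospatial columns are accepted pre-computed and flagged
`geospatial`. Visits missing a mandatory indicator are excluded with a
logged reason, never imputed. A visit counts as "flowing" iff any surface
flow was recorded — the protocol ties the dichotomy to the visual estimate,
and this convention is applied uniformly.

**Screening.** Each metric must pass a distribution criterion (most common
value below 95% of rows) and at least one responsiveness criterion: one-way
ANOVA F > 2 across the three classes; Welch two-sided |t| > 2 for any of
the contrasts ephemeral vs at-least-intermittent, perennial vs
non-perennial, perennial vs flowing-intermittent, ephemeral vs
dry-intermittent; or top-quartile importance in a single 500-tree random
forest fit on all metrics. Welch's unequal-variance t is used because group
sizes are unequal by design. A statistic that cannot be computed (group
with fewer than two rows, or no variance anywhere) is flagged undefined
and counts as criterion-not-met, never as a pass. The importance quartile
is computed over all metrics entering screening and then intersected with
the other criteria; ties share the better rank. Screening uses initial
visits only — revisits are withheld from all fitting.

**Importance.** Variable importance throughout is mean decrease in
accuracy computed on out-of-bag samples: for every tree, accuracy on the
rows it did not see during its bootstrap is compared with accuracy after
permuting one feature among those rows, and the drop is averaged over
trees. Computing on out-of-bag rather than training rows is essential —
a forest fits its calibration data essentially perfectly, so training-set
permutation importance is dominated by ties at zero and cannot rank
correlated informative metrics above noise.

**Splitting and selection.** Reaches (not visits) are split 80/20 into
calibration and validation, stratified by (subregion, class); within each
stratum round(0.8·n) go to calibration, and singleton strata go to
calibration so every stratum contributes to fitting. Recursive feature
elimination starts from all screened metrics, dropping the five least
important per step down to 20, then one per step down to a single metric.
Each subset is scored by stratified 5-fold cross-validated Cohen's κ
(κ = (p_o − p_e)/(1 − p_e), chance term from marginal products). The
selected model is the smallest whose κ is within 1% (relative) of the best;
if that would exceed 20 metrics, the 20-metric model is used. The 1%
tolerance is read as relative (κ ≥ 0.99·κ_best), the common convention; an
absolute option is available.

**Vote model and decision rule.** The final classifier is a bagged forest
of 1500 trees with √p candidate features per split; votes are literal
per-tree vote fractions, not averaged leaf probabilities, so a vote vector
is exactly the share of trees for each class. (A single cost-complexity-
pruned classification tree is available as the alternative model kind; its
vote is degenerate — 1 for the leaf class. The rpart-style defaults map to
`ccp_alpha = 0.01`, `min_samples_split = 20`; the pruning semantics of the
two implementations differ slightly but both expose the same contract.)
Votes become outcomes via a confidence threshold τ ∈ [0.5, 1]: a class with
votes ≥ τ wins; otherwise combined intermittent + perennial votes ≥ τ give
ALI; otherwise NMI. Both comparisons use ≥, harmonizing the source
wording; a consequence is that at τ = 0.5 NMI can arise only from an exact
vote tie involving the ephemeral class (ties between I and P resolve to
ALI, ties involving E to NMI). The threshold sweep evaluates the five
outcome shares on the grid 0.50 to 1.00 in steps of 0.025; by
construction the abstention share is non-decreasing and each specific-class
share non-increasing in τ, and for any fixed vote vector the outcome passes
through at most three contiguous regimes (specific → ALI → NMI).

**Discretization and crosswalk.** To turn the fitted model into a paper
form, each selected metric's partial-dependence curve (mean class votes
with the metric pinned to each grid value; observed unique values for
counts, a 50-point grid otherwise) is reduced to a step function by
least-squares segmentation with at most two breaks; breaks whose
between-segment vote change is below 0.05 are merged away, so a flat curve
yields no cut. Adjacent-point jump detection was rejected: on a fine count
grid a strong but gradual dependence never produces a single large adjacent
jump. The shipped field method always uses the published cut points
(hydrophytes 0 | 1–2 | ≥3; invertebrates 0 | 1–19 | ≥20; algal cover
not-detected | <10% | ≥10%); the automatic proposer exists to reproduce the
workflow on new data. A forest refit on the discretized calibration data is
then enumerated over every admissible level combination crossed with the
single-indicator flags to produce the crosswalk table; lookup is total over
admissible inputs and identical to running the model + threshold + override
pipeline. Crosswalk enumeration is only attempted when the selected model
has at most 8 metrics (3^p combinations grow too fast beyond that); larger
models classify directly from votes.

**Evaluation.** Seven accuracy measures (3-way PvIvE; binary EvALI and
PvNP; PvIwet restricted to perennial and flowing-intermittent rows; EvIdry
restricted to dry ephemeral/intermittent rows; the literal EnotP and PnotE)
plus repeatability (share of revisited reaches with the identical label on
both visits — exact equality, so ALI vs Intermittent is a mismatch). Every
report records its scoring convention for the hedged outcomes. The default:
ALI is credited as correct when the true class is intermittent or perennial
for EvALI, EvIdry, PvNP (and trivially for EnotP/PnotE, which only ask
whether the named wrong call was made, so NMI is also "correct" there);
ALI is incorrect for PvIvE (strict 3-way) and for PvIwet (ALI cannot
resolve perennial vs intermittent); NMI is incorrect everywhere, with an
exclusion option since the published treatment of abstentions in
denominators is not fully determinable. Under any single convention
EvALI ≥ PvIvE, since it scores a coarsening of the same partition.

## The synthetic generator

The generator emulates the study design the pipeline assumes: 150 reaches
(the development study used 89; 150 keeps every (subregion × class) stratum
comfortably populated at the default uniform proportions), three classes ×
five subregions, 10% of reaches revisited, and a dry-at-sampling
probability per class (E 0.93, I 0.40, P 0.0 — echoing the observed
column structure in which essentially all perennial visits and almost no
ephemeral visits found flowing water). Six informative biological metrics
are negative-binomial counts (dispersion 5 — overdispersion typical of
invertebrate tallies) with class-ordered means E ≤ I ≤ P, matching the
empirical pattern that no indicator takes higher values at drier reaches.
Their discrimination patterns are deliberately complementary, mirroring
real indicator suites: two ordered across all three classes (total
abundance / richness style), two separating ephemeral from wetter reaches
(hydrophyte style), two separating perennial from the rest (EPT style) —
so each carries non-redundant signal and a selection procedure should keep
all six. Class-mean profiles are stated at the reference effect size of 1.5
standardized adjacent-class separations and scale linearly with the
`effect_size` parameter; at 0 all signal vanishes. Fifty noise metrics
(counts, continuous scores, and six geospatial-flagged columns) are
class-independent. Two direct-water metrics are zero at dry visits and
class-ordered percentages at flowing ones, so the "exclude direct measures"
pipeline option is exercisable. Flow records draw the flowing-day count
inside the generating class's band with a margin that guarantees the 5%
rule recovers the class exactly, laid out as a contiguous wet season.

What the generator does **not** emulate: spatial correlation among nearby
reaches, subregion-dependent indicator distributions, observer error and
between-visit indicator drift beyond fresh sampling noise, missing data,
and the evidence-tier heterogeneity of real truth labels. Passing pipeline
tests on this generator therefore demonstrates the machinery is correct
and can recover planted structure — not that the method achieves any
particular accuracy on real arid-west reaches.

## Numerical and scale choices

Problem sizes were chosen to keep the default test run and the acceptance
script at desk scale: screening and RFE forests use 100–300 trees in tests
and the acceptance script (500 is the library default), final fits 200–300
(1500 is the method's production default and used when fidelity to the
field method matters). Cross-validated κ uses 5 folds, reduced
automatically when a class has fewer calibration reaches than folds. The
acceptance script averages the pipeline over 3 seeds and the dedicated
parameter-recovery test over 5. Vote sums are validated to 1e-9;
statistical oracle comparisons are asserted to 1e-10. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

- The stratified (subregional) pipeline option fits one model per
  subregion and pools predictions; with few reaches per subregion its
  κ estimates are noisy, and the returned model object is the largest
  subregion's (the pooled predictions are the stratified result).
- The crosswalk path requires every selected metric to be discretized;
  when cross-validation noise keeps a large metric set within the 1%
  κ tolerance, the model stays continuous and no crosswalk is produced.
- `rpart`-style pruning and scikit-learn cost-complexity pruning are not
  numerically identical; single-tree results are contract-compatible, not
  bit-compatible, with the original tooling.
- Reproducing the published performance numbers requires the original
  deposited field dataset, which is not bundled; the acceptance script
  reports the synthetic-condition quantities instead.
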