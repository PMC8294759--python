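# Methods

This note documents the models, conventions and numerical choices behind
`mdinet`, what the synthetic-data generator does and does not emulate, and
the known limitations of each stage.

## Exact-mass arithmetic

All annotation is carried out over the element alphabet C, H, N, O, P, S,
Na with monoisotopic atomic masses (IUPAC/AME2020) hard-coded to ≥ 9
decimal places. Ionisation uses the proton mass (1.00727646688 Da) for
[M+H]⁺ and the sodium atomic mass minus the electron mass for [M+Na]⁺, so
calibrant values such as arginine [M+H]⁺ = 175.11895 follow from the table
with no fitted constants. A `MassDifference` encodes a biochemical
transformation as the formulas gained and lost; its Δm =
m(gained) − m(lost) is strictly positive by convention, so network edges
always point from the lower-mass to the higher-mass feature. The packaged
default list holds ~50 curated transformations (water, CO₂, ammonia,
methylene, ketene, oxidation, fatty-acyl condensations C12–C24 at 0–6
double bonds, hexose/pentose/glucuronate, phosphate, sulfate, amino-acid
and steroid-backbone conjugations). Mass-difference lists are ordinary TSV
files; users studying other chemistries supply their own.

## Mass-defect feasibility

A peak is kept only if *some* CHNOPS+Na composition has a protonated m/z
within tolerance (default 1 ppm). This is decided exactly, not by a
nominal-mass envelope: two partial-mass tables ({N,O,P,S,Na} combinations
and {C,H} combinations up to 1000 Da) are enumerated once, sorted, and each
query becomes a vectorised two-table search for a sum within tolerance,
with results memoised at 10⁻⁴ Th granularity. An envelope of minimum /
maximum exact mass per nominal-mass bin was rejected during design: between
sulfur-rich and hydrogen-rich compositions the per-bin envelope spans
several Da and cannot exclude anything in the mid-mass range, whereas exact
enumeration leaves genuine gaps (e.g. no composition sits within 1 ppm of
m/z 150.50). Note that with unrestricted element counts the composition
space above ~300 Da is dense at 1 ppm, so on clean synthetic data the
filter is mostly a pass-through; its value is rejecting low-mass noise and
gross artefacts.

## Calibration

The interactive density-surface calibration of vendor tooling is replaced
by a deterministic equivalent with the same contract: reference masses are
matched within 2 ppm, a polynomial of degree ≤ 2 in m/z is fitted to the
ppm error (one 3-MAD trimming pass for robustness), and the correction is
applied multiplicatively. With fewer than 5 matches calibration is refused
and peaks pass through flagged. On synthetic spectra with smooth injected
error the residual SD is below 0.1 ppm under m/z 500, the regime the
instrument's spectra reach after manual kernel calibration.

## Alignment

Peaks pooled over samples are sorted by (m/z, intensity, sample) — keys
independent of input order, so alignment is invariant to sample order — and
clustered in a single greedy pass: a peak joins the current cluster while
it lies within the window (default 1 ppm) of the running intensity-weighted
consensus, otherwise it opens a new cluster. A sample contributing several
peaks to one cluster has them summed. The greedy pass is O(n log n) and, on
features separated by more than the window with sub-window jitter, agrees
with complete-linkage clustering at the same cut; disagreements are
confined to exact window-boundary geometries. Consensus drift can in
principle leave an early member slightly outside the window of the final
consensus; at the jitter levels of calibrated FT-ICR data (≤ 0.3 ppm) this
is negligible.

## Isotopologue removal

A feature is removed as a +1 ¹³C isotopologue when it sits one ¹³C–¹²C
spacing (1.0033548 Da) above another feature within 3 ppm and its raw
across-sample Pearson correlation with that candidate parent is ≥ 0.9
(pairwise-complete observations, minimum 3 shared samples). Parents are
always retained. Only the +1 peak is modelled; higher isotopologues and
fine structure are out of scope. Whether the removal runs is a config
switch (default on for both study designs).

## Missing data, imputation, transforms

Presence filtering keeps features observed in ≥ 10% of samples (all
boundary rules in the package are "keep if ≥"). Each remaining missing cell
is imputed as 0.9 × the feature's minimum observed intensity — a
left-shifted value reflecting that absence in DI-MS is usually censoring —
and intensities are then log₂-transformed (state-flagged so a double
transform is an error). For three-timepoint designs, per-subject response
matrices t₁−t₀ and t₂−t₁ are formed from log₂ values; subjects missing any
timepoint are dropped from *both* matrices so the two responses stay on one
subject set.

## Network annotation

Network arithmetic runs on neutralised masses under a single [M+H]⁺
hypothesis (m/z minus proton mass); sodiated species are expected to be
removed or targeted separately (the steroid-adduct prefilter handles the
targeted case). Edges are assigned per mass difference by a two-pointer
sweep over the sorted masses with the tolerance (default 0.1 ppm) evaluated
at the mean of the pair; the result is identical to the all-pairs scan.

Propagation is best-evidence-first: candidate assignments sit in a priority
queue ordered by |implied ppm error|, then m/z, then formula string, which
makes the outcome deterministic and independent of input order and tends to
let well-measured nodes anchor their neighbourhoods before poorly measured
ones. A candidate (neighbour formula ± the edge's formula delta) is
accepted only if every element count stays non-negative, the plausibility
rules pass, the implied mass is within the annotation tolerance (default
0.2 ppm), and it is consistent with every already-annotated neighbour. Each
rejection increments the node's failure counter; nodes exceeding 10
failures are discarded. The first accepted assignment for a node is kept —
with error-greedy ordering a later, worse candidate never overwrites a
better one.

The plausibility screen is the ratio/count/RDBE subset of the usual
heuristic filters: H/C ∈ [0.2, 3.1], N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3,
S/C ≤ 0.8 (applied when C > 1 — the windows are asymptotic heuristics and
misfire on single-carbon molecules such as methane or formic acid, which
the other rules already constrain), element-count maxima scaled linearly
with mass above 500 Da, and a ring-plus-double-bond equivalent
(C − (H+Na)/2 + (N+P)/2 + 1) that must be a non-negative integer — a
half-integer RDBE implies an open-shell species. Isotope-pattern rules are
deliberately absent: the pipeline removes isotopologues upstream, so no
envelope information survives to be tested.

Class assignment maps annotated formulas to a compound library by exact
formula match (modal class on collisions, alphabetical tie-break; no match
gives the generic "unassigned" label). The pipeline complements propagation
with direct library matching of feature m/z against [M+H]⁺ masses within
the alignment window, so nodes in small network components still receive
classes; propagated assignments win on conflict.

## PLS-DA and feature selection

Classes are coded +1 (risk/mutant) and −1 (control); features are
mean-centred and unit-variance scaled by default (a center-only switch
exists). R² is the fraction of class-coding variance explained in training;
Q² = 1 − PRESS/TSS over held-out predictions of a sevenfold stratified,
seeded cross-validation. The component count is chosen per fit by
maximising Q² over 1–5. Selection iterates: fit, rank by |coefficient|,
keep the top half (configurable), refit; the loop stops when an iteration
improves neither R² nor Q², and the final model is the last improving one.
The in-loop Q² is conditioned on the selection path and therefore
optimistic as an estimate of out-of-sample performance; on null data the
guard is empirical — permuted labels give mean Q² ≤ 0, and the type-I
checks below run the full loop. Replication-style selection is rule-based:
median immediate response higher in risk, median short-term response lower,
and an equal-variance two-sample t-test p < 0.1 in at least one response.
Tile-map statistics report, per feature, the risk−nonrisk mean difference
and equal-variance t-test p for t₀, t₁, t₂ and both responses, flagged at
p < 0.05.

## Enrichment

ORA is hypergeometric. For a class with K members among N reference
features and a selected subset, three tests are run: the subset overall and
its positive- and negative-coefficient parts (draws n, hits k), each
against the full reference. The default tail is the upper one,
P(X ≥ k) — the over-representation reading; the literal lower-tail variant
("k or fewer") is available by config. Raw p-values are reported by
default, mirroring common practice for this analysis; Benjamini–Hochberg
q-values are optional. The tissue-style analysis additionally restricts to
classes with reference count strictly greater than 40; the OGTT-style
analysis applies no size filter. The generic unassigned label participates
in universes and (for ORA) is tested like any class, but is never itself
tested in MDEA.

MDEA: per mass-difference type, the universe is that type's usable edges
(both nodes carrying a coefficient sign). The forward subset has
sign(source) < 0 and sign(target) > 0 — substrate consumed, product
accumulating; backward is the mirror. For each role and class the subset's
class hits are tested hypergeometrically against the type's universe.
Types with fewer than `mdea_min_edges` (default 5) usable edges are
skipped.

### Calibration of the ORA under the null

Two facts, established on simulated null studies, matter when reading ORA
p-values from this pipeline. First, features that are near-deterministic
functions of one another (an [M+Na]⁺ adduct rises and falls with its
parent) are selected together, which violates the independent-sampling
premise of the hypergeometric test and inflates rejection rates for
whatever label such satellites carry. Second, the iterative loop can end in
small final models, and with few draws the discrete hypergeometric test is
conservative — per-test rejection rates at the 0.05 threshold fall to
0.00–0.04 depending on where the nearest support atom sits (the exact
achieved level, computable from the hypergeometric cdf, ranges over
~0.01–0.05 across realistic universe/class/draw sizes). The calibration
test therefore checks the two-sided binomial band per class under
independent-feature nulls with exchangeable selection, and holds the
full-selection-loop route and the more-discrete signed sub-tests to the
no-inflation side of the band. In practice: treat marginal ORA p-values
near the threshold with care when the selected subset is small or when
adduct/isotopologue satellites may share a class label.

## Synthetic data

The generator emulates the statistical skeleton the analysis relies on,
per compound *k*, sample *s*:

log₂ intensity = baseline_k + subject intercept + sample offset +
genotype/timepoint shift + ε,

with baseline ~ U(18, 30) log₂ counts (the acquisition regime implied by a
1.5×10⁶-count floor at S/N 4 over a ~2¹⁶ noise floor), subject intercept
SD 0.5 log₂ units (so the multilevel step has between-subject variance to
cancel), sample offset SD 0.1, and measurement noise SD 0.2 log₂ units
(~15% CV, typical for direct-infusion replicates). Class-targeted effects
shift a configurable fraction of a class's members in the risk group at
chosen timepoints. Each compound emits an [M+H]⁺ peak; with configurable
probabilities it also emits a +1 ¹³C isotopologue (intensity = parent ×
0.0107 × carbon count, hence exactly correlated with the parent) and an
[M+Na]⁺ adduct (ratio ~ U(0.1, 0.5) with small independent noise). m/z
values carry Gaussian ppm jitter (default SD 0.05 ppm, the post-calibration
regime). Missingness is MCAR by default; a left-censored mode drops each
compound's lowest-intensity fraction for stress tests. Everything is
deterministic given the design seed, and a ground-truth table traces every
emitted peak identity.

Study shapes mirror the two designs the pipeline serves: a two-genotype
single-timepoint adipose design (default 10 per group, one sex, one depot)
and a two-genotype three-timepoint OGTT plasma design (default 25 per
group, t₀/t₁/t₂ per subject). Compound libraries are drawn from class-
typical composition recipes (steroids C17–C30 with few oxygens and RDBE
4–8, fatty acyls CnH(2n−2d)O₂, oxygen-rich low-RDBE sugars, …), screened by
the same validity rules the annotator uses and deduplicated at 6-decimal
mass precision; a 280-compound library generated this way ships with the
package (synthetic stand-in for a curated compound database). A separate
helper grows *reaction-connected* formula sets by repeatedly applying
listed mass differences to existing members — by construction these form a
connected MDiN at exact masses, the right substrate for propagation
recovery tests.

Not emulated: chromatography/retention, detector transients and Gibbs
sidelobes, isotope envelopes beyond the +1 peak, multiply charged ions,
intensity-dependent mass error, and between-batch drift. Passing recovery
tests on these data shows the chain's logic is correct under its stated
assumptions; it does not certify performance against matrix effects or
calibration pathologies real spectra can show.

## Problem sizes in the test suite

The suite exercises the chain at desk scale, chosen to finish in minutes
while keeping every statistical check in its informative regime: oracle
equivalence of the network builder on 50 instances × 300 features;
propagation recovery on ten 100-compound connected networks (0.02-ppm
jitter, 5 seeds each); isotopologue recovery on 20 simulated studies;
permutation nulls with 100 label permutations; selection recovery at
2000 features / 5% informative / 25 subjects per class over 20 seeds;
end-to-end OGTT recovery at 25 subjects per group × 3 timepoints × 210
compounds over 20 seeds; and 200-replicate null calibration at 700
compounds. The cohort-scale feature counts and model statistics of a real
study depend on raw data this package does not ship and are out of scope.
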