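# Methods

This note documents the models and procedures implemented in `geoseek`,
the assumptions behind the synthetic data generator, the numerical
choices, and the limits of what the synthetic results demonstrate.

## Study design

The pipeline reconstructs, on synthetic data with known ground truth, an
analysis that predicts future medical-facility visits from geotagged
search logs and evaluates the predictions through advertising
show-conversion metrics.  A *patient* is a user whose log ends in an
inferred facility visit with at least 42 distinct search days of prior
history; a *control* is a user with no inferred visit, matched on
search-day count.  Each user contributes an analysis window of exactly 41
search days (calendar dates with ≥ 1 search) strictly before an endpoint:
the first visit date for patients, a seeded random date for controls.
The endpoint day itself is excluded; day buckets are indexed 1..41 from
the endpoint backward.

Two inclusion/exclusion ambiguities were resolved as follows and are
exposed as configuration:

* The endpoint is the **first** retained visit (`GeofencePolicy.endpoint`
  switches to "last").  The generator plants exactly one visit per
  patient, so the two coincide in synthetic worlds.
* The monthly proximal-search cap counts searches near **any** facility,
  using the same 200 m radius as visit detection; "month" is the
  calendar month of the timestamp at a single configured UTC offset.

## Visit detection

A candidate visit is a maximal run of one user's time-ordered searches
all within `radius_m` (200 m) of the same facility, uninterrupted by an
out-of-fence search and with ≤ 6 h between consecutive members (the gap
cap prevents phantom dwells spanning sleep periods; visit runs in
real logs rarely pause longer).  Dwell time is last minus first
timestamp; runs dwelling < 900 s are discarded.  Distances are
great-circle (haversine) on a sphere of 6 371 000 m, under which 1e-4
degrees of latitude is ≈ 11 m — the precision kept when coordinates are
rounded to four decimals for landmark resolution.

## Features

**General (daywise)** — number of searches; number of health-related
searches (any token mapping to a *disease*, *drug*, or *procedure*
concept — the device group is excluded, see "Semantic groups" below);
mean session duration under 30-minute-inactivity sessionization (theme
linkage between consecutive searches would need result-page data that
logs do not carry); mean token count of search texts; and the interval
reduction score.

**Interval reduction score.**  For a day's health-related searches at
sorted times with intervals Δ₁..Δₙ₋₁,

    IRS = (1/(n−2)) Σᵢ [ w + (1−w)·Δᵢ₊₁/Δᵢ ],  n ≥ 3;   IRS = 1 for n ≤ 2.

The exact published formula for this statistic is not machine-readable
in the source material; this form is the simplest satisfying every
stated property — exactly 1 for ≤ 2 searches, exactly 1 at constant
intervals, < 1 under interval shortening, > 1 under lengthening, with
the weight `w` (default 0.1, "small values close to 0.1") damping
extreme ratios.  Each ratio is clamped to [0.01, 100] so that zero or
enormous intervals cannot dominate; a 0/0 ratio counts as neutral (1).

**Semantic (daywise + aggregate)** — per-day counts of searches whose
tokens map into each of the four semantic groups (one search may count
in several groups); daywise search specificity; and counts of enriched
tokens.

*Information content.*  Concepts form a rooted DAG; IC(c) =
−ln(n(c)/n(root)) with n(c) the concept's corpus count plus all
descendants' counts.  Since a descendant's descendant set is contained
in its ancestor's, IC is monotonically nondecreasing along every
root-to-leaf path.  Natural log is used (any base is order-preserving).
A day's specificity is the maximum over its searches of each search's
most-specific-term IC (the mean of per-search maxima is available via
`FeatureConfig.specificity_mode`); days without a mapped term score 0.

*Enriched tokens.*  Two screens on training users only: (1) per token, a
two-sided Fisher exact test on patients-ever-using vs controls-ever-using;
(2) the same test at day level (user-days using the token, each user
contributing 41 days), which catches tokens whose *frequency* of use
rather than mere presence differs.  The source analysis names only "a
Fisher test with Bonferroni correction" for the presence screen and
describes the second as a term-frequency comparison without naming a
test; reusing the same machinery on day-level units is this package's
choice.  Both are Bonferroni-corrected over the tokens tested; the union
is ranked by the smaller adjusted p (ties: larger |log odds|, then token
id) and the top `n_enriched_tokens` (default 100) kept.  At toy cohort
sizes fewer than k tokens typically reach significance; the selection
then returns all significant tokens and flags the shortfall.

*Semantic groups and the device exclusion.*  Lexicon-based group
mapping misattributes common non-medical words to medical concepts, and
device-group mappings are the noisiest.  `categorization_agreement`
reproduces the diagnosis: segregate searches health/non-health by group
membership and compare with ground-truth labels; dropping the device
group improves agreement whenever the generator plants device-term
misattribution (`device_noise_rate` > 0).  Accordingly, health-related
search counts use disease/drug/procedure only, while the four per-group
count features retain all groups.

**Location (daywise + aggregate)** — each search's coordinates are
rounded to 4 decimals, resolved once per unique pair to the 10 closest
landmarks ranked by great-circle distance, and labeled with the nearest
landmark's category and name.  Daywise counts are kept for enriched
landmark categories (default k = 53) and window-level 0/1 indicators for
enriched location-name word tokens (default k = 113); both selections
reuse the token enrichment machinery, since the source states the
set sizes but not the selection procedure.

Matrices: the daywise matrix has 41 × (5 general + 4 group counts + 1
specificity + |tokens| + |categories|) columns plus the label; the
aggregate matrix holds the window totals/means of the same quantities
(IRS is daywise-only) plus the name-token indicators.  Columns carry
category tags (general/semantic/location) for the ablation.  No feature
of one user depends on another user's records, and only strictly
pre-endpoint records are visible to the feature engine.

## Models and evaluation

Learner internals come from scikit-learn; the module owns the protocol.
The 80/20 split is user-level and stratified (stratification is a
package choice; it is configurable).  Lasso/ridge/elastic-net logistic
models are tuned by 5-fold stratified CV of binomial deviance over a
50-point log-spaced lambda path descending from the null-model gradient
bound; the one-SE rule picks the *largest* lambda within one standard
error (over folds) of the minimum, so chosen penalization is never
weaker than the minimizer.  Elastic net grids over
α ∈ {0.1, 0.3, 0.5, 0.7, 0.9}.  The optimizer differs from the R glmnet
path algorithm but the protocol (folds, path, 1-SE) is the same.  The
SVM uses an RBF kernel with γ = 1/(number of features) and a CV-chosen
cost from {0.1, 1, 10, 100}; random forests use 200 trees (no tuning).

ROC curves sweep thresholds over distinct scores (tied scores move
together, equivalent to rank-averaged ties); AUC is the trapezoid area
and equals the Mann–Whitney statistic U/(n₁n₀), which the tests assert
against `scipy.stats.mannwhitneyu`.  Multiclass performance uses the
Hand–Till measure — the mean over unordered class pairs (i, j) of
[A(i|j) + A(j|i)]/2, each term a binary AUC on the pair's samples —
which reduces exactly to the binary AUC for two classes; accuracy is
plain argmax fraction-correct.  The ablation refits the same family on
the same split three times, each with one tagged category's columns
removed.

## Ad evaluation

A user converts when some impression from facility F is followed by a
visit to F within 14 days ("2 weeks"), and the user had no visit to F in
the 30 days ("1 month") before that visit.  Windows are fixed-length in
seconds on timestamps.  The local show conversion rate at rank r of the
score-ranked population is the mean conversion flag in the T-person
window centered at r, truncated at the ends (when T ≥ population, every
local rate equals the global rate); the curve is indexed by score
percentile.  The exact published formula for the local rate is likewise
not machine-readable; the implementation follows the verbal definition.
T has no published production value and is a required configuration
parameter (default 101 in `ConversionPolicy`).  Scores map to bid
coefficients linearly, 0.7 + 0.6·score, onto the stated (0.7, 1.3)
interval; any monotone map is pluggable.  A/B comparisons report
100·(B−A)/A for the show conversion rate (converted impressions /
impressions) and CPA (total cost / conversions); zero conversions in
either arm makes CPA undefined and is flagged, not imputed.  Ties in
score rank are broken by user id for determinism.

## The synthetic generator

The real logs this analysis was designed for are proprietary, and no
distributional facts about them (searches/user/day, dwell times, token
frequencies) are published; all generator defaults are therefore free
parameters chosen once as plausible for mobile search behavior and
documented here:

* 60 days per user, Poisson(3) searches/day between 08:00 and 23:00,
  15% of searches health-related at baseline; filler vocabulary of 600
  Zipf(1.1)-weighted tokens, 1 + Poisson(1.2) filler tokens per search.
* toy lexicon of 200 terms over a rooted concept DAG (4 group subtrees,
  occasional second parents, 8% of drug concepts also tagged procedure);
  a child concept's corpus frequency is a U(0.15, 0.7) fraction of its
  parent's, which enforces the ancestor ≥ descendant frequency
  invariant edge by edge.
* patients' latent risk ~ Beta(5, 2), controls' ~ Beta(2, 5); each
  planted signal ramps linearly (the simplest monotone shape; no
  functional form is published) over the final 15 search days before
  the visit, scaled by risk: health-search rate ×2.5, interval
  shortening ×2 (escalated days with ≥ 3 health searches become bursts
  with geometrically contracting intervals), specificity drift ×1.5
  (term sampling reweighted by m^IC and mixed with a small per-specialty
  high-IC signature set — patients converge on their actual condition's
  terms), health-landmark search origin odds ×3.
* every patient ends in exactly one visit: three searches spanning
  1000 s inside one facility's fence (multiple visits would add nothing
  to the tested surface); controls' homes and outing landmarks are kept
  ≥ 500 m from every facility so no control can enter a fence.
* terms the lexicon wrongly maps to medical concepts (`device_noise_rate`
  of device-only terms) are ordinary words and appear in everyday
  searches of all users — the mechanism behind the device-group
  agreement experiment.
* ad impressions are Poisson per user with lognormal(μ=1, σ=0.5) costs;
  P(visit within 14 days) = 0.02 + 0.25·risk, an increasing function of
  latent risk.

Outside the final 15 days (and the visit day), patients and controls are
generated by the *identical* process, so features restricted to earlier
days carry no class signal — asserted by the chance-level AUC of models
trained on days 16..41 only.  Setting every effect size to 1 makes the
classes distributionally identical on all non-visit days (asserted by
Kolmogorov–Smirnov over 50 seeds).

## What passing tests do and do not show

The generator plants exactly the signals the features were designed to
detect, with clean geometry, a tiny lexicon, one visit per patient, and
no confounding mobility structure.  Passing parameter-recovery tests
therefore shows that the pipeline's machinery is correct and can recover
known signals at realistic desk-scale sample sizes — not that the
features would discriminate on real logs, where signal strength,
vocabulary size, location noise, and class imbalance are all far less
favorable.  Published real-data headline numbers (test AUCs, conversion
changes) are not reproduction targets; the suite targets directions and
invariants instead: daywise features beat aggregates, the dominant
planted category's ablation hurts most, the conversion curve is monotone
when conversions track risk, and dropping the device group improves
agreement under planted misattribution.

## Numerical choices and degenerate inputs

* IRS ratio clamp [0.01, 100]; 0/0 intervals neutral; negative times
  rejected.
* Fisher log odds use Haldane's +0.5 correction for ranking only.
* Stratified folds and splits round per class to the nearest user.
* Lambda path floor `1e-3 · λ_max`; λ_max from the max absolute
  null-model gradient scaled by the ℓ1 mixing weight (0.5 for ridge's
  grid, which only shifts the grid, not the chosen model's family).
* Empty search days cannot occur inside windows (windows are built from
  search days); days with no *health* searches score IRS 1 and
  specificity 0; users with fewer than 41 qualifying days raise a typed
  error rather than producing short windows.
* All randomness flows from per-stage seeds hash-derived from one global
  seed, so no stage's draw count can perturb another stage.

## Problem sizes

The test suite exercises the full pipeline at 500 patients + 500 matched
controls (~180 k searches) for parameter recovery, 150 + 150 for the
location-dominant ablation, 125 + 125 (train) / 150 + 150 (score) for
the null-cohort conversion-curve check, 5000 scored users for curve
shape, and 20 seeded replicates for the device-group direction — sizes
chosen to give each property comfortable statistical power on one CPU.

## Known limitations

* Search text is a bag of tokens; no real-language structure,
  segmentation, or translation is modeled.
* Mobility is home + jitter + landmark outings; no trajectories or road
  networks, and sub-facility localization is a pass-through tag.
* The IRS and local-rate formulas follow stated verbal properties, not
  a published closed form (none is machine-readable).
* The A/B stage demonstrates plumbing on synthetic arms; it makes no
  causal claim — establishing causality between ad display and visits
  is explicitly out of scope.
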