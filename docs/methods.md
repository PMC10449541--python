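# Methods

## Data model

A food is its per-100 g (solids) or per-100 mL (liquids) composition in the
nine variables energy (kcal), protein (g), total lipids (g), saturated fat
(g), cholesterol (mg), carbohydrates (g), sugar (g), fiber (g), sodium (mg).
Before analysis the two aggregates are decomposed,

    carbohydrates = starch + sugar + fiber
    total lipids  = unsaturated + saturated fat,

yielding the fixed 9-component vector (energy, protein, unsaturated fat,
saturated fat, cholesterol, starch, sugar, fiber, sodium) used everywhere.
Starch and unsaturated fat are derived by subtraction when not given
explicitly; negative derived values (small inconsistencies are common in
published composition tables) are clipped to 0 and logged, never fatal.
Missing values in the nine mandatory columns are imputed as 0 and logged —
a nutrient left off a label is treated as absent.  Blank *optional* columns
(starch, trans fat, free sugar) mean "not provided": starch is then derived
and trans-fat rules are skipped, which also makes write/read round-trips
bit-identical.  Units are fixed (kcal, g, mg); no automatic conversion.

## Dimensionless transform

Nutrients live on incomparable scales, so each column j of an N-food table
is rescaled by its mean: x̄_ij = N·x_ij / Σ_i x_ij.  Every non-degenerate
column then has mean exactly 1 (asserted to 1e-9 in tests); all-zero columns
map to zeros and are flagged degenerate rather than raising, since small
tables legitimately zero out a nutrient.  The fitted column sums are frozen:
new foods are projected with the reference sums, never re-fitted, so
classifying one food cannot move the space.  The transform is positively
homogeneous (scaling a food scales its image), which is what makes cosine
similarity a concentration comparison.

## Similarity, equivalence factor, blends

Similarity is the cosine of the angle between dimensionless vectors, clamped
to [0, 1] against floating-point overshoot (nonnegative vectors cannot have
negative cosine).  The equivalence factor α = ⟨A,B⟩/|B|² is the closed-form
least-squares coefficient of A on B; 100·α g of candidate B exchanges for
100 g of target A.  α is computed in dimensionless space, where units
cancel; because dimensionless and raw α generally differ (the raw fit is
dominated by the large-unit columns), the raw-space value is reported
alongside (`alpha_raw`/`grams_raw`) and the dimensionless one is primary.
Ranking candidates sorts by similarity descending with ties broken by stable
input order; the target is excluded by name, so an exact duplicate under a
different name is retained as a legitimate equivalent.

The two-food blend C ≈ αA + βB is solved by the 2×2 normal equations with
α, β ≥ 0 enforced by an active-set fallback (the better of the two single-
food boundary fits).  Nonnegativity is imposed because negative food amounts
are physically meaningless.  Near-parallel A, B (Gram determinant below
1e-12 of its scale) raise a degeneracy error pointing at the single-food
factor.  No n > 2 mixtures are attempted.

## Classifiers

**Centroid (spherical-k-means) classifier.**  Labels are known, so centroid
placement is supervised: centroid W_j is the group's mean dimensionless
vector normalized to unit length; no iterative reassignment.  Prediction
ranks groups by cosine similarity, ties broken by centroid (first-
appearance) order.  Equivalent to a single-layer linear network with
unit-norm weight rows and no activation.

**MLP.**  Relaxing those constraints gives a feed-forward classifier on a
10-feature input: the 9 dimensionless components plus the vector's Euclidean
magnitude, restoring the amount information the transform discards.  The
magnitude is taken from the *dimensionless* vector (that is the space where
the information was lost); a `magnitude_source="raw"` switch exposes the
raw-norm alternative.  Default topology 10 → 32 → 32 → #groups, rectifier
hidden units, softmax output, cross-entropy loss, adam with learning rate
0.01, 300 epochs; two hidden layers are fixed by design, the widths and
optimizer settings are exposed configuration.  Training uses scikit-learn's
`MLPClassifier` driven one epoch at a time (`partial_fit`) so the train and
internal-validation (stratified 80/20) cross-entropy is logged per epoch;
the run is bit-deterministic given the seed.  Groups too small to stratify
raise an explicit error.

**Evaluation.**  Top-k accuracy is the fraction of foods whose true group
ranks within the k best-scored candidates; under ties the true rank is 1 +
the number of strictly better scores.  Stratified k-fold cross-validation
(default 5 folds) refits the dimensionless scale *and* the model on each
training portion only — validation-fold statistics never leak.  Groups with
fewer members than the fold count are pooled into an `"other"` stratum with
a warning.  Off-the-shelf classifiers (random forests, gradient boosting)
plug into the same harness through a callable adapter returning a
scikit-learn-style estimator; they are deliberately not re-implemented.

## Warning labels

Inclusive (≥) cut points per 100 g / 100 mL: solids ≥ 275 kcal or liquids
≥ 70 kcal (or ≥ 8 g free sugar — the clause is attached to the *calorie*
label, as the liquid row of the regulation prints it) for excess calories;
free sugars ≥ 10% of energy (4 kcal/g) for excess sugars; saturated fat
≥ 10% and trans fat ≥ 1% of energy (9 kcal/g, Atwater factors — the
regulation states the shares, the package supplies the factors); sodium
≥ 1 mg/kcal or ≥ 300 mg, with a 45 mg cut for calorie-free drinks (liquids
under 5 kcal/100 mL — the defining threshold is a package choice, exposed in
the rule set).  Free sugars default to the total-sugar column with a logged
caveat when no free-sugar column exists.  Zero-energy foods skip the
share-based rules (noted in the evidence) but keep the absolute ones.  Every
label decision records the computed quantity and threshold used.

## Portions

Each of the eight standard groups has a reference food and a key nutritional
component (vegetables 4 g carbohydrate, fruits 15 g, cereals 15 g, legumes
8 g protein, meats 7 g, milk 9 g protein with 12 g carbohydrate reported as
secondary, fats 5 g fat, sugars 10 g carbohydrate).  The portion is
100·key_amount/density grams; high-moisture foods (fruits, vegetables,
animal foods, dairy, cooked cereals/legumes) round to the nearest multiple
of 5 g with halves up (32.5 → 35), dry or raw foods keep exact grams.  The
moisture class is caller-supplied (or taken from the category map), since
the classes are defined by example, not rule.  A portion is acceptable when
the delivered key amount is within ±2 standard deviations of the group
target; the per-group SD is computed from the supplied table at run time and
the check is advisory.  Household measures (cup 240 mL, tablespoon 15 mL,
teaspoon 5 mL) are display text; grams are authoritative.

## Synthetic data

The generator emulates the *separation structure* of a real exchange-list
database — each of the 19 categories has a well-defined profile dominated by
its defining nutrients (high sugar for the sugar groups, high protein/low
fat for very-low-fat meats, ~zero energy for free-energy foods).  The
profile means are invented, nutritionally plausible per-100 g values; they
are **not** derived from any published database, and no attempt is made to
match a real database's distributions.  Foods are drawn as
mean ⊙ (1 + noise_scale·cv·ε) with ε ~ N(0,1) per component (NumPy PCG64,
seeded), clipped at 0; multiplicative noise keeps zero-mean components
exactly zero, preserving group sparsity.  The default per-component
coefficient of variation is 0.6, a typical within-group relative spread for
composition data; raw aggregates are reconstructed from the drawn
sub-nutrients so feature expansion inverts the generator exactly.

Consequently, passing tests on synthetic data demonstrate the machinery
(normalization, ranking, refit hygiene, determinism) — not field accuracy.
Real composition databases have heavier tails, correlated nutrients,
mislabeled rows and overlapping subgroup boundaries; accuracies measured
here (near-perfect at the default noise) overstate what any real table
yields, and the classifier must be refitted to a real labeled table before
use.

## Problem sizes and numerics

Default experiment sizes — 19 groups × 50 foods, 5 CV folds, 300 MLP
epochs, 1000-pair optimality sweeps on a 2001-point grid — run in seconds on
one CPU and are the sizes `scripts/acceptance.py` reports.  Tolerances:
column-mean invariant 1e-9; blend recovery 1e-6 with residual 1e-9;
parallelism guard 1e-12 relative; cosine clamped to [0, 1].  Ranking and
tie-breaks are everywhere resolved by stable order for determinism.

## Known limitations

* Group assignment uses nutrient composition only; foods of different
  culinary origin with similar composition are indistinguishable.
* The liquid free-sugar clause placement and the calorie-free threshold
  follow one reading of an ambiguous regulation layout (documented above).
* Milk's portion is solved on protein only; the carbohydrate target is
  reported, not reconciled.
* The built-in reference table used when a pipeline input is unlabeled is
  synthetic; supply a real labeled reference for real use.
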