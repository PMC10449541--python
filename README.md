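# felkit — food exchange list toolkit

Food exchange lists (FELs) group foods into categories — fruits, cereals,
meats of different fat contents, dairy, fats, sugars — within which stated
portions are nutritionally interchangeable.  Dietitians use them to build
meal plans for patients with diabetes, obesity and other metabolic disease,
but assigning every new product to a group and computing its exchangeable
portion is a manual, resource-intensive task.  `felkit` automates it from an
ordinary food-composition table (per-100 g nutrient values).

## Method

Each food is a 9-component nutrient vector — energy (kcal), protein,
unsaturated fat, saturated fat, cholesterol (mg), starch, sugar, fiber,
sodium (mg), with carbohydrates and total lipids expanded into their
sub-nutrients.  The table is made dimensionless column by column,

```
x̄_ij = N · x_ij / Σ_i x_ij
```

so every nutrient column has mean 1 and units cancel.  On these vectors:

* **Similarity** between foods A and B is the cosine
  `Sim(A,B) = ⟨A,B⟩ / (|A||B|)` — a comparison of nutrient concentration
  profiles, not amounts.
* **Equivalence factor** `α = |A| cos θ_AB / |B| = ⟨A,B⟩/|B|²` is the
  least-squares multiple of B that approximates A: 100·α g of B exchanges
  for 100 g of A.  A two-food blend `C ≈ αA + βB` is solved by nonnegative
  least squares.
* **Classification** places one unit-norm centroid `W_j` per exchange group
  (the group's mean dimensionless vector, spherical-k-means style) and
  assigns `argmax_j Sim(A, W_j)`; an MLP with two hidden layers, trained on
  the 9 dimensionless components plus the vector magnitude, smooths the
  centroid classifier's linear boundaries.  Both return full rankings, so
  accuracy can be read at the top-1/top-2/top-3 level.
* **Portions**: every group has a key nutritional component (e.g. 15 g
  carbohydrate per fruit portion, 7 g protein per meat portion); the
  equivalent portion is `100 · key_amount / density`, rounded to the nearest
  5 g for high-moisture foods.
* **Warning labels**: foods are flagged against the Mexican NOM-051 cut
  points for excess calories, sugars, saturated fat, trans fat and sodium.

A synthetic-data module generates labeled tables from 19 group-specific
nutrient profiles so the whole pipeline is testable without any database
download.

## Worked example

```
$ felkit simulate --n 20 --seed 7 --out foods.csv
wrote 380 foods in 19 groups to foods.csv

$ felkit equivalents --food "Fruits #3" --table foods.csv -k 3 --same-group --out eq.json
Fruits #12: similarity 0.9999, alpha 0.874 (87.4 g)
Fruits #13: similarity 0.9998, alpha 0.975 (97.5 g)
Fruits #10: similarity 0.9997, alpha 0.946 (94.6 g)
```

87.4 g of "Fruits #12" contributes nearly the same nutrient profile as
100 g of "Fruits #3" (cosine similarity 0.9999).

```
$ felkit classify --table foods.csv --model skm --top 3 --out cls.json
{
  "top1": 1.0,
  "top2": 1.0,
  "top3": 1.0
}

$ felkit portion --food "Fruits #3" --table foods.csv --group Fruits --out p.json
Fruits #3: 105.0 g delivers 14.85 g carbohydrates
```

The centroid classifier recovers every group label on this table, and a
105 g portion of the fruit (rounded to the nearest 5 g) delivers its
group's 15 g carbohydrate key amount to within the rounding error.
`felkit label` and `felkit pipeline` add the excess-nutrient flags and the
combined per-food report; `felkit evaluate` runs stratified k-fold
cross-validation, with an adapter seam for off-the-shelf classifiers
(random forests, gradient boosting) next to the built-in ones.

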