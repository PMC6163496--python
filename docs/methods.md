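# Methods

## Model and guarantee

The predictor is a Mondrian (class-conditional) inductive conformal
classifier over two classes, M (mutagenic, positive) and NM (nonmutagenic).
The conformity score of a compound for a hypothesized class is the predicted
class probability of a random forest — the fraction of trees voting for that
class — fitted on the proper training set. Calibration scores are collected
per true class: `scores_M` holds the class-M probabilities of true-M
calibration compounds, `scores_NM` the class-NM probabilities of true-NM
compounds. For a new compound with score *s* against a calibration list of
size *n*,

    p = #{ s_i < s } / (n + 1),

i.e. the new compound joins the list and the p-value is the fraction of the
augmented list strictly below it; ties are not counted as lower. The
prediction set at significance ε is `{c : p_c ≥ ε}` (boundary inclusive),
giving four outcomes: one class, the other, *both*, or *empty*.

Assumption: exchangeability of calibration and test compounds within each
class. Under it, the per-class probability that the true class is excluded
is controlled at ≈ ε, independently of how good the forest is — model
quality affects *efficiency* (how many single-label predictions are made),
not validity.

### Numerical properties of the p-value rule

The rule is the published rank formulation, kept exactly. Two consequences
are worth stating:

- **Discreteness.** p-values live on the grid k/(n+1); the error rate at
  level ε is really ceil(ε(n+1))/(n+1), within 1/(n+1) of ε. With the
  default calibration size (~131 per fold) this is < 0.008.
- **Ties.** Forest probabilities lie on the 1/n_trees grid, so exact ties
  between a test score and calibration scores occur. Excluding ties from
  the "lower" count shrinks p-values slightly, making the rule marginally
  anti-conservative relative to the textbook `(#{≤} + 1)/(n+1)` variant —
  empirically one to two validity points at desk scale, well inside the
  Monte-Carlo band the tests use. At saturating signal (many scores exactly
  1.0) the same effect produces *empty* predictions for highly confident
  compounds; the signal→efficiency monotonicity test therefore probes the
  unsaturated regime. The smoothed tie-breaking variant is deliberately not
  implemented, to keep the predictor deterministic and the rule faithful.

## Validation protocol

Each repetition r (default 50; the heavy tests and the acceptance script use
10 to stay desk-scale):

1. unstratified random 70/30 split into training and external test, with the
   test size `floor(0.30 · N)` (936 → 656/280);
2. the training set is shuffled once and cut into 5 near-equal blocks; fold
   k calibrates on block k (~20%) and fits the forest on the rest, so every
   training compound calibrates exactly once;
3. each fold scores the full external test set; the five per-fold p-values
   per compound and class are combined by their **median** (mean available
   via `aggregation="mean"`). The median is the conventional cross-conformal
   combination and keeps the aggregate on a coarse rank grid; cross-conformal
   validity is approximate rather than exact, which the validity simulations
   confirm empirically;
4. each fold also draws an 80/20 internal train/test split of its proper
   training set, fits a second forest on the internal-train part, calibrates
   it on the *same* fold calibration block (one draw per fold), and scores
   the internal test set; internal records are pooled across folds.

Splits are unstratified by default (a `stratify` flag exists on
`split_external`). Seeds: repetition r derives an order-insensitive
`SeedSequence` from `(base_seed, r)` with separate children for the split,
the fold partition and each fold's forests, so any repetition is
reproducible in isolation and results are invariant to execution order.

## Evaluation calculus

Per class, validity = (correct single labels + *both*) / class size; *empty*
and wrong single labels are errors. Efficiency, *both* and *empty* fractions
partition the records exactly. The 2×2 confusion table uses single-label
predictions only (M positive) — *both* and *empty* have no place in it — and
that exclusion is applied to *all* confusion-derived metrics: sensitivity,
specificity, balanced accuracy, Cohen's κ (po, pe from the counts), Matthews
correlation, FN:FP ratio. Zero denominators yield NaN, never 0.

The sweep report computes every metric per repetition and averages across
repetitions (NaN-skipping); confusion counts are reported as means and the
FN:FP ratio is taken from those mean counts, matching how pooled averages of
counts are conventionally summarised. Whether κ/MCC are averaged
per-repetition or computed from pooled counts was an open choice; the
per-repetition mean was adopted for consistency with the other columns.

## Synthetic data

The generator emulates the shape of the proprietary aromatic-amine screening
set: 936 compounds, 630 M / 306 NM (2.06:1), D = 200 binary features. D is a
deliberate compromise — the real descriptor dictionaries (27,000 generic
substructures, or 157 curated alerts) are proprietary, and 200 bits is large
enough for realistic forest behaviour yet small enough for fast tests.
Twenty "activating" bits fire with probability 0.30 in class M and 0.05
otherwise; ten "deactivating" bits are symmetric for NM; the remaining 170
fire at the 0.05 background rate in both classes. The 2:1 activating:
deactivating count mirrors a structural-alert regime where positive alerts
outnumber mitigating features, and the 0.30/0.05 rates give a forest that is
informative but far from separable — efficiencies in the 0.70–0.90 range
over ε ∈ [0.15, 0.30], comparable to what fingerprint models achieve in
practice.

Rows are i.i.d. given the label, hence exchangeable within class — exactly
the hypothesis of the validity theorem. What passing tests show is therefore
that the *machinery* delivers its guarantee under its stated assumption;
they do not show that real fingerprint data (correlated bits, activity
cliffs, assay noise, non-exchangeable batches) would achieve the same
efficiency, and absolute benchmark values from proprietary data are not
reproduced here. Bit correlations are not modelled: no public statistics of
the real descriptors exist to emulate, and validity does not depend on them.

`generate_record_fixture` builds prediction records realizing requested
(true label, label set) outcomes exactly — included classes get
p = ε + (1−ε)/2, excluded ones p = ε/2 — used to unit-test the evaluation
calculus against hand-computed values.

## Problem sizes and tolerances

The validity simulation in the test suite and the acceptance script runs 10
repetitions of the full protocol on the default 936 × 200 dataset with
100-tree forests — 100 forest fits, a couple of minutes on one CPU — and
checks mean per-class external validity ≥ 1 − ε − 2·SE with SE the standard
error across repetitions. Other tests run at reduced scale (150–240
compounds, 25–50 trees) since they probe exact arithmetic or invariants, not
statistical power. Equality checks on p-values are exact (the quantities are
small integer ratios); the p-value implementation is verified against an
independent insert-sort-count oracle on 1,000 random tied instances, and
κ/MCC against scikit-learn's implementations on reconstructed label vectors.

## Known limitations

- Cross-conformal median aggregation carries no finite-sample proof of
  validity; the guarantee is checked empirically.
- The strictly-lower tie rule is marginally anti-conservative (above) and
  can produce *empty* sets for compounds the forest is most confident about
  when scores saturate at 1.0.
- Underlying-classifier abstention (trees whose leaf cannot vote) is not
  modelled; probabilities come from scikit-learn's probability interface,
  which always votes.
- No chemistry: SMILES/SDF parsing, fingerprint computation and feature
  curation are out of scope; the input contract is a labeled binary CSV.
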