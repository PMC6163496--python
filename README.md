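# amescp — Mondrian cross-conformal prediction for mutagenicity classification

`amescp` implements set-valued binary classification of compounds as
mutagenic (M) or nonmutagenic (NM) from binary molecular fingerprints, for
QSAR modellers who need predictions with a *guaranteed* error rate rather
than a bare point estimate. It targets the Ames-mutagenicity setting —
e.g. primary aromatic amines screened during drug development — where a
false negative can compromise safety and a false positive triggers
unnecessary testing.

## The method

A 100-tree random forest is fitted on a *proper training set*; the fraction
of trees voting for a class is used as the conformity score of a compound
for that class. Calibration is **Mondrian** (class-conditional): the scores
of true-M calibration compounds form one sorted list, those of true-NM
compounds another. A new compound with score *s* for class *c* receives the
conformal p-value

```
p_c = #{ s_i in calibration_c : s_i < s } / (n_c + 1)
```

(the new compound joins the list; ties do not count as lower), and its
prediction set at significance level ε is `{c : p_c ≥ ε}` — a single class,
**both** classes, or the **empty** set (a compound outside the model's
applicability domain). Under exchangeability the per-class error rate is
controlled at ≈ ε, which is the *validity* guarantee; *efficiency* is the
fraction of compounds receiving exactly one label.

Validation follows a repeated cross-conformal protocol: 50× random 70/30
training/external-test splits; each training set rotated through 5 folds so
every training compound serves once in a ~20% calibration block; the five
per-fold p-values of each external compound aggregated by their median; and
per fold an 80/20 internal train/test split scored the same way. Reported
metrics — per-class validity, efficiency, both/empty fractions, sensitivity,
specificity, balanced accuracy, Cohen's κ, Matthews correlation and the
FN:FP ratio (computed over single-label predictions only, M positive) — are
averaged across repetitions in a significance-level sweep.

The curated aromatic-amine dataset such studies use is proprietary, so the
package ships a generator of exchangeable synthetic fingerprint data with the
same shape (936 compounds, 630 M / 306 NM ≈ 2.06:1, sparse binary bits of
which a few are class-informative), on which every stage of the pipeline —
including the validity guarantee itself — is testable.

## Worked example

```python
>>> from amescp import conformal_p_value, assign_label_set
>>> cal_M  = [0.10, 0.20, 0.35, 0.40, 0.55, 0.60, 0.80]   # true-M calibration scores
>>> cal_NM = [0.55, 0.58, 0.61, 0.70, 0.80, 0.90, 0.95]   # true-NM calibration scores
>>> conformal_p_value(0.73, cal_M)    # 6 of 7 scores below 0.73 -> 6/8
0.75
>>> conformal_p_value(0.27, cal_NM)   # no score below 0.27 -> 0/8
0.0
>>> sorted(assign_label_set(0.75, 0.0, significance=0.20))
['M']
```

The compound is accepted as mutagenic (0.75 ≥ 0.20) and rejected as
nonmutagenic (0.0 < 0.20): a single-label prediction. Had both p-values
cleared 0.20 the set would be *both*; had neither, *empty*.

End-to-end on synthetic data (10 repetitions, default 936-compound shape):

```python
>>> from amescp import SyntheticConfig, SplitPlan, generate, run_experiment, build_sweep_report
>>> dataset = generate(SyntheticConfig(seed=42))
>>> results = run_experiment(dataset, SplitPlan(n_repetitions=10, base_seed=1))
>>> report = build_sweep_report(results, [0.15, 0.20, 0.25, 0.30])
```

which for the external test sets prints (columns abridged):

```
     set  significance  validity_M  validity_NM  efficiency
external          0.15    0.846631     0.864139    0.862500
external          0.20    0.791887     0.811281    0.804286
external          0.25    0.741841     0.758838    0.752500
external          0.30    0.691018     0.698254    0.698214
```

Per-class validity tracks the confidence level 1 − ε at every significance
level — the conformal guarantee in action — while efficiency falls as ε
grows and more compounds drop to the *empty* class.

The same pipeline is available from the shell:

```sh
amescp synth --out data.csv --seed 4
amescp run --data data.csv --reps 50 --folds 5 --levels 0.15,0.20,0.25,0.30 \
           --trees 100 --seed 3 --out results/
```

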