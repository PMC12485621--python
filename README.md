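# ystr-ancestry

Population-of-origin classification from Y-chromosome short tandem
repeat (Y-STR) haplotypes, built for rapid forensic ancestry screening
among closely related populations that commercial ancestry panels lump
together.

A Y-STR haplotype is the set of repeat-count alleles a male sample
carries across a small forensic marker panel (the built-in default is
the common 20-locus screening set with the two-copy marker DYS385ab).
Because allele frequencies differ between populations, a haplotype
carries a population signal — weak per locus, useful in aggregate.

## Method

The core model is a **one-vs-rest (OvR) attention ensemble**:

1. **Encoding.** Every observed (locus, allele) pair — including
   microvariants such as `13.2`, treated as distinct categories — becomes
   one binary feature (`DYS439_10` style). Complete profiles activate
   exactly one feature per locus-copy.
2. **Experts.** One binary classifier per population (that population vs
   the rest). Three families are supported — L2 logistic regression,
   random forest, gradient-boosted trees — with per-expert Bayesian
   (Gaussian-process) hyperparameter tuning under stratified k-fold CV.
3. **Calibration.** Each expert's raw score *s* is mapped through a Platt
   sigmoid `P(y=1|s) = 1/(1+exp(A·s+B))`, with `(A, B)` fit by maximum
   likelihood on out-of-fold scores, so the ensemble works with honest
   probabilities instead of overconfident raw scores.
4. **Attention fusion.** Per-expert weights
   `w = softmax((balanced_accuracy + normalized_MI)/T)` combine the k
   calibrated probabilities, `final_prediction = Σ wᵢ·pᵢ`; the weighted
   terms and their sum feed a small fully-connected meta-network trained
   with cross-entropy that outputs the final k-class probabilities.

A **one-vs-one (OvO) stacking comparator** — one calibrated classifier
per population pair, k(k−1)/2 in total, stacked by the same
meta-network design — is provided for architecture comparison, along
with its pairwise-accuracy matrix, which localizes which population
pairs are genuinely hard (admixed pairs show up as its minimum).

A synthetic haplotype simulator (Dirichlet allele frequencies,
admixture blending between chosen pairs, microvariants, missing calls)
makes every stage testable without access to real reference databases.

## Worked example

```python
from ystr_ancestry import RunConfig, run_experiment

cfg = RunConfig(
    simulate={"n_populations": 3, "n_per_population": 80,
              "alleles_per_locus": 5, "concentration": 0.5},
    architectures=("ovr", "ovo"),
    meta={"hidden_sizes": (32, 16), "epochs": 200, "learning_rate": 0.01},
    seed=11,
)
report, artifacts = run_experiment(cfg)
print(artifacts["ovr"].summary())
```

prints

```
One-vs-Rest attention ensemble
  populations: 3   experts: 3   train samples: 192   features: 204

population    algorithm              bal.acc     MI   attn        A        B
POP1          logistic_regression      1.000  0.751  0.341   -9.387    4.961
POP2          logistic_regression      1.000  0.626  0.301   -9.441    4.965
POP3          logistic_regression      1.000  0.800  0.358   -9.390    4.957
```

— per expert: its out-of-fold balanced accuracy, the normalized mutual
information of its best single feature, the attention weight those two
produce, and the fitted calibration parameters (A < 0 means the sigmoid
is orientation-preserving). On this well-separated simulation both
architectures reach test accuracy 1.0
(`report["architectures"]["ovr"]["accuracy"]`), and per-sample
probabilistic guidance is available as
`artifacts["ovr"].predict_report(artifacts["test"])`:

```
  SampleID Predicted  Top1_prob Top2  Top2_prob
POP1_00002      POP1   0.997334 POP3   0.002666
POP1_00010      POP1   0.997438 POP3   0.002562
```

The same pipeline is scriptable from the shell:

```bash
ystr-ancestry simulate --pops 3 --n-per-pop 200 --seed 1 --out table.csv
ystr-ancestry preprocess --in table.csv --train-out train.csv --test-out test.csv --seed 1
ystr-ancestry train --train train.csv --model-out model/ --seed 1
ystr-ancestry predict --model model/ --in test.csv --out predictions.csv --on-unseen zero
ystr-ancestry evaluate --model model/ --test test.csv --report-out report.json --on-unseen zero
```

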