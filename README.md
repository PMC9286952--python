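# iaoadbn

Metaheuristic-tuned deep belief networks for five-year-survival
classification on tabular clinical data, with the full method stack built
from first principles:

* the **Archimedes optimization algorithm (AOA)** — a population
  metaheuristic in which each candidate ("material") carries a density,
  volume and acceleration, with a transfer factor
  `TF(t) = exp((t − t_max)/t_max)` switching the search from global
  exploration to local exploitation and a density factor
  `d(t) = exp((t_max − t)/t_max) − t/t_max` shrinking step sizes;
* an **improved variant (IAOA)** adding sine-chaos
  (`x_{t+1} = sin(2/x_t)`) plus opposition-based initialization and a
  Gaussian elite mutation `x_best ⊙ (1 + N(0, σ))` accepted only on strict
  improvement;
* **MRMR feature ranking** — greedy maximization of `Φ = D − R`, where
  `D = (1/|S|) Σ I(x_i; C)` is the mean feature–label mutual information and
  `R = (1/|S|²) Σ I(x_i; x_j)` the normalized pairwise redundancy, with
  binned plug-in MI estimates and the incremental-subset CV procedure;
* a **deep belief network** — stacked Bernoulli restricted Boltzmann
  machines with energy `E(v,h) = −v'Wh − a'v − b'h`, pretrained greedily by
  one-step contrastive divergence and fine-tuned by backpropagation through
  a 2-unit softmax head;
* **IAOA-driven hyperparameter search** of the DBN's learning rate α and
  batch size β under a stratified 10-fold cross-validation protocol;
* a **seeded synthetic cohort generator** emulating a 298-patient
  esophageal squamous cell carcinoma (ESCC) dataset — 17 blood indicators,
  age, and T/N/TNM staging with published marginal statistics, and a binary
  five-year-survival label (exact 147/151 split) planted through a logistic
  score over 11 designated indicators;
* the 13-function **benchmark suite** (Sphere … Penalized 2, Kowalik,
  six-hump camel, Branin) with a seeded run-matrix reporter.

The real clinical cohort behind the method is private; the synthetic
generator reproduces its shape and marginals so every experiment here is
fully reproducible from a seed.

## Worked example

```python
from iaoadbn import (CvProtocol, DbnConfig, escc_spec, generate_cohort,
                     optimize_hyperparams)

cohort = generate_cohort(escc_spec(n=298, seed=0))
report = optimize_hyperparams(
    cohort, optimizer="iaoa", population_size=5, max_iterations=3,
    cv=CvProtocol(n_folds=5, seed=0),
    dbn_config=DbnConfig(layer_sizes=(16, 8), pretrain_epochs=10,
                         finetune_epochs=60),
)
for f in report.folds:
    print(f.fold, round(f.alpha, 4), f.beta, round(f.test_accuracy, 3))
print("mean accuracy:", round(report.mean_accuracy, 4))
```

prints one line per outer fold — the learning rate and batch size the
search selected on that fold's inner validation split, and the accuracy of
the retrained model on the held-out fold — followed by the 5-fold mean,
e.g.:

```
0 0.1866 48 0.8
1 0.2743 32 0.867
2 0.0291 6 0.85
3 0.0329 5 0.898
4 0.1917 64 0.61
mean accuracy: 0.805
```

Four folds classify 80–90% of held-out patients correctly on a cohort whose
planted signal admits at most ~90% (the generator's Bayes rate); fold 4's
15-evaluation search picked a weak configuration, which is the price of the
example's one-minute budget — the default budget (population 20, 30
iterations) and the full architecture close that gap (the test suite runs
the tuned-versus-default comparison at 10 folds and reaches ≈0.89). The
same pipeline is scriptable from the shell
(`iaoadbn simulate | select | train | tune | bench`), and `examples/`
contains one short narrative script per capability.

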