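"""Tune a deep belief network's learning rate and batch size with the
improved Archimedes optimizer, scored by stratified cross-validation.

Uses a small search budget and a compact network so the example runs in
about a minute; each outer fold reports the hyperparameters the search
selected on its inner validation split and the held-out fold accuracy.
"""

from iaoadbn import CvProtocol, DbnConfig, escc_spec, generate_cohort, optimize_hyperparams

cohort = generate_cohort(escc_spec(n=298, seed=0))
report = optimize_hyperparams(
    cohort,
    optimizer="iaoa",
    population_size=5,
    max_iterations=3,
    cv=CvProtocol(n_folds=5, seed=0),
    dbn_config=DbnConfig(layer_sizes=(16, 8), pretrain_epochs=10, finetune_epochs=60),
)

print(f"{'fold':>4s} {'alpha':>8s} {'beta':>5s} {'inner acc':>10s} {'test acc':>9s}")
for f in report.folds:
    print(f"{f.fold:4d} {f.alpha:8.4f} {f.beta:5d} {f.search_accuracy:10.3f} {f.test_accuracy:9.3f}")
print(f"\nmean held-out accuracy: {report.mean_accuracy:.4f}")
print("alpha/beta are the CD learning rate and minibatch size chosen per fold;")
print("inner acc is the validation accuracy that drove the search, test acc the")
print("held-out fold accuracy of the model retrained with the chosen values.")
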