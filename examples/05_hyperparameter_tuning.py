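"""Seeded random-search hyperparameter tuning with median pruning.

Each trial samples a configuration from the search space, is scored by its
median test MCC over a few CV iterations, and may be pruned early if its
running median trails the field.  The best trial's hyperparameters feed a
final, longer CV run.
"""

from pathpairs import (
    ModelSpec,
    SplitSpec,
    SynthConfig,
    build_feature_sets,
    cross_join,
    generate,
    run_cv,
    tune,
)

matrix, catalog = generate(SynthConfig(seed=0))
sets = build_feature_sets(matrix, catalog)
ds = cross_join(sets.metabolite, sets.pathway, catalog)

space = {
    "n_estimators": {"type": "int", "low": 50, "high": 300},
    "max_depth": {"type": "int", "low": 3, "high": 8},
    "learning_rate": {"type": "float", "low": 0.05, "high": 0.5, "log": True},
}
result = tune(ds, "gbt", space, n_trials=5, max_cv_iterations=3, seed=0)
print(result.trials[["trial", "median_mcc", "n_iterations", "pruned"]]
      .to_string(index=False))
print(f"best trial {result.best_trial}: median MCC "
      f"{result.best_median_mcc:.4f}, {result.best_hyperparameters}")

final = run_cv(ds, ModelSpec("gbt", result.best_hyperparameters, 0),
               SplitSpec(seed=0), 5)
mean, sd = final.overall("mcc")
print(f"final CV with tuned hyperparameters: MCC {mean:.4f} +/- {sd:.4f}")
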