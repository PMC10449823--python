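"""How much manual labeling does pseudo-labeling save?

The manually labeled pool is subsampled class-proportionally to a set of
fractions; each reduced pool seeds its own full pseudo-labeling run, and
the rows compare test accuracy and the share of all training-side images
utilized, before vs after.
"""

import warnings

from herdid import (
    CaptureConfig,
    ClassifierSpec,
    SplitPlan,
    generate_study,
    labeled_fraction_ablation,
    prepare_experiment,
)

config = CaptureConfig(n_individuals=6, master_seed=2)
plan = SplitPlan(train_per_individual=4, val_total=24, test_total=24, n_unlabeled=90)
data = prepare_experiment(generate_study(config, plan))
spec = ClassifierSpec(backbone="nearest-centroid-reference", n_classes=data.n_classes)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # small fractions keep >= 1 image per class
    rows = labeled_fraction_ablation(
        data, fractions=(0.25, 0.50, 1.0), n_rounds=2, spec=spec, master_seed=2
    )

print("fraction  base_size  base_acc%  final_size  final_acc%  util% initial->final")
for r in rows:
    print(f"{r.fraction:>8.2f}  {r.baseline_train_size:>9}  {r.baseline_test_accuracy:>8.1f}"
          f"  {r.final_train_size:>10}  {r.final_test_accuracy:>9.1f}"
          f"  {r.initial_pct_utilized:>5.0f} -> {r.final_pct_utilized:.0f}")

# Reading a row: starting from that fraction of the labels, pseudo-labeling
# grows the training set to final_size (final utilization % of all available
# training-side images) and moves test accuracy from base_acc to final_acc.
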