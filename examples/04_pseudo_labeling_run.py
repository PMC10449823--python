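"""A full multi-round pseudo-labeling run on a synthetic herd.

Round 0 trains only on the manually labeled pool; each later round sweeps
the 13-value confidence-threshold grid, keeps the threshold whose model
scores best on validation, promotes the filtered unlabeled images with
their predicted labels (frozen thereafter), and carries that model on.
Uses the deterministic nearest-centroid reference backbone, so the run is
bit-reproducible; swap the ClassifierSpec backbone for "small-cnn" to reproduce
the accuracy gains of the full experiment (slower).
"""

from herdid import (
    CaptureConfig,
    ClassifierSpec,
    SplitPlan,
    generate_study,
    prepare_experiment,
    pseudo_label_precision,
    run_pseudo_labeling,
)

config = CaptureConfig(n_individuals=8, master_seed=2)
plan = SplitPlan(train_per_individual=3, val_total=32, test_total=32, n_unlabeled=120)
data = prepare_experiment(generate_study(config, plan))

spec = ClassifierSpec(backbone="nearest-centroid-reference", n_classes=data.n_classes)
result = run_pseudo_labeling(data, n_rounds=3, spec=spec, master_seed=2)

print("round  threshold   train  pseudo  val_acc  test_acc")
for rr in result.history:
    thr = "-" if rr.chosen_threshold is None else str(rr.chosen_threshold)
    print(f"{rr.round_index:>5}  {thr:>9}  {rr.n_manual + rr.n_pseudo:>5} "
          f"{rr.n_pseudo:>7}  {rr.validation_accuracy:.3f}    {rr.test_accuracy:.3f}")

if result.state.pseudo_pool:
    precision = pseudo_label_precision(result.state.pseudo_pool, data.true_labels)
    print(f"\npromoted {len(result.state.pseudo_pool)} pseudo-labels, "
          f"{100 * precision:.1f}% of them correct (vs the hidden ledger)")

# Each row is one round: the chosen threshold, the resulting training-set
# composition, and validation/test accuracy of that round's model.
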