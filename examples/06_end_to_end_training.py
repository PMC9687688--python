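"""Run the whole pipeline: logs -> features -> scalograms -> CNN -> metrics.

Trains on a strongly separated synthetic cohort (40 subjects per class,
64x64 images) with early stop by validation loss, then prints the
confusion matrix and derived metrics on the held-out test split.
Takes roughly half a minute on one CPU.
"""

from wavetap import TrainConfig, run_pipeline, separated_scenario, simulate_cohort

logs = simulate_cohort(separated_scenario(n_per_class=40, gap_sd=3.0, seed=0))
config = TrainConfig(
    batch_size=8, steps_per_epoch=10, max_epochs=10,
    early_stop_valid_loss=0.4, image_size=(64, 64, 3), seed=0,
)
result = run_pipeline(logs, image_size=(64, 64), smote=False, train_config=config, model_seed=0)

print("training history:")
print(result.history.to_string(index=False))

rep = result.report
print(f"\nconfusion matrix (rows = truth):\n{rep.to_frame()}")
print(
    f"\naccuracy={rep.accuracy:.3f}  sensitivity={rep.sensitivity:.3f}  "
    f"specificity={rep.specificity:.3f}  F1={rep.f1:.3f}"
)
print(
    "\ntraining stopped the first epoch validation loss fell below 0.4; "
    "with a 3-sd class gap the held-out subjects separate almost perfectly"
)
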