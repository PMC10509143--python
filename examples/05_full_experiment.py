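"""The whole protocol in one call: simulate, split 7:3, fit, score.

Runs the feature-extraction linear model on a small noisy dataset and
writes metrics.csv / agreement.csv / predictions.csv / summary.json.
Add "resnet" or "se_resnet" to `models` to include the CNN regressors
(a few extra minutes each on one CPU).
"""

from spongehb import ExperimentConfig, run_experiment

config = ExperimentConfig(
    n_images=100,
    scene_size=96,
    models=("feature_extraction",),
    seed=5,
    out_dir="scratch/experiment",
)
summary = run_experiment(config)

print(f"train {summary['n_train']} / test {summary['n_test']} (7:3 split)")
for name, m in summary["metrics"].items():
    print(f"{name}: MAE {m['mae']:.2f} mg, MAPE {m['mape']:.1f}%, R2 {m['r2']:.3f}")
rep = summary["agreement"]["feature_extraction"]
print(
    f"Bland-Altman: bias {rep['bias']:.2f} mg, "
    f"LOA ({rep['loa_lower']:.2f}, {rep['loa_upper']:.2f}) mg"
)
print(f"\nfull reports under {config.out_dir}/")
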