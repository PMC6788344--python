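"""Train the Siamese change detector on a small phantom cohort.

Uses a reduced-width network and a small aligned cohort so the script runs
in about a minute on one CPU, then prints the training trace and the
held-out ROC metrics with a Monte-Carlo confidence interval.
"""

import numpy as np

from longisym.evalstats import evaluate_scores
from longisym.nn import DeepSymNetConfig, InceptionSpec, TrainConfig, build, train
from longisym.phantom import PhantomConfig, generate_cohort

config = PhantomConfig(noise_sd=0.05, misalign_max=(0.0, 0.0), seed=3)
_, records = generate_cohort(config, {"progressor": 15, "non-progressor": 15})
code = {"non-progressor": 0, "progressor": 1}
dataset = [
    (r.session1.data.astype(np.float32), r.session2.data.astype(np.float32),
     code[r.class_label])
    for r in records
]
y = np.array([d[2] for d in dataset])
rng = np.random.default_rng(0)
order = rng.permutation(len(dataset))
train_idx, val_idx, test_idx = order[:20], order[20:24], order[24:]

model = build(
    DeepSymNetConfig(input_shape=(16, 16, 16), inception=InceptionSpec(filters_per_branch=8)),
    seed=0,
)
print(f"network: {model.n_parameters} parameters, "
      f"{len(model.branch)} shared + {len(model.post)} post-merge Inception modules")
train(model, dataset, train_idx, val_idx,
      TrainConfig(learning_rate=1e-3, max_epochs=8, early_stop_patience=3, seed=0))
for h in model.training_history:
    print(f"  epoch {h['epoch']:2d}: train loss {h['train_loss']:.4f}  "
          f"val loss {h['val_loss']:.4f}")

x1 = np.stack([dataset[i][0] for i in test_idx])
x2 = np.stack([dataset[i][1] for i in test_idx])
probs = model.predict_proba(x1, x2)
report = evaluate_scores(probs, y[test_idx], ci_iters=500, seed=0)
print(f"\nheld-out subjects: {len(test_idx)}")
print(f"AUC {report.auc:.3f}  (95% MC CI {report.ci_low:.3f}-{report.ci_high:.3f})")
print(f"cutoff {report.cutoff:.3f}: sensitivity {report.sensitivity:.3f}, "
      f"specificity {report.specificity:.3f}, balanced accuracy {report.balanced_accuracy:.3f}")
# The 40% intensity-loss signal is strong, so the toy run typically reaches
# a perfect or near-perfect held-out AUC within a few epochs.
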