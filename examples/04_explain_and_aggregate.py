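"""Explain predictions with epsilon-LRP and rank atlas regions.

Trains a quick model, computes per-voxel relevance for a few held-out
subjects, accumulates absolute relevance over subjects and sessions
(M_N), aggregates it into volume-normalized region scores (M_r), and
prints the ranked table — the implanted region should come first.
"""

import numpy as np

from longisym.lrp import relevance
from longisym.nn import DeepSymNetConfig, InceptionSpec, TrainConfig, build, train
from longisym.phantom import PhantomConfig, generate_cohort
from longisym.regions import accumulate, aggregate_by_region, top_regions

config = PhantomConfig(noise_sd=0.05, misalign_max=(0.0, 0.0), seed=5)
atlas, records = generate_cohort(config, {"progressor": 12, "non-progressor": 12})
code = {"non-progressor": 0, "progressor": 1}
dataset = [
    (r.session1.data.astype(np.float32), r.session2.data.astype(np.float32),
     code[r.class_label])
    for r in records
]
order = np.random.default_rng(0).permutation(len(dataset))
train_idx, val_idx, test_idx = order[:16], order[16:20], order[20:]

model = build(
    DeepSymNetConfig(input_shape=(16, 16, 16), inception=InceptionSpec(filters_per_branch=8)),
    seed=1,
)
train(model, dataset, train_idx, val_idx,
      TrainConfig(learning_rate=1e-3, max_epochs=6, early_stop_patience=3, seed=1))

maps = [relevance(model, (dataset[i][0], dataset[i][1]), subject_id=str(i))
        for i in test_idx]
print(f"accumulated |relevance| over {len(maps)} held-out subjects, both sessions")
table = aggregate_by_region(accumulate(maps), atlas)
print(table.table[["rank", "region_id", "name", "V_r", "M_r"]].to_string(index=False))
best = top_regions(table, 1).iloc[0]
print(f"\ntop region: {best['name']} (id {int(best['region_id'])}) — "
      f"atrophy was implanted in region {config.target_regions[0]}")
# Volume normalization (M_r = summed relevance / V_r) is what lets a small
# but consistently-relevant region outrank large regions with diffuse noise.
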