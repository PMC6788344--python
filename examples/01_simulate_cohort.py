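"""Generate a synthetic longitudinal cohort and verify its ground truth.

Builds a seeded 16^3 phantom cohort with two sessions per subject, prints
the atlas layout and shows that the implanted atrophy fraction is exactly
recoverable from the noiseless target-region means.
"""

import numpy as np

from longisym.phantom import PhantomConfig, generate_cohort

config = PhantomConfig(noise_sd=0.0, misalign_max=(0.0, 0.0), seed=7)
atlas, records = generate_cohort(config, {"progressor": 3, "non-progressor": 3})

print(f"atlas: {len(atlas.region_ids)} regions over "
      f"{sum(atlas.region_volumes.values())} brain voxels")
for r in atlas.region_ids:
    mark = " <- atrophy target" if r in config.target_regions else ""
    print(f"  region {r:2d} ({atlas.region_names[r]}): V_r = {atlas.region_volumes[r]}{mark}")

target = np.isin(atlas.labels.data, config.target_regions)
print("\nsubject  class            implanted  recovered (1 - mean_s2/mean_s1)")
for rec in records:
    m1 = rec.session1.data[target].mean()
    m2 = rec.session2.data[target].mean()
    print(f"{rec.subject_id}    {rec.class_label:15s}  {rec.true_atrophy_fraction:.3f}"
          f"      {1 - m2 / m1:.6f}")
# With noise and misalignment switched off, the recovered fraction matches
# the implanted one to machine precision — the generator's ground truth is
# analytically exact, which is what makes the downstream checks meaningful.
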