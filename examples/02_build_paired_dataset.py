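"""Build a paired clean/artifact/residual dataset and split it 70/10/20.

The reference protocol extracts a 50-slice window from each volume and
turns every slice into one training pair; 200 volumes give 10,000 pairs
split 7000/1000/2000. Here we run the same pipeline at a small scale.
"""

from mrmotionsim import (PhantomSpec, SimulationParams, build_pairs,
                         extract_center_slices, generate_phantom,
                         normalize_volume, save_dataset, split_dataset)

volumes = []
for i in range(4):
    spec = PhantomSpec(matrix_size=64, n_slices=24, seed=100 + i)
    vol = normalize_volume(generate_phantom(spec).volume)
    volumes.append(extract_center_slices(vol, n=20))

samples = build_pairs(volumes, SimulationParams(), seed=1)
split = split_dataset(samples, fractions=(0.7, 0.1, 0.2), seed=1)
save_dataset(samples, split, "scratch_dataset.h5")

print(f"volumes: {len(volumes)}, slices/volume: 20 -> pairs: {len(samples)}")
print(f"split sizes (train/val/test): {split.sizes}")
# 4 volumes x 20 slices = 80 pairs; floor(0.1*80)=8 validation,
# floor(0.2*80)=16 test, remainder 56 train.
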