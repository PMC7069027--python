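"""Superpixel pre-segmentation and reference-mask labeling.

Over-segments a synthetic scene with SLIC, aggregates per-superpixel color
features and labels each superpixel by the 0.8 rule: positive when more
than 80% of its pixels fall inside the reference spike mask.
"""

from spikecount import (
    SceneConfig,
    aggregate_features,
    assign_labels,
    generate_scene,
    image_features,
    slic_segment,
)
from spikecount.features import SPIKE

image, truth = generate_scene(
    SceneConfig(image_height=486, image_width=648, n_spikes=10, seed=3)
)
features = image_features(image)
spmap = slic_segment(image, n=2500, m=10)
records = aggregate_features(spmap, features)
labeled = assign_labels(records, spmap, truth.class_map == SPIKE, threshold=0.8)

n_pos = sum(r.label for r in labeled)
mixed = sum(1 for r in labeled if 0.0 < r.spike_fraction <= 0.8)
print(f"{spmap.n_segments} superpixels from a requested n = 2500")
print(f"{n_pos} labeled spike (fraction > 0.8), {mixed} mixed but labeled background")
print(
    "\nMixed superpixels sit on spike boundaries; the strict 0.8 rule keeps"
    "\nthem out of the positive training class."
)
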