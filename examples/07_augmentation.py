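"""Expand an image set with randomized geometric transforms.

Each scalogram receives two affine variants (rotation up to 40 degrees,
shear/zoom/height-shift up to 0.2, optional horizontal flip), tripling
the dataset while preserving labels and class balance.
"""

from wavetap import (
    AugmentConfig,
    SimConfig,
    augment_dataset,
    extract_matrix,
    matrix_to_images,
    minmax_scale,
    simulate_cohort,
)

logs = simulate_cohort(SimConfig(n_healthy=3, n_parkinson=3, events_per_subject=80, seed=5))
scaled, _, _ = minmax_scale(extract_matrix(logs))
images = matrix_to_images(scaled, outdir=None, size=(64, 64))

augmented = augment_dataset(images, AugmentConfig(copies_per_image=2, seed=0))
print(f"input : {len(images)} images, class counts {images.class_counts()}")
print(f"output: {len(augmented)} images, class counts {augmented.class_counts()}")
print(f"provenance tags: {sorted(set(augmented.provenance))}")
print(
    "\naugmentation belongs after the train/test split (the pipeline default): "
    "augmenting first would leak near-duplicates of training images into the test set"
)
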