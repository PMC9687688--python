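"""Geometric image augmentation for the scalogram dataset.

Each source image receives a configurable number of randomized variants.
One variant = a single composed affine transform about the image centre —
rotation, shear, isotropic zoom and a vertical (height) shift — applied
with bilinear interpolation and reflect padding, plus an optional
horizontal flip with probability 1/2.  Parameters are drawn uniformly on
symmetric intervals: rotation in [-r, r] degrees, shear in [-s, s], zoom
factor in [1-z, 1+z], height shift in [-h, h] of the image height (the
keras ImageDataGenerator convention for a "range").

Augmenting before the train/test split leaks near-duplicate images across
splits, so the pipeline applies this to the training split only;
``wavetap.cli`` exposes a flag reproducing the leakage-prone
augment-then-split order for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .pipeline import ImageDataset

__all__ = ["AugmentConfig", "augment_dataset", "random_affine"]


@dataclass
class AugmentConfig:
    """Transform ranges (defaults are the pipeline's standard settings)."""

    rotation_range: float = 40.0  # degrees
    height_shift_range: float = 0.2  # fraction of image height
    shear_range: float = 0.2
    zoom_range: float = 0.2
    horizontal_flip: bool = True
    rescale: float = 1.0 / 255.0  # intensity scale applied at load time, not here
    copies_per_image: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rotation_range <= 40):
            raise ValueError("rotation_range must lie in [0, 40] degrees")
        for name in ("height_shift_range", "shear_range", "zoom_range"):
            v = getattr(self, name)
            if not (0 <= v <= 0.2):
                raise ValueError(f"{name} must lie in [0, 0.2]")
        if self.copies_per_image < 1:
            raise ValueError("copies_per_image must be >= 1")


def random_affine(image: np.ndarray, rng: np.random.Generator, config: AugmentConfig) -> np.ndarray:
    """One randomized affine variant of an H x W x 3 uint8 image."""
    h, w = image.shape[:2]
    theta = np.deg2rad(rng.uniform(-config.rotation_range, config.rotation_range))
    shear = rng.uniform(-config.shear_range, config.shear_range)
    zoom = rng.uniform(1.0 - config.zoom_range, 1.0 + config.zoom_range)
    shift = rng.uniform(-config.height_shift_range, config.height_shift_range) * h
    flip = config.horizontal_flip and rng.random() < 0.5

    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    mat = zoom * (rot @ shr)  # output->input coordinate map (rows, cols)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ center + np.array([shift, 0.0])

    out = np.empty_like(image)
    for ch in range(image.shape[2]):
        out[..., ch] = ndimage.affine_transform(
            image[..., ch].astype(np.float32),
            mat,
            offset=offset,
            order=1,
            mode="reflect",
        ).round().clip(0, 255).astype(np.uint8)
    if flip:
        out = out[:, ::-1]
    return out


def augment_dataset(dataset: ImageDataset, config: AugmentConfig | None = None) -> ImageDataset:
    """Original images plus ``copies_per_image`` randomized variants each.

    Labels, subject ids and class proportions are inherited exactly; output
    size is ``len(dataset) * (copies_per_image + 1)``.  Deterministic given
    ``config.seed``.
    """
    config = config or AugmentConfig()
    if len(dataset) == 0:
        raise ValueError("cannot augment an empty dataset")
    rng = np.random.default_rng(config.seed)
    images, labels, sids, prov = [], [], [], []
    for i in range(len(dataset)):
        images.append(dataset.images[i])
        labels.append(dataset.labels[i])
        sids.append(dataset.subject_ids[i])
        prov.append(dataset.provenance[i])
        for c in range(config.copies_per_image):
            images.append(random_affine(dataset.images[i], rng, config))
            labels.append(dataset.labels[i])
            sids.append(f"{dataset.subject_ids[i]}_aug{c}")
            prov.append("augmented")
    return ImageDataset(
        images=np.stack(images),
        labels=np.array(labels, dtype=object),
        subject_ids=np.array(sids, dtype=object),
        provenance=np.array(prov, dtype=object),
    )
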