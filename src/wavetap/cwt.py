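"""Morlet continuous wavelet transform and scalogram image rendering.

A normalized feature vector is treated as a discrete signal with unit
spacing along its index; its continuous wavelet transform against the real
Morlet mother wavelet

    psi(t) = exp(-t^2 / 2) * cos(5 t)

is evaluated by a Riemann-sum discretization of the CWT integral,

    W[lambda, t] = sum_tau x[tau] * (1 / sqrt(lambda)) * psi((tau - t) / lambda),

for an increasing grid of scales (default: the integers 1..20; the constant
5 is the Morlet centre frequency, so scale lambda localizes angular
frequency ~5/lambda).  The coefficient magnitude matrix (scale x position)
is the scalogram, rendered as a colormapped RGB image for the downstream
convolutional classifier.

The wavelet support is truncated where |arg| > 8, where its magnitude falls
below 1e-14; no padding is applied, the wavelet simply overlaps the signal
where it can (equivalently, the signal is zero-extended).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")
from matplotlib import colormaps as _colormaps
from PIL import Image

from .tappy_io import FeatureMatrix

__all__ = [
    "CENTER_FREQUENCY",
    "TRUNCATION_RADIUS",
    "WaveletConfig",
    "Scalogram",
    "morlet",
    "cwt",
    "render_scalogram",
    "matrix_to_images",
]

#: Morlet centre-frequency constant (the 5 in cos(5t)).
CENTER_FREQUENCY = 5.0
#: |psi| < 1e-14 beyond this argument radius; the kernel is truncated there.
TRUNCATION_RADIUS = 8.0


def morlet(t):
    """Real Morlet mother wavelet ``exp(-t^2/2) * cos(5 t)``.

    Even in ``t``; accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    out = np.exp(-0.5 * t * t) * np.cos(CENTER_FREQUENCY * t)
    return out if out.ndim else float(out)


@dataclass
class WaveletConfig:
    """CWT configuration: mother wavelet and scale grid.

    Scales must be strictly positive and increasing.  The printed interval
    [0, 20] would include the degenerate scale 0 (division by zero in the
    scaled wavelet), so the default grid is the 20 integer scales 1..20.
    """

    mother: str = "morlet"
    scales: np.ndarray = field(default_factory=lambda: np.arange(1.0, 21.0))

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.ndim != 1 or self.scales.size == 0:
            raise ValueError("scales must be a non-empty 1-D sequence")
        if np.any(self.scales <= 0) or np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly positive and increasing")
        if self.mother not in _MOTHERS:
            raise ValueError(f"unknown mother wavelet {self.mother!r}")

    @property
    def mother_fn(self):
        return _MOTHERS[self.mother]


_MOTHERS = {"morlet": morlet}


@dataclass
class Scalogram:
    """Wavelet coefficient matrix (n_scales x n_positions) for one signal."""

    coefficients: np.ndarray
    scales: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.scales), self.source_length):
            raise ValueError("coefficient matrix shape must be (n_scales, source_length)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def cwt(signal: np.ndarray, config: WaveletConfig | None = None) -> Scalogram:
    """Riemann-sum CWT of a 1-D signal over the configured scale grid.

    ``W[i, t] = sum_tau x[tau] * psi((tau - t)/scale_i) / sqrt(scale_i)``,
    computed per scale as a correlation with a truncated wavelet kernel.
    Real-valued throughout because the mother wavelet is real.
    """
    config = config or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal values must be finite")
    n = x.size
    psi = config.mother_fn
    coeffs = np.empty((config.scales.size, n), dtype=float)
    for i, lam in enumerate(config.scales):
        radius = int(np.ceil(TRUNCATION_RADIUS * lam))
        offsets = np.arange(-radius, radius + 1, dtype=float)
        # kernel[d] = psi(d / lam) / sqrt(lam); even because psi is even
        kernel = psi(offsets / lam) / np.sqrt(lam)
        # correlation with an even kernel == convolution
        coeffs[i] = np.convolve(x, kernel, mode="full")[radius : radius + n]
    return Scalogram(coefficients=coeffs, scales=config.scales.copy(), source_length=n)


def render_scalogram(
    s: Scalogram,
    size: tuple[int, int] = (240, 240),
    colormap: str = "viridis",
) -> np.ndarray:
    """Render a scalogram as an H x W x 3 uint8 RGB image.

    Coefficient magnitudes are linearly mapped to [0, 1] over the whole
    matrix (sign carries no display meaning), colormapped, and resampled to
    the target size with bilinear interpolation.  A zero-range matrix
    renders as a uniform single-colour image.
    """
    mag = np.abs(s.coefficients)
    lo, hi = float(mag.min()), float(mag.max())
    norm = np.zeros_like(mag) if hi == lo else (mag - lo) / (hi - lo)
    cmap = _colormaps[colormap]
    rgb = (cmap(norm)[..., :3] * 255.0).round().astype(np.uint8)
    h, w = size
    img = Image.fromarray(rgb, mode="RGB").resize((w, h), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def matrix_to_images(
    matrix: FeatureMatrix,
    config: WaveletConfig | None = None,
    outdir: str | Path | None = None,
    size: tuple[int, int] = (240, 240),
    colormap: str = "viridis",
):
    """Convert every feature row to a scalogram image.

    With ``outdir`` set, writes one PNG per row under class-named
    subdirectories plus a ``manifest.csv`` mapping file -> subject id,
    label and provenance, and returns the manifest DataFrame.  Without
    ``outdir``, returns an in-memory :class:`~wavetap.pipeline.ImageDataset`.

    The input matrix is expected to be min-max scaled to [0, 1].
    """
    import pandas as pd

    from .pipeline import ImageDataset

    config = config or WaveletConfig()
    images = np.empty((matrix.n_subjects, size[0], size[1], 3), dtype=np.uint8)
    for i in range(matrix.n_subjects):
        images[i] = render_scalogram(cwt(matrix.values[i], config), size, colormap)

    dataset = ImageDataset(
        images=images,
        labels=matrix.labels.copy(),
        subject_ids=matrix.subject_ids.copy(),
        provenance=matrix.provenance.copy(),
    )
    if outdir is None:
        return dataset

    outdir = Path(outdir)
    rows = []
    for i in range(matrix.n_subjects):
        label = str(matrix.labels[i])
        cls_dir = outdir / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        fname = f"{matrix.subject_ids[i]}_{i:04d}.png"
        Image.fromarray(images[i], mode="RGB").save(cls_dir / fname)
        rows.append(
            {
                "file": f"{label}/{fname}",
                "subject_id": matrix.subject_ids[i],
                "label": label,
                "provenance": matrix.provenance[i],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
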