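"""End-to-end pipeline: keystroke logs -> features -> images -> classifier.

Chains every stage with the study's ordering: feature extraction, SMOTE
oversampling of the minority class, min-max scaling to [0, 1], Morlet-CWT
scalogram rendering, stratified splitting, optional training-split
augmentation, CNN training with early stop by validation loss, and
confusion-matrix evaluation on the held-out test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .augmentation import AugmentConfig, augment_dataset
from .cwt import WaveletConfig, matrix_to_images
from .features import build_schema, extract_matrix
from .nn.model import ModelConfig, Sequential, build_model
from .pipeline import EvalReport, ImageDataset, TrainConfig, evaluate, split_dataset, train
from .resampling import SmoteConfig, minmax_scale, smote_oversample
from .tappy_io import FeatureMatrix, SubjectLog

__all__ = ["PipelineResult", "prepare_features", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, for inspection and reporting."""

    matrix: FeatureMatrix
    images: ImageDataset
    model: Sequential
    history: pd.DataFrame
    report: EvalReport


def prepare_features(
    logs: list[SubjectLog],
    smote: SmoteConfig | None | bool = None,
) -> FeatureMatrix:
    """Logs -> oversampled, min-max-scaled feature matrix.

    ``smote=False`` skips oversampling (for ablation); otherwise the
    minority class is grown to match the majority before scaling.
    """
    matrix = extract_matrix(logs, build_schema())
    if smote is not False:
        cfg = smote if isinstance(smote, SmoteConfig) else SmoteConfig()
        matrix = smote_oversample(matrix, cfg)
    scaled, _, _ = minmax_scale(matrix)
    return scaled


def run_pipeline(
    logs: list[SubjectLog],
    image_size: tuple[int, int] = (240, 240),
    smote: SmoteConfig | None | bool = None,
    wavelet: WaveletConfig | None = None,
    train_config: TrainConfig | None = None,
    augment: AugmentConfig | None = None,
    augment_before_split: bool = False,
    model_seed: int = 0,
) -> PipelineResult:
    """Run the full study pipeline on a set of subject logs.

    Augmentation defaults to off; when given, it is applied to the
    training split only unless ``augment_before_split=True`` reproduces
    the leakage-prone augment-then-split ordering for comparison.
    """
    train_config = train_config or TrainConfig(image_size=(*image_size, 3))
    scaled = prepare_features(logs, smote=smote)
    images = matrix_to_images(scaled, wavelet, outdir=None, size=image_size)
    if augment is not None and augment_before_split:
        images = augment_dataset(images, augment)
    train_set, test_set, valid_set = split_dataset(
        images, train_config.split_fractions, seed=train_config.seed
    )
    if augment is not None and not augment_before_split:
        train_set = augment_dataset(train_set, augment)
    model = build_model(
        ModelConfig(input_shape=(*image_size, 3), seed=model_seed)
    )
    model, history = train(model, train_set, valid_set, train_config)
    report = evaluate(model, test_set)
    return PipelineResult(
        matrix=scaled, images=images, model=model, history=history, report=report
    )
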