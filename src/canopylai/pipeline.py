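"""End-to-end orchestration: calibrate, featurize, screen, augment, train.

Ties the modules together under the leakage-safe protocol: the hold-out
split is made at the sampling-point level before anything is fit;
feature screening and normalization statistics see training rows only;
CutMix runs on training samples only (synthetic features recomputed from
the mixed patches); the hybrid is trained on the normalized F x L
matrices and scored on the untouched test set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from canopylai import augment as aug
from canopylai import evaluation, features, preprocessing, screening
from canopylai.model import CNNGRURegressor, ModelConfig, build_baseline
from canopylai.synthdata import PanelObservations
from canopylai.types import RGBPatch, TemporalSample

__all__ = [
    "PipelineResult",
    "assemble_feature_inputs",
    "assemble_image_inputs",
    "calibrate_samples",
    "run_pipeline",
    "tile_predictor",
]


def calibrate_samples(
    samples: list[TemporalSample], panel: PanelObservations
) -> list[TemporalSample]:
    """Convert any DN-unit patches to reflectance via the panel curve."""
    curve = preprocessing.fit_radiometric_response(panel)
    out = []
    for s in samples:
        patches = [
            p
            if p is None or p.units == "reflectance"
            else preprocessing.apply_radiometric_calibration(p, curve)
            for p in s.patches
        ]
        out.append(dataclasses.replace(s, patches=patches))
    return out


def assemble_feature_inputs(
    samples: list[TemporalSample], config: features.FeatureConfig
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack per-sample F x L feature matrices into model inputs."""
    mats = np.stack([features.sample_feature_matrix(s, config) for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    return {"matrix": mats}, y


def assemble_image_inputs(
    samples: list[TemporalSample], image_size: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Image-mode inputs: per-stage patches stacked on channels.

    Patches are resized to ``image_size`` square; the GRU branch receives
    the per-stage band means and standard deviations (6 values per
    timestep) as its temporal sequence.
    """
    from skimage.transform import resize

    imgs, seqs, ys = [], [], []
    for s in samples:
        stack, seq = [], []
        for p in s.patches:
            if p is None:
                raise ValueError("fill missing stages before assembling images")
            v = p.values
            if v.shape[:2] != (image_size, image_size):
                v = resize(v, (image_size, image_size), anti_aliasing=True)
            stack.append(v.transpose(2, 0, 1))  # (3, H, W)
            seq.append(
                np.concatenate([v.mean(axis=(0, 1)), v.std(axis=(0, 1))])
            )
        imgs.append(np.concatenate(stack, axis=0))
        seqs.append(np.stack(seq))
        ys.append(s.label)
    return (
        {"image": np.stack(imgs), "sequence": np.stack(seqs)},
        np.array(ys, dtype=float),
    )


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, for scoring and mapping."""

    plan: evaluation.SplitPlan
    screening_report: screening.ScreeningReport
    retained_features: list[str]
    feature_config: features.FeatureConfig
    stats: preprocessing.NormalizationStats
    model: object
    metrics: evaluation.MetricBundle
    y_test: np.ndarray
    y_pred: np.ndarray
    n_train: int
    n_test: int
    n_augmented: int


def run_pipeline(
    samples: list[TemporalSample],
    panel: PanelObservations | None = None,
    model_config: ModelConfig | None = None,
    feature_config: features.FeatureConfig = features.FeatureConfig(),
    model_name: str = "cnn_gru",
    split_seed: int = 0,
    augment_fraction: float = 0.5,
    cutmix_fraction: float = 0.40,
    seed: int = 0,
) -> PipelineResult:
    """Run the full inversion pipeline on a labelled sample set.

    ``augment_fraction`` sets how many CutMix samples are appended
    relative to the training-set size (0 disables augmentation). The
    train/test split is fixed by ``split_seed``; ``seed`` drives model
    initialization and augmentation so repeats vary only those.
    """
    if panel is not None:
        samples = calibrate_samples(samples, panel)
    kept, _rejected = preprocessing.fill_all(samples)

    plan = evaluation.split(kept, fraction=0.8, mode="point", seed=split_seed)
    tr_idx, te_idx = evaluation.split_indices(plan, kept)
    train = [kept[i] for i in tr_idx]
    test = [kept[i] for i in te_idx]

    # screening sees training rows only
    table = features.build_feature_table(train, feature_config)
    report = screening.screen_features(table)
    retained = report.retained
    sub_config = dataclasses.replace(
        feature_config, feature_subset=tuple(retained)
    )

    rng = np.random.default_rng(seed)
    n_aug = int(round(augment_fraction * len(train)))
    if n_aug > 0:
        train = aug.augment_training_set(
            train, n_aug, rng=rng, fraction=cutmix_fraction
        )
    evaluation.assert_no_leakage(plan, train + test)

    tr_inputs, tr_y = assemble_feature_inputs(train, sub_config)
    te_inputs, te_y = assemble_feature_inputs(test, sub_config)
    tr_inputs["matrix"], stats = preprocessing.normalize_matrix(tr_inputs["matrix"])
    te_inputs["matrix"], _ = preprocessing.normalize_matrix(te_inputs["matrix"], stats)

    if not retained:
        raise ValueError("screening eliminated every candidate feature")
    if model_config is None:
        model_config = ModelConfig()
    # a heavily screened feature set may be narrower than the configured
    # pooling depth allows; trim conv blocks from the top until they fit
    filters = model_config.cnn_filters
    while filters and len(retained) // (2 ** len(filters)) < 1:
        filters = filters[:-1]
    model_config = dataclasses.replace(
        model_config,
        input_mode="feature",
        n_features=len(retained),
        cnn_filters=filters,
        seed=seed,
    )
    model = (
        CNNGRURegressor(model_config)
        if model_name == "cnn_gru"
        else build_baseline(model_name, model_config)
    )
    model.fit(tr_inputs, tr_y)
    y_pred = model.predict(te_inputs)
    m = evaluation.regression_metrics(te_y, y_pred)
    return PipelineResult(
        plan=plan,
        screening_report=report,
        retained_features=retained,
        feature_config=sub_config,
        stats=stats,
        model=model,
        metrics=m,
        y_test=te_y,
        y_pred=y_pred,
        n_train=len(train),
        n_test=len(test),
        n_augmented=n_aug,
    )


def tile_predictor(result: PipelineResult):
    """A callable(list of stage crops) -> LAI for sliding-window mapping."""

    def predict_tile(crops: list[RGBPatch]) -> float:
        sample = TemporalSample(point_id=-1, patches=list(crops), label=np.nan)
        mat = features.sample_feature_matrix(sample, result.feature_config)
        mats, _ = preprocessing.normalize_matrix(mat[None, :, :], result.stats)
        return float(result.model.predict({"matrix": mats})[0])

    return predict_tile
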