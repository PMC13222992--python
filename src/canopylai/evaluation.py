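"""Splitting, cross-validation, repeated metrics and significance tests.

The protocol guards against the leakage mode specific to multi-temporal
point sampling: all time-series samples from one sampling point share
strong autocorrelation, so splits and folds partition *point ids*, never
raw samples, and augmented samples (which carry two parents) may only
live where both parents live. The hold-out split is fixed once per
study; repeated runs vary only initialization and augmentation. Metrics
follow the usual regression conventions (R^2, RMSE in label units, MAE,
MAPE and rRMSE in percent), with uncertainty from repeats (mean, SD) and
percentile bootstrap confidence intervals, and pairwise model comparison
by a paired bootstrap test on squared residuals.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from canopylai.types import TemporalSample

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "split",
    "split_indices",
    "assert_no_leakage",
    "kfold_by_point",
    "regression_metrics",
    "repeated_evaluation",
    "paired_bootstrap_test",
    "input_size_study",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitPlan:
    """A train/test partition of sampling points (or raw sample indices)."""

    train_points: frozenset
    test_points: frozenset
    fraction: float
    seed: int
    mode: str  # "point" or "sample"
    train_idx: np.ndarray | None = None  # populated in sample mode
    test_idx: np.ndarray | None = None

    def side_of(self, sample: TemporalSample) -> str:
        """'train', 'test', or raise if the sample straddles the boundary."""
        parents = set(sample.parent_point_ids)
        if parents <= self.train_points:
            return "train"
        if parents <= self.test_points and not sample.synthetic:
            return "test"
        raise ValueError(
            f"sample (point {sample.point_id}, parents {sorted(parents)}) "
            "crosses the train/test boundary"
        )


def split(
    samples: Sequence[TemporalSample],
    fraction: float = 0.8,
    mode: str = "point",
    seed: int = 0,
) -> SplitPlan:
    """Seeded train/test split.

    Sample mode assigns ``round(fraction * N)`` (half-up) shuffled samples
    to train. Point mode accumulates shuffled whole points until the train
    *sample* count is nearest the same target, so no point id ever appears
    on both sides; ties resolve to the smaller prefix.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(samples)
    target = _round_half_up(fraction * n)
    rng = np.random.default_rng(seed)
    if mode == "sample":
        perm = rng.permutation(n)
        train_idx, test_idx = np.sort(perm[:target]), np.sort(perm[target:])
        train_pts = frozenset(samples[i].point_id for i in train_idx)
        test_pts = frozenset(samples[i].point_id for i in test_idx)
        return SplitPlan(train_pts, test_pts, fraction, seed, mode,
                         train_idx=train_idx, test_idx=test_idx)
    if mode != "point":
        raise ValueError(f"unknown split mode {mode!r}")
    points = sorted({s.point_id for s in samples})
    if len(points) < 2:
        raise ValueError("point-level split needs at least 2 points")
    order = rng.permutation(len(points))
    shuffled = [points[i] for i in order]
    counts = pd.Series([s.point_id for s in samples]).value_counts()
    cum = np.cumsum([counts[p] for p in shuffled])
    k = int(np.argmin(np.abs(cum - target))) + 1  # argmin = smallest prefix
    k = min(k, len(points) - 1)  # both sides must be non-empty
    train_pts = frozenset(shuffled[:k])
    test_pts = frozenset(shuffled[k:])
    return SplitPlan(train_pts, test_pts, fraction, seed, mode)


def split_indices(
    plan: SplitPlan, samples: Sequence[TemporalSample]
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize a plan on a sample list (augmented samples included)."""
    if plan.mode == "sample" and plan.train_idx is not None and len(
        plan.train_idx
    ) + len(plan.test_idx) == len(samples):
        return plan.train_idx, plan.test_idx
    train, test = [], []
    for i, s in enumerate(samples):
        (train if plan.side_of(s) == "train" else test).append(i)
    return np.array(train, dtype=int), np.array(test, dtype=int)


def assert_no_leakage(plan: SplitPlan, samples: Sequence[TemporalSample]) -> None:
    """Raise if any point id (or augmented parent) straddles the split."""
    if plan.train_points & plan.test_points:
        raise AssertionError("point sets overlap")
    for s in samples:
        plan.side_of(s)  # raises on a straddling sample


def kfold_by_point(
    samples: Sequence[TemporalSample], k: int = 10, seed: int = 0
) -> list[frozenset]:
    """Partition point ids into k folds of near-equal point counts."""
    points = sorted({s.point_id for s in samples})
    if k > len(points):
        raise ValueError(f"k={k} exceeds the {len(points)} available points")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(points))
    folds = np.array_split([points[i] for i in order], k)
    return [frozenset(f.tolist()) for f in folds]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricBundle:
    r2: float
    rmse: float
    mae: float
    mape: float  # percent
    rrmse: float  # percent
    r2_undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2, "rmse": self.rmse, "mae": self.mae,
            "mape": self.mape, "rrmse": self.rrmse,
        }


def regression_metrics(y_true, y_pred) -> MetricBundle:
    """R^2, RMSE, MAE, MAPE(%) and rRMSE(%) of a prediction vector.

    R^2 = 1 - SS_res/SS_tot; a zero-variance truth vector flags R^2 as
    undefined (returned as nan). MAPE guards |y| < 1e-9 — impossible for
    LAI labels >= 3.3 but kept for safety.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    safe = np.where(np.abs(y_true) < 1e-9, np.nan, y_true)
    mape = float(np.nanmean(np.abs(err / safe)) * 100.0)
    mean_y = float(np.mean(y_true))
    rrmse = float(rmse / mean_y * 100.0) if mean_y != 0 else float("nan")
    sst = float(((y_true - mean_y) ** 2).sum())
    if sst == 0:
        return MetricBundle(float("nan"), rmse, mae, mape, rrmse, r2_undefined=True)
    r2 = 1.0 - float((err**2).sum()) / sst
    return MetricBundle(r2, rmse, mae, mape, rrmse)


# ---------------------------------------------------------------------------
# Repeated runs, bootstrap uncertainty, significance
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Mean +/- SD over repeats plus bootstrap CIs on the fixed test set."""

    per_repeat: pd.DataFrame
    mean: pd.Series
    sd: pd.Series | None  # None when a single repeat makes SD undefined
    ci: dict[str, tuple[float, float]]
    n_repeats: int
    predictions: np.ndarray = field(repr=False, default=None)  # (repeats, n_test)
    y_true: np.ndarray = field(repr=False, default=None)


def repeated_evaluation(
    run: Callable[[int], tuple[np.ndarray, np.ndarray]],
    seeds: Sequence[int],
    n_boot: int = 1000,
    boot_seed: int = 0,
) -> EvaluationReport:
    """Repeat an experiment over seeds and summarize with uncertainty.

    ``run(seed)`` must evaluate one fresh initialization/augmentation on
    the *fixed* hold-out set and return (y_true, y_pred). The percentile
    CI resamples test positions (pooling residuals across repeats) 1000
    times for R^2 and RMSE.
    """
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    preds, y_ref = [], None
    rows = []
    for seed in seeds:
        y_true, y_pred = run(seed)
        y_true = np.asarray(y_true, dtype=float)
        if y_ref is None:
            y_ref = y_true
        elif not np.array_equal(y_ref, y_true):
            raise ValueError("the hold-out set must be fixed across repeats")
        preds.append(np.asarray(y_pred, dtype=float))
        rows.append(regression_metrics(y_true, y_pred).as_dict())
    per_repeat = pd.DataFrame(rows, index=seeds)
    mean = per_repeat.mean(axis=0)
    sd = per_repeat.std(axis=0, ddof=1) if len(seeds) > 1 else None
    pred_arr = np.stack(preds)
    rng = np.random.default_rng(boot_seed)
    n_test = len(y_ref)
    boot = {"r2": [], "rmse": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n_test, size=n_test)
        vals_r2, vals_rmse = [], []
        for p in pred_arr:
            m = regression_metrics(y_ref[idx], p[idx])
            vals_r2.append(m.r2)
            vals_rmse.append(m.rmse)
        boot["r2"].append(np.mean(vals_r2))
        boot["rmse"].append(np.mean(vals_rmse))
    ci = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in boot.items()
    }
    return EvaluationReport(
        per_repeat=per_repeat, mean=mean, sd=sd, ci=ci,
        n_repeats=len(seeds), predictions=pred_arr, y_true=y_ref,
    )


def paired_bootstrap_test(
    residuals_a, residuals_b, n: int = 1000, seed: int = 0,
    alternative: str = "a_better",
) -> float:
    """Paired bootstrap on squared residuals.

    One-sided ``a_better``: p is the fraction of resamples in which model
    A's mean squared residual is >= model B's (ties count toward >=), so
    a small p supports A being the better model. ``two_sided`` doubles
    the smaller tail.
    """
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("residual vectors must have equal length")
    rng = np.random.default_rng(seed)
    m = len(a)
    idx = rng.integers(0, m, size=(n, m))
    msa = (a[idx] ** 2).mean(axis=1)
    msb = (b[idx] ** 2).mean(axis=1)
    p_a = float(np.mean(msa >= msb))
    if alternative == "a_better":
        return p_a
    if alternative == "b_better":
        return float(np.mean(msb >= msa))
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_a, np.mean(msb >= msa))))
    raise ValueError(f"unknown alternative {alternative!r}")


def input_size_study(
    samples: Sequence[TemporalSample],
    sizes: Sequence[int],
    base_config,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy vs input size for the image-mode hybrid.

    For each size the per-stage patches are resized, the hybrid is
    trained afresh ``n_repeats`` times on the fixed point-level split,
    and mean R^2/RMSE are reported next to the pixel-count ratio versus
    the smallest size. Timing columns are informational only.
    """
    import dataclasses

    from canopylai.model import CNNGRURegressor
    from canopylai.pipeline import assemble_image_inputs

    sizes = list(sizes)
    if any((not float(s).is_integer()) or s < 1 for s in sizes):
        raise ValueError("sizes must be positive integers")
    plan = split(samples, mode="point", seed=seed)
    tr_idx, te_idx = split_indices(plan, samples)
    rows = []
    base_px = min(sizes) ** 2
    for size in sizes:
        inputs, y = assemble_image_inputs(samples, image_size=size)
        tr_in = {k: v[tr_idx] for k, v in inputs.items()}
        te_in = {k: v[te_idx] for k, v in inputs.items()}
        r2s, rmses, secs = [], [], []
        for rep in range(n_repeats):
            cfg = dataclasses.replace(
                base_config, input_mode="image", image_size=size,
                image_channels=inputs["image"].shape[1],
                sequence_dim=inputs["sequence"].shape[2],
                seed=seed + rep,
            )
            model = CNNGRURegressor(cfg)
            t0 = time.perf_counter()
            model.fit(tr_in, y[tr_idx])
            secs.append(time.perf_counter() - t0)
            m = regression_metrics(y[te_idx], model.predict(te_in))
            r2s.append(m.r2)
            rmses.append(m.rmse)
        rows.append(
            {
                "size": size,
                "pixel_ratio": size**2 / base_px,
                "r2": float(np.mean(r2s)),
                "rmse": float(np.mean(rmses)),
                "train_seconds": float(np.mean(secs)),
            }
        )
    return pd.DataFrame(rows)
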