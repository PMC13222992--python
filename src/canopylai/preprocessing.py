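"""Radiometric calibration, cross-date normalization and table prep.

Raw UAV frames carry digital numbers (DN), the camera's photoelectric
response, not surface reflectance. Calibration fits a monotone response
curve from a grayscale panel photographed at flight altitude and inverts
it per pixel. Residual cross-date illumination differences (solar angle,
atmosphere) are removed by matching each date's histogram to a reference
date. Feature tables are min-max normalized with statistics fit on
training rows only, and time series with a single missing phenological
stage are filled by interpolation from the adjacent stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from skimage.exposure import match_histograms

from canopylai.types import BANDS, META_COLUMNS, RGBPatch, TemporalSample
from canopylai.synthdata import PanelObservations

__all__ = [
    "ResponseCurve",
    "NormalizationStats",
    "MissingTimestepRejection",
    "fit_radiometric_response",
    "apply_radiometric_calibration",
    "histogram_match",
    "fit_normalization",
    "apply_normalization",
    "normalize_matrix",
    "fill_missing_timesteps",
    "fill_all",
    "feature_columns",
]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table = everything that is not metadata."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# Radiometric calibration
# ---------------------------------------------------------------------------


@dataclass
class ResponseCurve:
    """Monotone per-band DN -> relative-reflectance mapping.

    Piecewise-linear through the panel knots; outside the fitted DN domain
    the output clamps to the end reflectances (np.interp semantics), so
    results always lie in [0, 1].
    """

    dn_knots: np.ndarray  # (n_steps, 3)
    reflectance_knots: np.ndarray  # (n_steps, 3)

    @property
    def domain(self) -> tuple[np.ndarray, np.ndarray]:
        return self.dn_knots[0], self.dn_knots[-1]

    def __call__(self, dn: np.ndarray, band: int | str = 0) -> np.ndarray:
        if isinstance(band, str):
            band = BANDS.index(band)
        out = np.interp(
            np.asarray(dn, dtype=float),
            self.dn_knots[:, band],
            self.reflectance_knots[:, band],
        )
        return np.clip(out, 0.0, 1.0)


def fit_radiometric_response(panel: PanelObservations) -> ResponseCurve:
    """Fit the monotone piecewise-linear DN -> reflectance curve.

    Raises a data error naming the offending band and step if the panel
    pairs are not strictly increasing.
    """
    dn = np.asarray(panel.dn, dtype=float)
    refl = np.asarray(panel.reflectance, dtype=float)
    if dn.shape[0] < 2:
        raise ValueError("need at least 2 panel steps per band")
    for b, name in enumerate(BANDS):
        for arr, what in ((dn, "DN"), (refl, "reflectance")):
            bad = np.nonzero(np.diff(arr[:, b]) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"non-monotone panel {what} in band {name} at step {bad[0] + 1}"
                )
    return ResponseCurve(dn_knots=dn, reflectance_knots=np.clip(refl, 0.0, 1.0))


def apply_radiometric_calibration(image: RGBPatch, curve: ResponseCurve) -> RGBPatch:
    """Convert a DN image to relative reflectance, band by band."""
    if image.units != "dn":
        raise ValueError("image is not in DN units")
    if curve.dn_knots.shape[1] != image.values.shape[2]:
        raise ValueError("band count mismatch between image and response curve")
    out = np.empty_like(image.values)
    for b in range(image.values.shape[2]):
        out[:, :, b] = curve(image.values[:, :, b], band=b)
    return image.copy_with(values=out, units="reflectance")


# ---------------------------------------------------------------------------
# Histogram matching
# ---------------------------------------------------------------------------


def histogram_match(image: RGBPatch, reference: RGBPatch) -> RGBPatch:
    """Match each band's empirical CDF to the reference date's.

    Exact quantile mapping (monotone), the standard relative radiometric
    normalization when a physical reference is unavailable per date.
    """
    if image.values.shape[2] != reference.values.shape[2]:
        raise ValueError("band count mismatch")
    if image.values.size == 0:
        raise ValueError("empty image")
    matched = match_histograms(image.values, reference.values, channel_axis=2)
    return image.copy_with(values=np.asarray(matched, dtype=float))


# ---------------------------------------------------------------------------
# Feature normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationStats:
    """Per-feature min/max fit on training rows only."""

    mins: pd.Series
    maxs: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.mins.index)


def fit_normalization(table: pd.DataFrame) -> NormalizationStats:
    cols = feature_columns(table)
    if not cols:
        raise ValueError("table has no feature columns")
    sub = table[cols].astype(float)
    return NormalizationStats(mins=sub.min(axis=0), maxs=sub.max(axis=0))


def apply_normalization(table: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Min-max scale features to [0, 1] on the fitted range.

    Constant features map to 0. Values outside the fitted range map
    outside [0, 1] deliberately — out-of-range signal on test rows is
    preserved, not clamped.
    """
    cols = feature_columns(table)
    unknown = [c for c in cols if c not in stats.mins.index]
    if unknown:
        raise KeyError(f"features not covered by normalization stats: {unknown}")
    out = table.copy()
    for c in cols:
        span = stats.maxs[c] - stats.mins[c]
        if span == 0:
            out[c] = 0.0
        else:
            out[c] = (table[c].astype(float) - stats.mins[c]) / span
    return out


def normalize_matrix(
    matrices: np.ndarray, stats: NormalizationStats | None = None
) -> tuple[np.ndarray, NormalizationStats]:
    """Min-max scale a stack of F x L feature matrices along the feature axis.

    ``matrices`` has shape (N, F, L); statistics pool all timesteps. If
    ``stats`` is given it is applied, otherwise fit-and-apply.
    """
    arr = np.asarray(matrices, dtype=float)
    if stats is None:
        flat = arr.transpose(1, 0, 2).reshape(arr.shape[1], -1)
        mins = pd.Series(flat.min(axis=1))
        maxs = pd.Series(flat.max(axis=1))
        stats = NormalizationStats(mins=mins, maxs=maxs)
    span = (stats.maxs.to_numpy() - stats.mins.to_numpy())[None, :, None]
    lo = stats.mins.to_numpy()[None, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span == 0, 0.0, (arr - lo) / np.where(span == 0, 1.0, span))
    return out, stats


# ---------------------------------------------------------------------------
# Missing timesteps
# ---------------------------------------------------------------------------


@dataclass
class MissingTimestepRejection:
    """Return state for samples with too many missing stages."""

    sample: TemporalSample
    reason: str


def fill_missing_timesteps(
    sample: TemporalSample,
) -> TemporalSample | MissingTimestepRejection:
    """Fill a single missing stage; reject samples missing more than one.

    An interior gap is filled with the pixelwise (or featurewise) mean of
    its two neighbouring stages — linear interpolation on the stage axis.
    An edge gap takes the nearest present stage's values. Samples with
    more than one missing stage are excluded rather than imputed.
    """
    missing = [i for i, p in enumerate(sample.patches) if p is None]
    if not missing:
        return sample
    if len(missing) > 1:
        return MissingTimestepRejection(
            sample, f"{len(missing)} missing time steps (more than 1)"
        )
    (idx,) = missing
    patches = list(sample.patches)
    n = len(patches)
    if 0 < idx < n - 1:
        left, right = patches[idx - 1], patches[idx + 1]
        values = 0.5 * (left.values + right.values)
        source = left
    else:
        source = patches[idx + 1] if idx == 0 else patches[idx - 1]
        values = source.values.copy()
    patches[idx] = source.copy_with(values=values, stage=idx, date=f"filled-{idx}")
    out = TemporalSample(
        point_id=sample.point_id,
        patches=patches,
        label=sample.label,
        stage_lais=sample.stage_lais,
        synthetic=sample.synthetic,
        parent_point_ids=sample.parent_point_ids,
    )
    return out


def fill_all(samples: Iterable[TemporalSample]) -> tuple[list[TemporalSample], list[MissingTimestepRejection]]:
    """Apply :func:`fill_missing_timesteps` to a dataset, partitioning output."""
    kept, rejected = [], []
    for s in samples:
        out = fill_missing_timesteps(s)
        (rejected if isinstance(out, MissingTimestepRejection) else kept).append(out)
    return kept, rejected
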