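"""RGB spectral parameters and GLCM texture statistics.

The spectral set comprises the three band values plus 23 visible-band
vegetation indices (chromatic coordinates, ratio and difference indices,
excess-colour indices, etc.) — 26 parameters in all. NIR-dependent
indices such as NDVI are out of scope: the emulated platform carries no
near-infrared sensor.

Texture is summarized through the gray-level co-occurrence matrix (GLCM)
per band: pixel values are quantized to ``levels`` equal-width gray
levels, co-occurrences accumulated symmetrically for a fixed displacement
vector, and eight Haralick statistics (mean, variance, homogeneity,
contrast, dissimilarity, entropy, second moment, correlation) derived
from the normalized joint distribution. The default 9 x 9 window with a
(2, 2) displacement corresponds to a 7.47 cm footprint and 1.66 cm step
at the nominal 0.83 cm/pixel resolution — the scale of a single mature
leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from canopylai.types import BANDS, RGBPatch, TemporalSample

__all__ = [
    "SPECTRAL_NAMES",
    "TEXTURE_STATS",
    "FeatureConfig",
    "SpectralFeatureVector",
    "GLCMatrix",
    "TextureFeatureVector",
    "compute_spectral_features",
    "compute_glcm",
    "compute_texture_features",
    "extract_patch_features",
    "build_feature_table",
    "sample_feature_matrix",
    "texture_feature_names",
    "all_feature_names",
    "window_footprint",
    "texture_sensitivity_sweep",
]

SPECTRAL_NAMES = (
    "R", "G", "B",
    "RCC", "GCC", "BCC",
    "GRRI", "GBRI", "RBRI",
    "GRVI", "NDI", "WI", "IKAW", "GLI", "VARI",
    "EXR", "EXG", "EXB",
    "IPCA", "CIVE",
    "SDGB", "SDRB", "SDRG",
    "MRGB", "SGRB", "CI",
)

TEXTURE_STATS = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEC", "COR")


def texture_feature_names() -> list[str]:
    """Texture feature names, ``<stat>_<band>``, 8 stats x 3 bands = 24."""
    return [f"{stat}_{band}" for band in BANDS for stat in TEXTURE_STATS]


def all_feature_names() -> list[str]:
    """The full 50-entry candidate feature set (26 spectral + 24 texture)."""
    return list(SPECTRAL_NAMES) + texture_feature_names()


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings.

    ``feature_subset`` of ``None`` keeps the full candidate set; after
    screening, pass the retained names. ``aggregation`` controls whether
    band values are averaged over the patch before index computation
    (default, one vector per sampling point) or indices are computed per
    pixel and then averaged.
    """

    feature_subset: tuple[str, ...] | None = None
    aggregation: str = "mean-then-index"  # or "index-then-mean"
    glcm_window: int = 9
    glcm_displacement: tuple[int, int] = (2, 2)
    glcm_levels: int = 32
    #: average the four principal displacement directions instead of the
    #: single configured vector
    four_directions: bool = False

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean-then-index", "index-then-mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.feature_subset is not None:
            unknown = set(self.feature_subset) - set(all_feature_names())
            if unknown:
                raise KeyError(f"unknown feature names: {sorted(unknown)}")


@dataclass
class SpectralFeatureVector:
    """The 26 spectral parameters plus degenerate-denominator counters."""

    values: dict[str, float]
    degenerate_counts: dict[str, int] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(SPECTRAL_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# Spectral parameters
# ---------------------------------------------------------------------------


def _safe_div(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, int]:
    """Elementwise division with the zero-denominator policy: 0, counted."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    bad = den == 0
    out = np.divide(num, np.where(bad, 1.0, den))
    out = np.where(bad, 0.0, out)
    return out, int(np.count_nonzero(bad))


def _spectral_from_bands(R, G, B) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    v: dict[str, np.ndarray] = {}
    deg: dict[str, int] = {}
    total = R + G + B
    v["R"], v["G"], v["B"] = R, G, B
    v["RCC"], deg["RCC"] = _safe_div(R, total)
    v["GCC"], deg["GCC"] = _safe_div(G, total)
    v["BCC"], deg["BCC"] = _safe_div(B, total)
    v["GRRI"], deg["GRRI"] = _safe_div(G, R)
    v["GBRI"], deg["GBRI"] = _safe_div(G, B)
    v["RBRI"], deg["RBRI"] = _safe_div(R, B)
    v["GRVI"], deg["GRVI"] = _safe_div(G - R, G + R)
    # the +0.01 in the denominator is the index's own guard
    v["NDI"], deg["NDI"] = _safe_div(v["RCC"] - v["GCC"], v["RCC"] + v["GCC"] + 0.01)
    v["WI"], deg["WI"] = _safe_div(G - B, R - G)
    v["IKAW"], deg["IKAW"] = _safe_div(R - B, R + B)
    v["GLI"], deg["GLI"] = _safe_div(2 * G - R - B, 2 * G + R + B)
    v["VARI"], deg["VARI"] = _safe_div(G - R, G + R - B)
    v["EXR"] = 1.4 * v["RCC"] - v["GCC"]
    v["EXG"] = 2 * v["GCC"] - v["RCC"] - v["BCC"]
    v["EXB"] = 1.4 * v["BCC"] - v["GCC"]
    v["IPCA"] = 0.994 * np.abs(R - B) + 0.961 * np.abs(G - B) + 0.914 * np.abs(G - R)
    v["CIVE"] = 0.441 * R - 0.881 * G + 0.385 * B + 18.78745
    v["SDGB"] = G - B
    v["SDRB"] = R - B
    v["SDRG"] = R - G
    v["MRGB"] = total / 3.0
    v["SGRB"] = 2 * G - R - B
    v["CI"], deg["CI"] = _safe_div(R - B, R)
    return v, deg


def compute_spectral_features(
    patch: RGBPatch, aggregation: str = "mean-then-index"
) -> SpectralFeatureVector:
    """All 26 spectral parameters of a patch.

    With the default aggregation the patch's band means are computed
    first and the indices evaluated once on the mean triple — the
    sampling-point-level convention. ``index-then-mean`` evaluates every
    index per pixel and averages the resulting maps.
    """
    if patch.values.size == 0:
        raise ValueError("empty patch")
    if aggregation == "mean-then-index":
        R, G, B = (patch.values[:, :, i].mean() for i in range(3))
        v, deg = _spectral_from_bands(np.float64(R), np.float64(G), np.float64(B))
        values = {k: float(v[k]) for k in SPECTRAL_NAMES}
    elif aggregation == "index-then-mean":
        R, G, B = (patch.values[:, :, i] for i in range(3))
        v, deg = _spectral_from_bands(R, G, B)
        values = {k: float(np.mean(v[k])) for k in SPECTRAL_NAMES}
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return SpectralFeatureVector(values=values, degenerate_counts=deg)


# ---------------------------------------------------------------------------
# GLCM and texture statistics
# ---------------------------------------------------------------------------


@dataclass
class GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    p: np.ndarray  # (levels, levels) joint probabilities
    levels: int
    window_shape: tuple[int, int]
    displacement: tuple[int, int]


def quantize(band: np.ndarray, levels: int, value_range=None) -> np.ndarray:
    """Equal-width quantization of a band to integer gray levels."""
    band = np.asarray(band, dtype=float)
    if value_range is None:
        lo, hi = band.min(), band.max()
    else:
        lo, hi = value_range
    if hi <= lo:
        return np.zeros(band.shape, dtype=np.intp)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    band_window: np.ndarray,
    levels: int = 32,
    displacement: tuple[int, int] = (2, 2),
    value_range=None,
) -> GLCMatrix:
    """Symmetric co-occurrence probabilities for one displacement vector.

    The window is quantized to ``levels`` equal-width bins over its own
    value range (or ``value_range`` if given); each pixel pair separated
    by ``displacement`` contributes to P(i, j) and P(j, i).
    """
    band_window = np.asarray(band_window, dtype=float)
    if band_window.ndim != 2:
        raise ValueError("band window must be 2-D")
    dr, dc = displacement
    h, w = band_window.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(
            f"window {band_window.shape} smaller than displacement {displacement}"
        )
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    q = quantize(band_window, levels, value_range)
    r0 = slice(max(-dr, 0), h - max(dr, 0))
    c0 = slice(max(-dc, 0), w - max(dc, 0))
    r1 = slice(max(dr, 0), h + min(dr, 0) or None)
    c1 = slice(max(dc, 0), w + min(dc, 0) or None)
    a = q[r0, c0].ravel()
    b = q[r1, c1].ravel()
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)
    p = counts / counts.sum()
    return GLCMatrix(
        p=p, levels=levels, window_shape=(h, w), displacement=(dr, dc)
    )


@dataclass
class TextureFeatureVector:
    """The 8 Haralick statistics of one GLCM."""

    values: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(TEXTURE_STATS), dtype=float)


def compute_texture_features(glcm: GLCMatrix) -> TextureFeatureVector:
    """Haralick statistics of a normalized GLCM.

    Conventions: ``0 * log 0 = 0`` in the entropy; correlation is 0 when
    either marginal standard deviation vanishes; level indices run from
    0, so the mean/variance are in gray-level units.
    """
    p = glcm.p
    n = glcm.levels
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(n) * px).sum())
    mu_y = float((np.arange(n) * py).sum())
    sig_x = float(np.sqrt(((np.arange(n) - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((np.arange(n) - mu_y) ** 2 * py).sum()))
    diff = i - j
    v: dict[str, float] = {}
    v["MEA"] = float((i * p).sum())
    v["VAR"] = float(((i - v["MEA"]) ** 2 * p).sum())
    v["HOM"] = float((p / (1.0 + diff**2)).sum())
    v["CON"] = float((diff**2 * p).sum())
    v["DIS"] = float((np.abs(diff) * p).sum())
    nz = p > 0
    v["ENT"] = float(-(p[nz] * np.log(p[nz])).sum())
    v["SEC"] = float((p**2).sum())
    if sig_x * sig_y > 0:
        v["COR"] = float(((i * j * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        v["COR"] = 0.0
    return TextureFeatureVector(values=v)


_FOUR_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _window_origins(extent: int, window: int) -> list[int]:
    """Non-overlapping tiling origins; a short patch gets one centred window."""
    if extent < window:
        return [0]
    return list(range(0, extent - window + 1, window))


def _band_texture(band: np.ndarray, config: FeatureConfig) -> dict[str, float]:
    """Patch-aggregated texture stats: GLCM per window, stats averaged."""
    h, w = band.shape
    win = config.glcm_window
    wh, ww = min(win, h), min(win, w)
    dr, dc = config.glcm_displacement
    if config.four_directions:
        d = max(abs(dr), abs(dc))
        displacements = [(d * a, d * b) for a, b in _FOUR_DIRECTIONS]
    else:
        displacements = [(dr, dc)]
    value_range = (band.min(), band.max())  # common quantization across windows
    acc = {stat: 0.0 for stat in TEXTURE_STATS}
    count = 0
    for r in _window_origins(h, wh):
        for c in _window_origins(w, ww):
            window = band[r : r + wh, c : c + ww]
            for disp in displacements:
                if window.shape[0] <= abs(disp[0]) or window.shape[1] <= abs(disp[1]):
                    continue
                glcm = compute_glcm(
                    window, config.glcm_levels, disp, value_range=value_range
                )
                stats = compute_texture_features(glcm)
                for stat in TEXTURE_STATS:
                    acc[stat] += stats.values[stat]
                count += 1
    if count == 0:
        raise ValueError("patch too small for the configured displacement")
    return {stat: acc[stat] / count for stat in TEXTURE_STATS}


def extract_patch_features(
    patch: RGBPatch, config: FeatureConfig = FeatureConfig()
) -> pd.Series:
    """The candidate (or configured subset of the) feature vector of a patch.

    Spectral parameters are computed at the patch level; texture
    statistics are computed per sliding GLCM window and averaged, per
    band. Ordering is stable: the 26 spectral names, then
    ``<stat>_<band>`` for R, G, B.
    """
    names = (
        list(config.feature_subset)
        if config.feature_subset is not None
        else all_feature_names()
    )
    need_spectral = any(n in SPECTRAL_NAMES for n in names)
    need_texture = any("_" in n for n in names)
    values: dict[str, float] = {}
    if need_spectral:
        values.update(compute_spectral_features(patch, config.aggregation).values)
    if need_texture:
        for b, band_name in enumerate(BANDS):
            if not any(n.endswith(f"_{band_name}") for n in names):
                continue
            stats = _band_texture(patch.values[:, :, b], config)
            for stat, val in stats.items():
                values[f"{stat}_{band_name}"] = val
    return pd.Series({n: values[n] for n in names}, dtype=float)


def build_feature_table(
    samples: Iterable[TemporalSample], config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Long feature table with one row per (point, stage).

    Rows carry the metadata columns ``point_id``, ``stage``, ``lai``
    (the per-stage true LAI when the generator recorded it, else the
    sample label) plus all configured features. Missing stages are
    skipped — fill them first if the time series must stay complete.
    """
    rows = []
    for s in samples:
        for stage, patch in enumerate(s.patches):
            if patch is None:
                continue
            feats = extract_patch_features(patch, config)
            lai = (
                s.stage_lais[stage]
                if s.stage_lais is not None
                else s.label
            )
            row = {"point_id": s.point_id, "stage": stage, "lai": float(lai)}
            row.update(feats.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def sample_feature_matrix(
    sample: TemporalSample, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """F x L feature matrix of one complete sample (columns = stages)."""
    cols = []
    for patch in sample.patches:
        if patch is None:
            raise ValueError("sample has missing stages; fill or reject it first")
        cols.append(extract_patch_features(patch, config).to_numpy())
    return np.stack(cols, axis=1)


def window_footprint(window_px: int, resolution_cm_per_px: float) -> float:
    """Physical side length (cm) of a processing window."""
    if window_px <= 0 or resolution_cm_per_px <= 0:
        raise ValueError("window size and resolution must be positive")
    return window_px * resolution_cm_per_px


def texture_sensitivity_sweep(
    samples: Sequence[TemporalSample],
    windows: Sequence[int] = (3, 5, 7, 9, 11),
    displacements: Sequence[int] = (1, 2, 3),
    base_config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature-LAI correlation across GLCM window/displacement settings.

    For every (window, displacement) pair the 24 texture features are
    computed on each sample's final-stage patch and correlated with the
    sample labels. One row per setting: the signed Pearson r per feature
    plus the mean absolute correlation across features.
    """
    labels = np.array([s.label for s in samples], dtype=float)
    rows = []
    for win in windows:
        for disp in displacements:
            row: dict[str, float] = {"window": win, "displacement": disp}
            if disp >= win:
                # no co-occurring pair fits in the window; the setting is
                # reported but carries no correlations
                for name in texture_feature_names():
                    row[name] = np.nan
                row["mean_abs_r"] = np.nan
                rows.append(row)
                continue
            cfg = FeatureConfig(
                feature_subset=tuple(texture_feature_names()),
                glcm_window=win,
                glcm_displacement=(disp, disp),
                glcm_levels=base_config.glcm_levels,
                four_directions=base_config.four_directions,
            )
            feats = np.stack(
                [
                    extract_patch_features(s.patches[-1], cfg).to_numpy()
                    for s in samples
                ]
            )
            rs = []
            for k, name in enumerate(texture_feature_names()):
                col = feats[:, k]
                if col.std() == 0 or labels.std() == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(col, labels)[0, 1])
                row[name] = r
                rs.append(abs(r))
            row["mean_abs_r"] = float(np.mean(rs))
            rows.append(row)
    return pd.DataFrame(rows)
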