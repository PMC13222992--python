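"""LAI map production and spatial quality metrics.

A trained regressor is swept over the scene in tiles; each tile's
prediction is written to its footprint, overlaps are averaged, and edge
tiles read reflection-padded pixels so the map covers the full scene.
Map quality is scored by four complementary statistics: global Moran's I
(spatial autocorrelation: +1 smooth, -1 perfectly alternating), SSIM
against a reference map (structural fidelity), the coefficient of
variation (spread relative to level) and the Shannon entropy of the
value histogram (heterogeneity / noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from canopylai.types import RGBPatch

__all__ = [
    "LAIMap",
    "sliding_window_map",
    "morans_i",
    "ssim",
    "spatial_cv",
    "spatial_entropy",
    "write_map_geotiff",
]


@dataclass
class LAIMap:
    """A predicted LAI raster with its grid metadata."""

    values: np.ndarray  # (H, W)
    cell_size_cm: float = 0.83
    origin: tuple[float, float] = (0.0, 0.0)
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LAI map contains non-finite values")


def _as_array(m) -> np.ndarray:
    return m.values if isinstance(m, LAIMap) else np.asarray(m, dtype=float)


def sliding_window_map(
    model: Callable[[list[RGBPatch]], float],
    scenes: Sequence[np.ndarray],
    window: int,
    stride: int | None = None,
    resolution_cm: float = 0.83,
    truth: np.ndarray | None = None,
) -> LAIMap:
    """Tile the multi-date scene and predict LAI per tile.

    ``model`` maps the L per-date tile crops (as reflectance patches) to
    one LAI value; the pipeline module builds such a callable from a
    trained regressor plus its feature config and normalization stats.
    ``stride`` defaults to the window (non-overlapping tiling); smaller
    strides overlap and average.
    """
    scenes = [np.asarray(s, dtype=float) for s in scenes]
    h, w = scenes[0].shape[:2]
    if window > h or window > w:
        raise ValueError(f"window {window} larger than scene {(h, w)}")
    stride = window if stride is None else stride
    pad_h = (-(h - window)) % stride
    pad_w = (-(w - window)) % stride
    padded = [
        np.pad(s, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect") for s in scenes
    ]
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for r in range(0, h + pad_h - window + 1, stride):
        for c in range(0, w + pad_w - window + 1, stride):
            crops = [
                RGBPatch(
                    s[r : r + window, c : c + window],
                    units="reflectance",
                    resolution_cm=resolution_cm,
                    stage=t,
                )
                for t, s in enumerate(padded)
            ]
            val = float(model(crops))
            r1, c1 = min(r + window, h), min(c + window, w)
            acc[r:r1, c:c1] += val
            cnt[r:r1, c:c1] += 1.0
    return LAIMap(values=acc / cnt, cell_size_cm=resolution_cm, truth=truth)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

_ROOK = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN = _ROOK + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def morans_i(lai_map, weights: str = "queen") -> float:
    """Global Moran's I on the grid with row-standardized contiguity weights.

    Queen contiguity (8 neighbours) by default; ``rook`` restricts to the
    4 orthogonal neighbours. Zero variance makes the statistic undefined.
    """
    x = _as_array(lai_map)
    if x.ndim != 2 or min(x.shape) < 2:
        raise ValueError("need a 2-D grid of at least 2x2 cells")
    z = x - x.mean()
    denom = float((z**2).sum())
    if denom == 0:
        raise ValueError("Moran's I undefined for a zero-variance map")
    offsets = _QUEEN if weights == "queen" else _ROOK if weights == "rook" else None
    if offsets is None:
        raise ValueError(f"unknown weights {weights!r}")
    h, w = x.shape
    neigh_sum = np.zeros_like(z)
    deg = np.zeros_like(z)
    for dr, dc in offsets:
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        neigh_sum[r0:r1, c0:c1] += z[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        deg[r0:r1, c0:c1] += 1.0
    # row standardization: each cell's weights sum to one
    num = float((z * neigh_sum / deg).sum())
    return num / denom


def ssim(lai_map, reference) -> float:
    """Mean structural similarity with a 7x7 uniform window.

    Standard stabilizers K1=0.01, K2=0.03 on the dynamic range of the
    reference map.
    """
    x = _as_array(lai_map)
    ref = _as_array(reference)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    data_range = float(ref.max() - ref.min())
    if data_range == 0:
        raise ValueError("reference map has zero dynamic range")
    return float(
        structural_similarity(
            x, ref, win_size=7, gaussian_weights=False,
            data_range=data_range, K1=0.01, K2=0.03,
        )
    )


def spatial_cv(lai_map) -> float:
    """Population standard deviation over mean of the predicted values."""
    x = _as_array(lai_map)
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("CV undefined for a zero-mean map")
    return float(x.std()) / mean


def spatial_entropy(lai_map, bins: int = 64) -> float:
    """Shannon entropy (nats) of the equal-width value histogram."""
    x = _as_array(lai_map).ravel()
    if x.size == 0:
        raise ValueError("empty map")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def write_map_geotiff(path, lai_map: LAIMap) -> None:
    import tifffile

    px_per_cm = 1.0 / lai_map.cell_size_cm
    tifffile.imwrite(
        str(path),
        lai_map.values.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
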