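"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Metadata columns of a feature table; everything else is a feature.
META_COLUMNS = ("point_id", "stage", "date", "lai")

#: Band order of all rasters handled by the package.
BANDS = ("R", "G", "B")


@dataclass(eq=False)
class RGBPatch:
    """An H x W x 3 raster of DN counts or relative reflectance.

    Parameters
    ----------
    values : ndarray, shape (H, W, 3)
        Pixel values in R, G, B band order.
    units : {"dn", "reflectance"}
        Whether values are raw sensor digital numbers or calibrated
        dimensionless relative reflectance in [0, 1].
    resolution_cm : float
        Ground sampling distance in cm/pixel.
    stage : int or None
        Phenological stage index (0-based) this patch was acquired at.
    date : str or None
        Acquisition date tag.
    """

    values: np.ndarray
    units: str = "reflectance"
    resolution_cm: float = 0.83
    stage: int | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) raster, got {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("patch must contain at least one pixel")
        if self.units not in ("dn", "reflectance"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D array; ``name`` is 'R', 'G' or 'B'."""
        return self.values[:, :, BANDS.index(name)]

    def copy_with(self, **kwargs) -> "RGBPatch":
        out = replace(self, **kwargs)
        if "values" not in kwargs:
            out.values = self.values.copy()
        return out


@dataclass(eq=False)
class TemporalSample:
    """One labelled time series for a sampling point.

    Holds the L stage-ordered patches (some possibly missing), the
    per-stage true LAI trajectory where known, and the regression label —
    the final-stage LAI. ``feature_matrix`` caches the F x L matrix of
    extracted features once computed. ``synthetic`` marks samples created
    by augmentation; such samples carry every parent's point id in
    ``parent_point_ids`` so split/fold logic can keep them on the correct
    side of a train/test boundary.
    """

    point_id: int
    patches: list[RGBPatch | None]
    label: float
    stage_lais: Sequence[float] | None = None
    feature_matrix: np.ndarray | None = None
    feature_names: Sequence[str] | None = None
    synthetic: bool = False
    parent_point_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.parent_point_ids:
            self.parent_point_ids = (self.point_id,)

    @property
    def n_stages(self) -> int:
        return len(self.patches)

    @property
    def n_missing(self) -> int:
        return sum(p is None for p in self.patches)

    @property
    def complete(self) -> bool:
        return self.n_missing == 0
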