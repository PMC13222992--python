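"""Synthetic orchard scenes, calibration panels and labelled time series.

The generator emulates the statistical structure of multi-date UAV RGB
imagery over a drip-irrigated orchard planted in a wide-row / narrow-plant
grid: canopies rendered as ellipses on a regular row grid over a bare-soil
background, canopy greenness and internal texture coupled to a latent
leaf-area index (LAI), a logistic LAI growth trajectory over three
phenological stages (growth, maturity, fruit-bearing) with a point-level
random effect, per-date global illumination gain/bias, and a nonlinear
camera response anchored to a 24-step grayscale calibration panel.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the config, so identical (config, seed) pairs produce bit-identical
rasters and labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from canopylai.types import RGBPatch, TemporalSample

__all__ = [
    "SceneConfig",
    "SceneBundle",
    "PanelConfig",
    "PanelObservations",
    "SceneSizingError",
    "generate_orchard_scene",
    "generate_panel_observations",
    "generate_time_series_dataset",
    "render_lai_patch",
    "bundle_to_samples",
    "ContinuousScene",
    "generate_continuous_scene",
    "continuous_samples",
    "make_benchmark",
    "dn_response",
    "to_dn",
    "write_scene_geotiff",
    "write_labels_csv",
    "config_to_yaml",
]


class SceneSizingError(ValueError):
    """Requested points do not fit in the configured scene."""


@dataclass(frozen=True)
class SceneConfig:
    """Study-design parameters of the synthetic orchard.

    Defaults reflect the emulated field campaign: 96 sampling points, a
    4.5 m x 1.5 m wide-row planting grid, three phenological stages, LAI
    between 3.3 and 5.2 m^2/m^2, and 0.83 cm/pixel imagery. ``scene_shape``
    of ``None`` auto-sizes the scene to fit the requested points at the
    configured spacing.
    """

    scene_shape: tuple[int, int] | None = None
    resolution_cm: float = 0.83
    row_spacing_m: float = 4.5
    plant_spacing_m: float = 1.5
    n_points: int = 96
    n_stages: int = 3
    stage_names: tuple[str, ...] = ("growth", "maturity", "fruit-bearing")
    lai_range: tuple[float, float] = (3.3, 5.2)
    #: slope of the logistic greenness-vs-LAI link (per LAI unit)
    greenness_slope: float = 1.8
    #: LAI at which the greenness logistic is centred
    greenness_offset: float = 4.25
    #: multiplicative amplitude of the Gaussian-blob canopy texture
    texture_noise: float = 0.04
    gain_range: tuple[float, float] = (0.92, 1.08)
    bias_range: tuple[float, float] = (-0.02, 0.02)
    soil_reflectance: tuple[float, float, float] = (0.28, 0.22, 0.16)
    patch_size: int = 48
    #: SD of the point-level random intercept on the LAI trajectory
    point_sigma: float = 0.15
    #: SD of independent per-(point, stage) trajectory noise
    trajectory_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_cm <= 0:
            raise ValueError("resolution must be positive")
        lo, hi = self.lai_range
        if not (0 < lo < hi <= 10):
            raise ValueError("LAI range must be within (0, 10] and ordered")
        if self.n_stages < 1:
            raise ValueError("need at least one stage")
        if self.n_points < 1:
            raise ValueError("need at least one point")
        if self.patch_size < 1:
            raise ValueError("patch size must be positive")

    @property
    def row_spacing_px(self) -> int:
        return max(int(round(self.row_spacing_m * 100.0 / self.resolution_cm)), 1)

    @property
    def plant_spacing_px(self) -> int:
        return max(int(round(self.plant_spacing_m * 100.0 / self.resolution_cm)), 1)


@dataclass
class SceneBundle:
    """Everything :func:`generate_orchard_scene` produces for one run."""

    config: SceneConfig
    scenes: list[np.ndarray]  # per date, (H, W, 3) reflectance
    patches: dict[tuple[int, int], RGBPatch]  # (point_id, stage) -> crop
    points_rc: np.ndarray  # (n_points, 2) row/col centres
    stage_lais: np.ndarray  # (n_points, n_stages)
    labels: np.ndarray  # final-stage LAI per point
    truth_lai: np.ndarray  # (H, W) LAI field on the scene grid
    gains: np.ndarray  # per-date multiplicative gain
    biases: np.ndarray  # per-date additive bias


@dataclass(frozen=True)
class PanelConfig:
    """24-step grayscale calibration panel and camera response model."""

    n_steps: int = 24
    gamma: float = 0.6
    scale: float = 255.0
    noise_sd: float = 0.0
    reflectance_range: tuple[float, float] = (0.02, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("panel needs at least 2 steps")


@dataclass
class PanelObservations:
    """Ordered (DN, reflectance) pairs per band, darkest step first."""

    dn: np.ndarray  # (n_steps, 3)
    reflectance: np.ndarray  # (n_steps, 3)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.reflectance, axis=0) <= 0):
            raise ValueError("panel reflectances must be strictly increasing")
        if np.any(np.diff(self.dn, axis=0) <= 0):
            raise ValueError("panel DN values must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return self.dn.shape[0]


# ---------------------------------------------------------------------------
# LAI trajectories and the greenness link
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _stage_profile(n_stages: int, steepness: float = 1.5) -> np.ndarray:
    """Normalized logistic growth profile over stage indices, ending at 1."""
    if n_stages == 1:
        return np.ones(1)
    t = np.arange(n_stages, dtype=float)
    t0 = (n_stages - 1) / 2.0
    g = _sigmoid(steepness * (t - t0))
    g = (g - g[0]) / (g[-1] - g[0])
    return g


def _draw_trajectories(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_points, n_stages) logistic LAI trajectories within the LAI range."""
    lo, hi = config.lai_range
    final = rng.uniform(lo, hi, size=config.n_points)
    intercept = rng.normal(0.0, config.point_sigma, size=config.n_points)
    start = lo + 0.15 * (final - lo)
    profile = _stage_profile(config.n_stages)
    traj = start[:, None] + (final - start)[:, None] * profile[None, :]
    traj = traj + intercept[:, None]
    if config.trajectory_sigma > 0:
        traj = traj + rng.normal(0.0, config.trajectory_sigma, size=traj.shape)
    return np.clip(traj, lo, hi)


def leaf_reflectance(lai: float, config: SceneConfig) -> np.ndarray:
    """Expected (R, G, B) leaf-layer reflectance at a given LAI.

    Greenness follows a monotone logistic link in LAI; red and blue fall
    mildly as the canopy greens up, mimicking chlorophyll absorption.
    """
    s = _sigmoid(config.greenness_slope * (lai - config.greenness_offset))
    r = 0.12 - 0.03 * s
    g = 0.10 + 0.35 * s
    b = 0.08 - 0.02 * s
    return np.array([r, g, b])


def canopy_coverage(lai: float) -> float:
    """Within-crown gap filling, a Beer-Lambert style saturating function."""
    return float(1.0 - np.exp(-0.55 * lai))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render_canopy(
    raster: np.ndarray,
    centre: tuple[int, int],
    semi_axes: tuple[float, float],
    lai: float,
    config: SceneConfig,
    rng: np.random.Generator,
) -> None:
    """Draw one elliptical crown (in place) with LAI-coupled texture."""
    cy, cx = centre
    ay, ax = semi_axes
    h, w = raster.shape[:2]
    y0, y1 = max(int(cy - ay), 0), min(int(np.ceil(cy + ay)) + 1, h)
    x0, x1 = max(int(cx - ax), 0), min(int(np.ceil(cx + ax)) + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    if not mask.any():
        return
    cov = canopy_coverage(lai)
    leaf = leaf_reflectance(lai, config)
    soil = np.asarray(config.soil_reflectance)
    base = (1.0 - cov) * soil + cov * leaf
    block = raster[y0:y1, x0:x1]
    block[mask] = base
    if config.texture_noise > 0:
        lo, hi = config.lai_range
        rel = float(np.clip((lai - lo) / (hi - lo), 0.0, 1.0))
        amp = config.texture_noise * (0.3 + 0.7 * rel)
        # denser canopies carry finer leaf-scale texture: the blob
        # correlation length shrinks as LAI grows, so displacement-based
        # contrast statistics rise with LAI even after the GLCM's
        # observed-range quantization
        sigma = 3.0 - 2.4 * rel
        blob = gaussian_filter(rng.standard_normal(mask.shape), sigma=sigma)
        sd = blob.std()
        if sd > 0:
            blob = blob / sd
        block[mask] *= np.clip(1.0 + amp * blob[mask, None], 0.05, None)
    raster[y0:y1, x0:x1] = block


def _grid_layout(config: SceneConfig) -> tuple[tuple[int, int], np.ndarray]:
    """Place ``n_points`` crowns on the row grid; return scene shape + centres."""
    row_px, plant_px = config.row_spacing_px, config.plant_spacing_px
    n = config.n_points
    n_rows = max(int(np.ceil(np.sqrt(n * plant_px / row_px))), 1)
    n_cols = int(np.ceil(n / n_rows))
    height = n_rows * row_px
    width = n_cols * plant_px
    if config.scene_shape is not None:
        height, width = config.scene_shape
        n_rows = height // row_px
        n_cols = width // plant_px
        if n_rows * n_cols < n:
            raise SceneSizingError(
                f"scene {config.scene_shape} fits only {n_rows * n_cols} points "
                f"at {row_px}x{plant_px} px spacing; {n} requested"
            )
    centres = []
    for i in range(n):
        r, c = divmod(i, n_cols)
        centres.append((r * row_px + row_px // 2, c * plant_px + plant_px // 2))
    return (height, width), np.array(centres)


def generate_orchard_scene(config: SceneConfig) -> SceneBundle:
    """Render per-date orchard scenes with known LAI truth.

    Each sampling point is one crown; its greenness, coverage and texture
    amplitude follow the configured links to its latent per-stage LAI. A
    global illumination gain and bias drawn per date is applied after
    rendering. Patch crops centred on each crown are returned alongside a
    truth LAI field on the scene grid (patch footprints carry the point's
    LAI exactly, so patch means of the truth field equal the labels).
    """
    rng = np.random.default_rng(config.seed)
    (h, w), centres = _grid_layout(config)
    half = config.patch_size // 2
    if config.patch_size > min(config.row_spacing_px, config.plant_spacing_px):
        raise SceneSizingError("patch size exceeds crown spacing; crops would overlap")
    traj = _draw_trajectories(config, rng)
    gains = rng.uniform(*config.gain_range, size=config.n_stages)
    biases = rng.uniform(*config.bias_range, size=config.n_stages)

    ay = 0.42 * config.row_spacing_px
    ax = 0.42 * config.plant_spacing_px
    soil = np.asarray(config.soil_reflectance)
    lo, hi = config.lai_range

    scenes: list[np.ndarray] = []
    patches: dict[tuple[int, int], RGBPatch] = {}
    truth = np.full((h, w), 0.5 * (lo + hi))
    for pid, (cy, cx) in enumerate(centres):
        y0, x0 = cy - half, cx - half
        truth[y0 : y0 + config.patch_size, x0 : x0 + config.patch_size] = traj[pid, -1]

    for stage in range(config.n_stages):
        scene = np.empty((h, w, 3))
        scene[:] = soil
        if config.texture_noise > 0:
            speck = gaussian_filter(rng.standard_normal((h, w)), sigma=1.0)
            sd = speck.std()
            if sd > 0:
                scene *= np.clip(
                    1.0 + 0.3 * config.texture_noise * speck[:, :, None] / sd, 0.05, None
                )
        for pid, (cy, cx) in enumerate(centres):
            _render_canopy(scene, (cy, cx), (ay, ax), traj[pid, stage], config, rng)
        scene = scene * gains[stage] + biases[stage]
        scenes.append(scene)
        for pid, (cy, cx) in enumerate(centres):
            y0, x0 = cy - half, cx - half
            y1, x1 = y0 + config.patch_size, x0 + config.patch_size
            if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
                raise SceneSizingError("patch crop falls outside scene bounds")
            patches[(pid, stage)] = RGBPatch(
                scene[y0:y1, x0:x1].copy(),
                units="reflectance",
                resolution_cm=config.resolution_cm,
                stage=stage,
                date=f"date-{stage}",
            )

    return SceneBundle(
        config=config,
        scenes=scenes,
        patches=patches,
        points_rc=centres,
        stage_lais=traj,
        labels=traj[:, -1].copy(),
        truth_lai=truth,
        gains=gains,
        biases=biases,
    )


# ---------------------------------------------------------------------------
# Calibration panel and camera response
# ---------------------------------------------------------------------------


def generate_panel_observations(config: PanelConfig = PanelConfig()) -> PanelObservations:
    """Ordered panel (DN, reflectance) pairs under a gamma-type response.

    The anchor DN values follow ``DN = scale * reflectance**gamma`` with
    optional additive noise; noisy sequences are nudged monotone so the
    strictly-increasing panel invariant always holds.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.reflectance_range
    refl = np.linspace(lo, hi, config.n_steps)
    dn = config.scale * refl**config.gamma
    dn = np.repeat(dn[:, None], 3, axis=1)
    refl = np.repeat(refl[:, None], 3, axis=1)
    if config.noise_sd > 0:
        dn = dn + rng.normal(0.0, config.noise_sd, size=dn.shape)
        dn = np.maximum.accumulate(dn, axis=0)
        eps = 1e-6 * max(config.scale, 1.0)
        dn = dn + eps * np.arange(config.n_steps)[:, None]
    return PanelObservations(dn=dn, reflectance=refl)


def dn_response(panel: PanelObservations):
    """Forward camera response: reflectance -> DN.

    The sensor is modeled as monotone piecewise-linear through the panel's
    anchor points, so the inverse fitted from the same panel recovers
    reflectance exactly (to float precision) everywhere in the panel range.
    """

    def forward(values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.empty_like(values)
        for b in range(3):
            out[..., b] = np.interp(
                values[..., b], panel.reflectance[:, b], panel.dn[:, b]
            )
        return out

    return forward


def to_dn(patch: RGBPatch, panel: PanelObservations) -> RGBPatch:
    """Convert a reflectance patch to DN units via the panel's response."""
    if patch.units != "reflectance":
        raise ValueError("patch is already in DN units")
    dn = dn_response(panel)(patch.values)
    return patch.copy_with(values=dn, units="dn")


# ---------------------------------------------------------------------------
# Labelled time-series dataset
# ---------------------------------------------------------------------------


def _render_point_patch(
    lai: float, config: SceneConfig, rng: np.random.Generator, stage: int,
    gain: float, bias: float,
) -> RGBPatch:
    size = config.patch_size
    raster = np.empty((size, size, 3))
    raster[:] = np.asarray(config.soil_reflectance)
    # the crown covers the whole crop (sampling-point patches are taken
    # at crown centres), so texture statistics see canopy, not edges
    _render_canopy(
        raster, (size // 2, size // 2), (0.80 * size, 0.80 * size), lai, config, rng
    )
    raster = raster * gain + bias
    return RGBPatch(
        raster, units="reflectance", resolution_cm=config.resolution_cm,
        stage=stage, date=f"date-{stage}",
    )


def render_lai_patch(
    lai: float,
    config: SceneConfig,
    seed: int = 0,
    stage: int = 0,
    gain: float = 1.0,
    bias: float = 0.0,
) -> RGBPatch:
    """Render a single centred-crown patch at a prescribed LAI.

    Deterministic when ``config.texture_noise`` is zero; mainly useful for
    probing the greenness/texture-vs-LAI links in isolation.
    """
    rng = np.random.default_rng(seed)
    return _render_point_patch(lai, config, rng, stage, gain, bias)


def generate_time_series_dataset(
    config: SceneConfig, missingness: float = 0.0
) -> list[TemporalSample]:
    """One labelled L-stage time series per sampling point.

    Per-point LAI trajectories follow the logistic stage profile with a
    point-level random intercept; patches are rendered per stage with the
    per-date gain/bias applied; a (point, stage) cell is dropped
    independently with probability ``missingness``. The regression label
    is the final-stage LAI regardless of missingness (field labels are
    measured on the ground, not read off the imagery).
    """
    if not 0.0 <= missingness <= 1.0:
        raise ValueError("missingness must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    traj = _draw_trajectories(config, rng)
    gains = rng.uniform(*config.gain_range, size=config.n_stages)
    biases = rng.uniform(*config.bias_range, size=config.n_stages)
    drop = rng.random(size=(config.n_points, config.n_stages)) < missingness
    samples: list[TemporalSample] = []
    for pid in range(config.n_points):
        patches: list[RGBPatch | None] = []
        for stage in range(config.n_stages):
            # render unconditionally so missingness does not perturb the
            # rng stream of later points
            patch = _render_point_patch(
                traj[pid, stage], config, rng, stage, gains[stage], biases[stage]
            )
            patches.append(None if drop[pid, stage] else patch)
        samples.append(
            TemporalSample(
                point_id=pid,
                patches=patches,
                label=float(traj[pid, -1]),
                stage_lais=traj[pid].tolist(),
            )
        )
    return samples


@dataclass
class ContinuousScene:
    """A closed-canopy scene with a smooth latent LAI field.

    Unlike the discrete-crown orchard, every window of this scene is a
    valid canopy sample, which makes it the right benchmark for
    sliding-window map production: predictions can be scored against the
    (final-stage) truth field at any tile position.
    """

    config: SceneConfig
    scenes: list[np.ndarray]  # per stage, (H, W, 3)
    truth_stages: list[np.ndarray]  # per-stage LAI fields
    truth_lai: np.ndarray  # final-stage LAI field
    gains: np.ndarray
    biases: np.ndarray


def generate_continuous_scene(
    config: SceneConfig,
    shape: tuple[int, int] = (256, 256),
    smoothness_px: float = 24.0,
) -> ContinuousScene:
    """Render a closed-canopy scene over a smooth LAI field.

    The latent final-stage LAI field is Gaussian-filtered noise rescaled
    to the configured LAI range; per-stage fields follow the same
    logistic stage profile as the point trajectories, and pixel
    reflectance follows the same coverage/greenness links, so a model
    trained on canopy patches transfers to scene tiles.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lai_range
    base = gaussian_filter(rng.standard_normal(shape), sigma=smoothness_px)
    base = (base - base.min()) / (base.max() - base.min() + 1e-12)
    final = lo + (hi - lo) * base
    start = lo + 0.15 * (final - lo)
    profile = _stage_profile(config.n_stages)
    gains = rng.uniform(*config.gain_range, size=config.n_stages)
    biases = rng.uniform(*config.bias_range, size=config.n_stages)
    soil = np.asarray(config.soil_reflectance)
    scenes, truths = [], []
    for stage in range(config.n_stages):
        lai = start + (final - start) * profile[stage]
        s = _sigmoid(config.greenness_slope * (lai - config.greenness_offset))
        leaf = np.stack(
            [0.12 - 0.03 * s, 0.10 + 0.35 * s, 0.08 - 0.02 * s], axis=-1
        )
        cov = (1.0 - np.exp(-0.55 * lai))[:, :, None]
        scene = (1.0 - cov) * soil + cov * leaf
        if config.texture_noise > 0:
            rel = np.clip((lai - lo) / (hi - lo), 0.0, 1.0)
            amp = config.texture_noise * (0.3 + 0.7 * rel)
            blob = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
            sd = blob.std()
            if sd > 0:
                blob /= sd
            scene = scene * np.clip(1.0 + (amp * blob)[:, :, None], 0.05, None)
        scenes.append(scene * gains[stage] + biases[stage])
        truths.append(lai)
    return ContinuousScene(
        config=config, scenes=scenes, truth_stages=truths,
        truth_lai=final, gains=gains, biases=biases,
    )


def continuous_samples(
    scene: ContinuousScene, n: int, seed: int = 0
) -> list[TemporalSample]:
    """Non-overlapping labelled crops from a continuous-canopy scene.

    Crop labels are the final-stage truth-field mean over the crop
    footprint; crops tile a grid and are drawn without replacement so
    point-level splits stay leakage-free.
    """
    rng = np.random.default_rng(seed)
    size = scene.config.patch_size
    h, w = scene.truth_lai.shape
    anchors = [
        (r, c)
        for r in range(0, h - size + 1, size)
        for c in range(0, w - size + 1, size)
    ]
    if n > len(anchors):
        raise SceneSizingError(
            f"scene holds only {len(anchors)} non-overlapping crops; {n} requested"
        )
    chosen = [anchors[i] for i in rng.choice(len(anchors), size=n, replace=False)]
    samples = []
    for pid, (r, c) in enumerate(chosen):
        patches = [
            RGBPatch(
                s[r : r + size, c : c + size].copy(),
                units="reflectance",
                resolution_cm=scene.config.resolution_cm,
                stage=t,
                date=f"date-{t}",
            )
            for t, s in enumerate(scene.scenes)
        ]
        label = float(scene.truth_lai[r : r + size, c : c + size].mean())
        samples.append(
            TemporalSample(point_id=pid, patches=patches, label=label)
        )
    return samples


def bundle_to_samples(bundle: SceneBundle) -> list[TemporalSample]:
    """Sampling-point time series cropped out of a rendered scene bundle."""
    samples = []
    for pid in range(bundle.config.n_points):
        patches = [
            bundle.patches[(pid, stage)] for stage in range(bundle.config.n_stages)
        ]
        samples.append(
            TemporalSample(
                point_id=pid,
                patches=patches,
                label=float(bundle.labels[pid]),
                stage_lais=bundle.stage_lais[pid].tolist(),
            )
        )
    return samples


def make_benchmark(
    n_points: int = 300, seed: int = 0, missingness: float = 0.0, **overrides
) -> tuple[SceneConfig, list[TemporalSample]]:
    """The default seeded synthetic benchmark used by the end-to-end tests."""
    config = SceneConfig(
        n_points=n_points, seed=seed, resolution_cm=10.0, patch_size=32, **overrides
    )
    return config, generate_time_series_dataset(config, missingness=missingness)


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------


def write_scene_geotiff(path, scene: np.ndarray, resolution_cm: float) -> None:
    """Write a scene raster as TIFF with resolution metadata (cm/pixel)."""
    import tifffile

    px_per_cm = 1.0 / resolution_cm
    tifffile.imwrite(
        str(path),
        scene.astype(np.float32),
        photometric="rgb",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_labels_csv(samples: list[TemporalSample], path) -> None:
    """Long-format label table: point_id, stage, date, lai, path."""
    import pandas as pd

    rows = []
    for s in samples:
        lais = s.stage_lais if s.stage_lais is not None else [np.nan] * s.n_stages
        for stage, patch in enumerate(s.patches):
            rows.append(
                {
                    "point_id": s.point_id,
                    "stage": stage,
                    "date": None if patch is None else patch.date,
                    "lai": lais[stage],
                    "path": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def config_to_yaml(config: SceneConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
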