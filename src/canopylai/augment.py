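"""CutMix augmentation for regression-labelled canopy patches.

A rectangular region covering a configured fraction of the patch area
(default 40%) is cropped from a donor sample and pasted at the same
coordinates into a base sample; the mixed label is the area-weighted
combination of the parents' labels, y_c = (1 - lam) * y_a + lam * y_b
with lam the realized donor pixel fraction. At the default 40% area this
gives the base label a 60% weight. Area weighting is physically
consistent with the definition of LAI (leaf area per unit ground area),
so mixed labels stay meaningful.

The same rectangle is applied to every stage of a time series, and
augmentation is only ever applied to training samples — synthetic
samples are tagged and carry both parents' point ids so the evaluation
module can keep them clear of the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from canopylai.types import RGBPatch, TemporalSample

__all__ = ["MixedSample", "cutmix", "augment_training_set"]


@dataclass
class MixedSample:
    """A CutMix product with its provenance and realized mixing weight."""

    sample: TemporalSample
    base_label: float  # y_a
    donor_label: float  # y_b
    region: tuple[int, int, int, int]  # (row0, col0, height, width)
    lam: float  # realized donor area fraction

    @property
    def mixed_label(self) -> float:
        return self.sample.label


def _draw_region(
    shape: tuple[int, int], fraction: float, rng: np.random.Generator
) -> tuple[int, int, int, int]:
    """Axis-aligned rectangle of ~fraction*H*W pixels at a random location.

    The aspect ratio is drawn uniformly in [0.5, 2] and the rectangle is
    scaled to the target area, then clipped to the patch. Degenerate
    fractions short-circuit to an empty or full region.
    """
    h, w = shape
    if fraction <= 0:
        return (0, 0, 0, 0)
    if fraction >= 1:
        return (0, 0, h, w)
    target = int(round(fraction * h * w))
    if target == 0:
        return (0, 0, 0, 0)
    aspect = rng.uniform(0.5, 2.0)  # height / width
    ideal_h = np.sqrt(target * aspect)
    # prefer an exact-area rectangle (any aspect); otherwise the nearest
    # achievable area, tie-broken toward the drawn aspect
    best: tuple[float, float, int, int] | None = None
    for rh in range(1, h + 1):
        for rw in {target // rh, -(-target // rh)}:
            rw = min(max(rw, 1), w)
            area_err = abs(rh * rw - target)
            aspect_err = abs(np.log(rh / ideal_h))
            key = (area_err, aspect_err, rh, rw)
            if best is None or key < best:
                best = key
    _, _, rh, rw = best
    r0 = int(rng.integers(0, h - rh + 1))
    c0 = int(rng.integers(0, w - rw + 1))
    return (r0, c0, rh, rw)


def cutmix(
    sample_a: TemporalSample,
    sample_b: TemporalSample,
    fraction: float = 0.40,
    rng: np.random.Generator | None = None,
) -> MixedSample:
    """Transplant a donor rectangle into a base sample, mixing the labels.

    The label weight uses the *realized* pixel fraction of the pasted
    rectangle, so y_c = (1 - lam) y_a + lam y_b holds exactly even when
    rounding moves the area slightly off the requested fraction. The
    same rectangle is used across all L stage patches.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if sample_a.n_stages != sample_b.n_stages:
        raise ValueError("samples have different numbers of stages")
    rng = np.random.default_rng() if rng is None else rng
    shapes_a = [p.values.shape for p in sample_a.patches if p is not None]
    shapes_b = [p.values.shape for p in sample_b.patches if p is not None]
    if not shapes_a or len(shapes_a) != sample_a.n_stages or len(shapes_b) != sample_b.n_stages:
        raise ValueError("cutmix requires complete samples; fill missing stages first")
    if len({*shapes_a, *shapes_b}) != 1:
        raise ValueError("patch shape mismatch between samples")
    h, w, _ = shapes_a[0]
    r0, c0, rh, rw = _draw_region((h, w), fraction, rng)
    lam = (rh * rw) / (h * w)
    patches = []
    for pa, pb in zip(sample_a.patches, sample_b.patches):
        mixed = pa.values.copy()
        mixed[r0 : r0 + rh, c0 : c0 + rw] = pb.values[r0 : r0 + rh, c0 : c0 + rw]
        patches.append(pa.copy_with(values=mixed))
    ya, yb = sample_a.label, sample_b.label
    yc = (1.0 - lam) * ya + lam * yb
    mixed_sample = TemporalSample(
        point_id=sample_a.point_id,
        patches=patches,
        label=float(yc),
        stage_lais=None,
        synthetic=True,
        parent_point_ids=tuple(
            sorted({*sample_a.parent_point_ids, *sample_b.parent_point_ids})
        ),
    )
    return MixedSample(
        sample=mixed_sample,
        base_label=ya,
        donor_label=yb,
        region=(r0, c0, rh, rw),
        lam=lam,
    )


def augment_training_set(
    train: list[TemporalSample],
    n_aug: int,
    rng: np.random.Generator | None = None,
    fraction: float = 0.40,
) -> list[TemporalSample]:
    """Append ``n_aug`` CutMix samples drawn from ordered training pairs.

    Originals are preserved and come first; every appended sample is
    tagged synthetic. Never call this on anything but training data —
    the test set must remain untouched.
    """
    if n_aug < 0:
        raise ValueError("n_aug must be non-negative")
    if n_aug > 0 and len(train) < 2:
        raise ValueError("need at least 2 training samples to augment")
    rng = np.random.default_rng() if rng is None else rng
    out = list(train)
    for _ in range(n_aug):
        ia, ib = rng.choice(len(train), size=2, replace=False)
        out.append(cutmix(train[ia], train[ib], fraction=fraction, rng=rng).sample)
    return out
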