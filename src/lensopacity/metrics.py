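"""Per-slice and per-eye opacity metrics, and control-cohort threshold calibration.

Nuclear opacity is summarized by the maximum and mean pixel intensity inside
an elliptical nucleus ROI on four meridians (45/90/135/180 degrees), then
averaged across meridians.  Cortical opacity is the percentage of cortex
pixels whose intensity exceeds a cutoff calibrated as the maximum intensity
observed anywhere in the cortex of a clear-lens control cohort; it is
reported for the whole cortex and for peripheral half/third/quarter bands,
with opaque and total pixel counts pooled across an eye's slice stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .roi import (
    PixelMask,
    ReflexExclusion,
    mask_centroid,
    peripheral_fraction_mask,
    radial_depth,
    subtract_exclusions,
)

__all__ = [
    "SliceImage",
    "NuclearSliceMetrics",
    "NuclearEyeMetrics",
    "ThresholdCalibration",
    "CorticalEyeMetrics",
    "NUCLEAR_MERIDIANS",
    "DEFAULT_FRACTIONS",
    "slice_nuclear_metrics",
    "eye_nuclear_metrics",
    "calibrate_threshold",
    "percent_opaque",
    "eye_cortical_metrics",
]

logger = logging.getLogger(__name__)

#: Meridians analysed for nuclear cataracts (degrees).
NUCLEAR_MERIDIANS: Tuple[float, ...] = (45.0, 90.0, 135.0, 180.0)

#: Cortex area fractions, measured inward from the periphery.
DEFAULT_FRACTIONS: Tuple[float, ...] = (1.0, 0.5, 1.0 / 3.0, 0.25)

#: Tolerance when matching a slice's meridian angle to a required one.
MERIDIAN_TOLERANCE_DEG = 1.0

GROUPS = ("control", "nuclear", "cortical")


@dataclass(frozen=True)
class SliceImage:
    """One meridional Scheimpflug section of a lens.

    ``pixels`` is an 8-bit grayscale intensity grid (0-255); ``meridian_angle``
    is the section's angle in degrees within ``[0, 180]`` (0 and 180 denote
    the same meridian imaged at either end of the sweep).
    """

    pixels: np.ndarray
    meridian_angle: float
    eye_id: str = ""
    group: str = "control"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("slice pixels must be a non-empty 2D grid")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("slice intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)
        if not (0.0 <= self.meridian_angle <= 180.0):
            raise ValueError(f"meridian angle {self.meridian_angle} outside [0, 180]")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class NuclearSliceMetrics:
    """Maximum / mean nucleus intensity for a single meridian."""

    meridian_angle: float
    max_intensity: float
    mean_intensity: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("nuclear slice metrics require a non-empty ROI")
        if not (0.0 <= self.mean_intensity <= self.max_intensity <= 255.0):
            raise ValueError("require 0 <= mean <= max <= 255")


@dataclass(frozen=True)
class NuclearEyeMetrics:
    """Four-meridian nuclear metrics plus their across-meridian averages.

    ``agg_max`` / ``agg_mean`` are the arithmetic means of the four per-slice
    maxima / means (the "average of the four meridians").
    """

    per_slice: Mapping[float, NuclearSliceMetrics]
    agg_max: float
    agg_mean: float

    def __post_init__(self) -> None:
        if tuple(sorted(self.per_slice)) != tuple(sorted(NUCLEAR_MERIDIANS)):
            raise ValueError(f"exactly the meridians {NUCLEAR_MERIDIANS} are required")
        maxima = [m.max_intensity for m in self.per_slice.values()]
        means = [m.mean_intensity for m in self.per_slice.values()]
        if not (min(maxima) - 1e-9 <= self.agg_max <= max(maxima) + 1e-9):
            raise ValueError("agg_max must lie within its per-slice inputs")
        if not (min(means) - 1e-9 <= self.agg_mean <= max(means) + 1e-9):
            raise ValueError("agg_mean must lie within its per-slice inputs")


@dataclass(frozen=True)
class ThresholdCalibration:
    """Clear/opaque cutoff derived from a clear-lens control cohort.

    The threshold equals the maximum cortical pixel intensity observed over
    all pixels of all clear eyes; median/min/max of the pooled pixels are
    kept as provenance.
    """

    threshold: float
    n_eyes: int
    control_median: float
    control_min: float
    control_max: float

    def __post_init__(self) -> None:
        if self.threshold != self.control_max:
            raise ValueError("threshold must equal the pooled control maximum")
        if not (self.control_min <= self.control_median <= self.control_max):
            raise ValueError("require control min <= median <= max")


@dataclass(frozen=True)
class CorticalEyeMetrics:
    """Percent-opaque-pixel metric of one eye, per cortex area fraction."""

    percent_opaque: Mapping[float, float]
    n_slices: int
    threshold_used: float
    n_slices_used: Mapping[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("cortical metrics require at least one slice")
        for frac, pct in self.percent_opaque.items():
            if not (0.0 <= pct <= 100.0):
                raise ValueError(f"percentage for fraction {frac} outside [0, 100]")


def slice_nuclear_metrics(
    image: SliceImage,
    mask: PixelMask,
    exclusions: Optional[ReflexExclusion] = None,
) -> NuclearSliceMetrics:
    """Maximum and arithmetic-mean intensity over the nucleus ROI of one slice.

    Reflex pixels are removed before either statistic; the mean is kept at
    full floating precision.
    """
    effective = subtract_exclusions(np.asarray(mask, dtype=bool), exclusions)
    if effective.shape != image.shape:
        raise ValueError("mask shape does not match the slice")
    values = image.pixels[effective]
    if values.size == 0:
        raise ValueError("nucleus ROI is empty after reflex exclusion")
    return NuclearSliceMetrics(
        meridian_angle=float(image.meridian_angle),
        max_intensity=float(values.max()),
        mean_intensity=float(values.mean()),
        n_pixels=int(values.size),
    )


def _match_meridian(angle: float) -> Optional[float]:
    for required in NUCLEAR_MERIDIANS:
        if abs(angle - required) <= MERIDIAN_TOLERANCE_DEG:
            return required
    return None


def eye_nuclear_metrics(
    slices: Sequence[Tuple[SliceImage, PixelMask, Optional[ReflexExclusion]]],
) -> NuclearEyeMetrics:
    """Nuclear metrics of one eye from its four meridians (45/90/135/180 deg).

    Each entry is ``(slice, nucleus mask, reflex exclusions or None)``; the
    four required meridians must each appear exactly once (matched within
    +/- 1 degree).
    """
    per_slice: Dict[float, NuclearSliceMetrics] = {}
    for image, mask, exclusions in slices:
        required = _match_meridian(float(image.meridian_angle))
        if required is None:
            raise ValueError(
                f"slice at {image.meridian_angle} deg is not a nuclear meridian "
                f"{NUCLEAR_MERIDIANS}"
            )
        if required in per_slice:
            raise ValueError(f"duplicate meridian {required} deg for eye {image.eye_id!r}")
        per_slice[required] = slice_nuclear_metrics(image, mask, exclusions)
    missing = set(NUCLEAR_MERIDIANS) - set(per_slice)
    if missing:
        raise ValueError(f"missing nuclear meridians: {sorted(missing)}")
    agg_max = float(np.mean([per_slice[a].max_intensity for a in NUCLEAR_MERIDIANS]))
    agg_mean = float(np.mean([per_slice[a].mean_intensity for a in NUCLEAR_MERIDIANS]))
    return NuclearEyeMetrics(per_slice=per_slice, agg_max=agg_max, agg_mean=agg_mean)


def calibrate_threshold(
    control_pixels: Iterable[np.ndarray],
) -> ThresholdCalibration:
    """Set the clear/opaque cutoff from a clear-lens control cohort.

    ``control_pixels`` holds one array of cortical pixel intensities per
    clear eye (reflexes already removed).  The threshold is the maximum over
    the pooled pixels of all eyes; the pooled median/min/max are recorded as
    provenance.
    """
    per_eye = [np.asarray(p).ravel() for p in control_pixels]
    if len(per_eye) == 0:
        raise ValueError("threshold calibration requires at least one control eye")
    for p in per_eye:
        if p.size == 0:
            raise ValueError("every control eye must contribute at least one pixel")
    pooled = np.concatenate(per_eye).astype(float)
    return ThresholdCalibration(
        threshold=float(pooled.max()),
        n_eyes=len(per_eye),
        control_median=float(np.median(pooled)),
        control_min=float(pooled.min()),
        control_max=float(pooled.max()),
    )


def percent_opaque(
    image: SliceImage,
    mask: PixelMask,
    threshold: float,
    exclusions: Optional[ReflexExclusion] = None,
) -> float:
    """Percentage of mask pixels with intensity strictly above ``threshold``.

    Strict inequality is deliberate: the threshold is itself the maximum
    intensity attained by a clear eye, so clear tissue must score 0 %.
    Excluded reflex pixels are absent from both numerator and denominator.
    """
    effective = subtract_exclusions(np.asarray(mask, dtype=bool), exclusions)
    if effective.shape != image.shape:
        raise ValueError("mask shape does not match the slice")
    total = int(effective.sum())
    if total == 0:
        raise ValueError("cortex ROI is empty after reflex exclusion")
    opaque = int((image.pixels[effective] > threshold).sum())
    return 100.0 * opaque / total


def eye_cortical_metrics(
    slices: Sequence[Tuple[SliceImage, PixelMask, Optional[ReflexExclusion]]],
    threshold: float,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    centroids: Optional[Sequence[Tuple[float, float]]] = None,
    aggregation: str = "pooled",
) -> CorticalEyeMetrics:
    """Percent-opaque cortex pixels of one eye, pooled over its slice stack.

    For each area fraction the peripheral sub-mask is built per slice, then
    opaque and total pixel counts are pooled across slices before forming the
    percentage (``aggregation="pooled"``, the default: slices are weighted by
    their cortex area).  ``aggregation="mean"`` instead averages the
    per-slice percentages.  A slice whose sub-mask is empty is skipped for
    that fraction with a logged warning; if every slice is empty for some
    fraction an error is raised.
    """
    if len(slices) < 1:
        raise ValueError("cortical metrics require at least one slice")
    if aggregation not in ("pooled", "mean"):
        raise ValueError("aggregation must be 'pooled' or 'mean'")
    fractions = tuple(float(f) for f in fractions)
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fraction {f} outside (0, 1]")

    opaque_counts = {f: 0 for f in fractions}
    total_counts = {f: 0 for f in fractions}
    slice_pcts: Dict[float, list] = {f: [] for f in fractions}
    used = {f: 0 for f in fractions}

    for idx, (image, mask, exclusions) in enumerate(slices):
        effective = subtract_exclusions(np.asarray(mask, dtype=bool), exclusions)
        if effective.shape != image.shape:
            raise ValueError("mask shape does not match the slice")
        if not effective.any():
            logger.warning(
                "WARN %s slice %s empty cortex mask after exclusions; skipped",
                image.eye_id,
                image.meridian_angle,
            )
            continue
        centroid = centroids[idx] if centroids is not None else mask_centroid(effective)
        depth = radial_depth(effective, centroid)
        above = image.pixels > threshold
        for f in fractions:
            sub = peripheral_fraction_mask(effective, centroid, f, depth=depth)
            total = int(sub.sum())
            if total == 0:
                logger.warning(
                    "WARN %s slice %s empty sub-mask for fraction %.4f; skipped",
                    image.eye_id,
                    image.meridian_angle,
                    f,
                )
                continue
            opaque = int(above[sub].sum())
            opaque_counts[f] += opaque
            total_counts[f] += total
            slice_pcts[f].append(100.0 * opaque / total)
            used[f] += 1

    percent: Dict[float, float] = {}
    for f in fractions:
        if used[f] == 0:
            raise ValueError(f"all slices had an empty sub-mask for fraction {f}")
        if aggregation == "pooled":
            percent[f] = 100.0 * opaque_counts[f] / total_counts[f]
        else:
            percent[f] = float(np.mean(slice_pcts[f]))
    return CorticalEyeMetrics(
        percent_opaque=percent,
        n_slices=len(slices),
        threshold_used=float(threshold),
        n_slices_used=used,
    )
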