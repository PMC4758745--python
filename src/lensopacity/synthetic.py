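"""Seeded phantom Scheimpflug slice stacks with ground truth.

No image data accompany the clinical summaries this pipeline reproduces, so
every stage is exercised on phantoms that emulate the statistical structure
the analysis assumes:

* a lens cross-section with an elliptical **nucleus**, a dark separating
  gap, and an annular **cortex band** whose outer boundary carries a smooth
  per-angle perturbation (lenses are not perfect ellipses);
* **nuclear opacification** as a homogeneous intensity elevation of the
  whole nucleus (nuclear cataracts grow homogeneously from the centre out);
* **cortical opacification** as bright spokes: angular sectors whose radial
  extent grows inward from the periphery with severity and whose angular
  positions are jittered per slice (cortical cataracts progress
  asymmetrically, periphery-in);
* saturated specular **reflex** blobs recorded in truth masks;
* additive Gaussian acquisition noise, rounded and clipped to 8 bits.

Clear-lens cortex intensities stay below a fixed ceiling when noise-free, so
control cohorts calibrate a sensible clear/opaque cutoff.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .metrics import SliceImage
from .roi import ContourROI, EllipseROI

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "EyeROIs",
    "SyntheticEye",
    "render_eye",
    "render_cohort",
    "grade_from_severity",
    "control_pixels_from_summary",
    "CONTROL_ANGLES",
    "DEFAULT_NUCLEAR_SEVERITIES",
    "DEFAULT_CORTICAL_SEVERITIES",
]

#: Control eyes are imaged on four meridians only (cortical transparency is
#: assumed homogeneous in clear lenses).
CONTROL_ANGLES: Tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

#: Default severity grids of the synthetic cohort (5 levels per group).
DEFAULT_NUCLEAR_SEVERITIES: Tuple[float, ...] = (6.0, 14.0, 26.0, 44.0, 60.0)
DEFAULT_CORTICAL_SEVERITIES: Tuple[float, ...] = (0.12, 0.25, 0.45, 0.65, 0.85)

# Fixed monotone severity -> synthetic LOCS grade binning, matching the grade
# sets observed clinically (nuclear 1.0-4.0, cortical 0.5-3.0).
_NUCLEAR_GRADE_EDGES = ((12.0, 1.0), (24.0, 2.0), (40.0, 3.0), (math.inf, 4.0))
_CORTICAL_GRADE_EDGES = ((0.18, 0.5), (0.35, 1.0), (0.60, 2.0), (math.inf, 3.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity model and acquisition settings of one phantom eye.

    Intensities are on the 8-bit 0-255 scale.  ``nuclear_severity`` is the
    homogeneous intensity elevation of the nucleus (>= 0);
    ``cortical_severity`` in [0, 1] is the fraction of cortex depth occupied
    by spokes (spoke angular width also widens with severity).  Noise-free
    clear cortex never exceeds ``clear_ceiling``.
    """

    shape: Tuple[int, int] = (160, 160)
    center: Tuple[float, float] = (80.0, 80.0)
    nucleus_a: float = 30.0
    nucleus_b: float = 20.0
    rotation: float = 0.0
    gap_scale: float = 1.15
    outer_a: float = 62.0
    outer_b: float = 46.0
    perturb_amp: float = 0.04
    background: float = 3.0
    nucleus_base: float = 8.0
    cortex_low: float = 10.0
    cortex_high: float = 30.0
    gap_intensity: float = 5.0
    clear_ceiling: float = 34.0
    noise_sd: float = 2.0
    nuclear_severity: float = 0.0
    cortical_severity: float = 0.0
    n_spokes: int = 6
    spoke_width_deg: float = 14.0
    spoke_elevation: float = 70.0
    spoke_jitter_deg: float = 4.0
    reflex_count: int = 2
    reflex_radius: float = 2.0
    reflex_intensity: int = 255
    n_slices: int = 25
    angle_step_deg: float = 7.5
    angles: Optional[Tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        cx, cy = self.center
        reach = max(self.outer_a, self.outer_b) * (1.0 + self.perturb_amp) + 1.0
        if not (cx - reach >= 0 and cx + reach <= cols - 1 and cy - reach >= 0 and cy + reach <= rows - 1):
            raise ValueError("lens geometry (outer boundary + margin) exceeds the image bounds")
        if self.nucleus_a <= 0 or self.nucleus_b <= 0:
            raise ValueError("nucleus semi-axes must be positive")
        if self.gap_scale <= 1.0:
            raise ValueError("gap_scale must exceed 1 (nucleus and cortex are disjoint)")
        if self.nuclear_severity < 0:
            raise ValueError("nuclear_severity must be >= 0")
        if not (0.0 <= self.cortical_severity <= 1.0):
            raise ValueError("cortical_severity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.cortex_high > self.clear_ceiling:
            raise ValueError("clear cortex intensities must stay below the clear ceiling")

    def slice_angles(self) -> Tuple[float, ...]:
        if self.angles is not None:
            return tuple(float(a) for a in self.angles)
        return tuple(i * self.angle_step_deg for i in range(self.n_slices))


@dataclass(frozen=True)
class EyeROIs:
    """Analysis ROIs derived from phantom ground truth.

    These are what an observer would have drawn: a nucleus ellipse slightly
    inside the true nucleus, outer/inner cortex contours sampled on the true
    band boundaries, and one exclusion contour per reflex per slice.
    """

    nucleus: EllipseROI
    cortex_outer: ContourROI
    cortex_inner: ContourROI
    reflex_contours: Tuple[Tuple[ContourROI, ...], ...]  # per slice


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one rendered eye."""

    nucleus_mask: np.ndarray
    cortex_mask: np.ndarray
    reflex_masks: Tuple[np.ndarray, ...]  # one combined mask per slice
    angles: Tuple[float, ...]
    nuclear_severity: float
    cortical_severity: float
    grade: float
    rois: EyeROIs


@dataclass(frozen=True)
class SyntheticEye:
    """One cohort member: rendered slices, truth, and its grade record fields."""

    eye_id: str
    group: str
    slices: Tuple[SliceImage, ...]
    truth: PhantomTruth


def grade_from_severity(kind: str, severity: float) -> float:
    """Map a scalar severity to a synthetic ordinal LOCS grade (monotone)."""
    if severity == 0.0:
        return 0.0
    edges = {"nuclear": _NUCLEAR_GRADE_EDGES, "cortical": _CORTICAL_GRADE_EDGES}[kind]
    for upper, grade in edges:
        if severity < upper:
            return grade
    raise AssertionError("unreachable")


class _EyeGeometry:
    """Per-eye analytic geometry shared by all slices of one eye."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        rows, cols = spec.shape
        cx, cy = spec.center
        ys, xs = np.mgrid[0:rows, 0:cols].astype(float)
        dx = xs - cx
        dy = ys - cy
        self.theta = np.degrees(np.arctan2(dy, dx)) % 360.0
        self.r = np.hypot(dx, dy)
        rot = math.radians(spec.rotation)
        u = dx * math.cos(rot) + dy * math.sin(rot)
        v = -dx * math.sin(rot) + dy * math.cos(rot)
        # smooth per-angle perturbation of the outer boundary
        self.phase2 = rng.uniform(0.0, 2.0 * math.pi)
        self.phase3 = rng.uniform(0.0, 2.0 * math.pi)
        self.level = rng.uniform(0.85, 1.0)  # per-eye cortex brightness factor
        self.spoke_offset = rng.uniform(0.0, 360.0)
        self.spec = spec
        perturb = self._perturb(self.theta)
        rho_n = np.sqrt((u / spec.nucleus_a) ** 2 + (v / spec.nucleus_b) ** 2)
        rho_o = np.sqrt((u / spec.outer_a) ** 2 + (v / spec.outer_b) ** 2) / perturb
        self.nucleus = rho_n <= 1.0
        self.band = (rho_o <= 1.0) & (rho_n >= spec.gap_scale)
        self.gap = (rho_o <= 1.0) & (rho_n > 1.0) & (rho_n < spec.gap_scale)
        # analytic inward depth of band pixels, 0 at periphery, 1 at the gap
        r_out = self.outer_radius(self.theta)
        r_in = self.inner_radius(self.theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            depth = (r_out - self.r) / (r_out - r_in)
        self.depth = np.clip(np.where(self.band, depth, np.nan), 0.0, 1.0)

    def _perturb(self, theta_deg: np.ndarray) -> np.ndarray:
        t = np.radians(theta_deg)
        s = self.spec
        return 1.0 + s.perturb_amp * (
            0.6 * np.sin(2.0 * t + self.phase2) + 0.4 * np.sin(3.0 * t + self.phase3)
        )

    def _ellipse_radius(self, theta_deg, a: float, b: float) -> np.ndarray:
        phi = np.radians(theta_deg) - math.radians(self.spec.rotation)
        return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)

    def outer_radius(self, theta_deg) -> np.ndarray:
        return self._ellipse_radius(theta_deg, self.spec.outer_a, self.spec.outer_b) * self._perturb(
            np.asarray(theta_deg, dtype=float)
        )

    def inner_radius(self, theta_deg) -> np.ndarray:
        return self.spec.gap_scale * self._ellipse_radius(
            theta_deg, self.spec.nucleus_a, self.spec.nucleus_b
        )

    def base_image(self) -> np.ndarray:
        s = self.spec
        img = np.full(s.shape, s.background, dtype=float)
        img[self.gap] = s.gap_intensity
        img[self.nucleus] = s.nucleus_base
        # triangular radial profile peaking mid-band, bounded by cortex_high
        band_shape = 1.0 - np.abs(2.0 * self.depth[self.band] - 1.0)
        img[self.band] = s.cortex_low + (s.cortex_high - s.cortex_low) * self.level * band_shape
        return img

    def rois(self, reflex_contours: Sequence[Sequence[ContourROI]]) -> EyeROIs:
        s = self.spec
        cx, cy = s.center
        angles = np.arange(0.0, 360.0, 18.0)  # 20 control points
        r_out = self.outer_radius(angles) + 0.6
        r_in = self.inner_radius(angles) - 0.6
        rad = np.radians(angles)
        outer_pts = np.column_stack([cx + r_out * np.cos(rad), cy + r_out * np.sin(rad)])
        inner_pts = np.column_stack([cx + r_in * np.cos(rad), cy + r_in * np.sin(rad)])
        return EyeROIs(
            nucleus=EllipseROI(cx, cy, 0.92 * s.nucleus_a, 0.92 * s.nucleus_b, s.rotation),
            cortex_outer=ContourROI(outer_pts),
            cortex_inner=ContourROI(inner_pts),
            reflex_contours=tuple(tuple(c) for c in reflex_contours),
        )


def _circle_contour(cx: float, cy: float, radius: float, n_points: int = 10) -> ContourROI:
    ang = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    return ContourROI(np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)]))


def _angular_distance(theta: np.ndarray, centre: float) -> np.ndarray:
    d = np.abs((theta - centre) % 360.0)
    return np.minimum(d, 360.0 - d)


def render_eye(
    spec: PhantomSpec, eye_id: str = "eye", group: str = "cortical"
) -> Tuple[List[SliceImage], PhantomTruth]:
    """Render one phantom eye: a stack of slice images plus ground truth.

    Deterministic for a fixed ``spec.seed``; slices differ through per-slice
    spoke jitter, reflex placement and noise draws.
    """
    rng = np.random.default_rng(spec.seed)
    geom = _EyeGeometry(spec, rng)
    base = geom.base_image()
    angles = spec.slice_angles()
    spoke_centres0 = geom.spoke_offset + np.arange(spec.n_spokes) * (360.0 / max(spec.n_spokes, 1))
    width = spec.spoke_width_deg * (0.4 + 0.6 * spec.cortical_severity)

    slices: List[SliceImage] = []
    reflex_masks: List[np.ndarray] = []
    reflex_contours: List[List[ContourROI]] = []
    for angle in angles:
        img = base.copy()
        img[geom.nucleus] += spec.nuclear_severity
        if spec.cortical_severity > 0 and spec.n_spokes > 0:
            jitter = rng.uniform(-spec.spoke_jitter_deg, spec.spoke_jitter_deg)
            spoke = np.zeros(spec.shape, dtype=bool)
            for centre in spoke_centres0 + jitter:
                spoke |= geom.band & (_angular_distance(geom.theta, centre % 360.0) <= width / 2.0)
            spoke &= ~np.isnan(geom.depth) & (geom.depth <= spec.cortical_severity)
            img[spoke] += spec.spoke_elevation
        reflex = np.zeros(spec.shape, dtype=bool)
        contours: List[ContourROI] = []
        for j in range(spec.reflex_count):
            beta = rng.uniform(0.0, 360.0)
            if j % 2 == 0:  # cortex mid-band
                r_spot = 0.5 * (
                    float(geom.inner_radius(beta)) + float(geom.outer_radius(beta))
                )
            else:  # inside the nucleus
                r_spot = 0.5 * float(geom._ellipse_radius(beta, spec.nucleus_a, spec.nucleus_b))
            px = spec.center[0] + r_spot * math.cos(math.radians(beta))
            py = spec.center[1] + r_spot * math.sin(math.radians(beta))
            spot = np.hypot(
                np.arange(spec.shape[1])[None, :] - px,
                np.arange(spec.shape[0])[:, None] - py,
            ) <= spec.reflex_radius
            img[spot] = spec.reflex_intensity
            reflex |= spot
            contours.append(_circle_contour(px, py, spec.reflex_radius + 1.6))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, spec.shape)
        pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        slices.append(SliceImage(pixels=pixels, meridian_angle=angle, eye_id=eye_id, group=group))
        reflex_masks.append(reflex)
        reflex_contours.append(contours)

    kind = "nuclear" if spec.nuclear_severity > 0 else "cortical"
    severity = spec.nuclear_severity if kind == "nuclear" else spec.cortical_severity
    truth = PhantomTruth(
        nucleus_mask=geom.nucleus,
        cortex_mask=geom.band,
        reflex_masks=tuple(reflex_masks),
        angles=angles,
        nuclear_severity=spec.nuclear_severity,
        cortical_severity=spec.cortical_severity,
        grade=grade_from_severity(kind, severity),
        rois=geom.rois(reflex_contours),
    )
    return slices, truth


def _eye_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def render_cohort(
    n_control: int = 10,
    n_nuclear: int = 30,
    n_cortical: int = 30,
    nuclear_severities: Sequence[float] = DEFAULT_NUCLEAR_SEVERITIES,
    cortical_severities: Sequence[float] = DEFAULT_CORTICAL_SEVERITIES,
    noise_sd: float = 2.0,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
) -> List[SyntheticEye]:
    """Render a full study cohort with per-eye seeds derived from ``seed``.

    Control eyes get 4 slices at 0/45/90/135 degrees (clear cortex assumed
    homogeneous); cataract eyes get the full 25-slice sweep.  Severities
    cycle through the given grid, so each level appears equally often, and
    map to synthetic ordinal grades by fixed monotone binning.
    """
    if n_control < 0 or n_nuclear < 0 or n_cortical < 0:
        raise ValueError("cohort counts must be >= 0")
    if n_control + n_nuclear + n_cortical == 0:
        raise ValueError("at least one group must be non-empty")
    base = base_spec if base_spec is not None else PhantomSpec()
    eyes: List[SyntheticEye] = []
    index = 0
    for i in range(n_control):
        spec = replace(
            base,
            nuclear_severity=0.0,
            cortical_severity=0.0,
            noise_sd=noise_sd,
            angles=CONTROL_ANGLES,
            seed=_eye_seed(seed, index),
        )
        eye_id = f"ctrl{i:03d}"
        slices, truth = render_eye(spec, eye_id=eye_id, group="control")
        eyes.append(SyntheticEye(eye_id, "control", tuple(slices), truth))
        index += 1
    for i in range(n_nuclear):
        sev = float(nuclear_severities[i % len(nuclear_severities)])
        spec = replace(
            base,
            nuclear_severity=sev,
            cortical_severity=0.0,
            noise_sd=noise_sd,
            angles=None,
            seed=_eye_seed(seed, index),
        )
        eye_id = f"nuc{i:03d}"
        slices, truth = render_eye(spec, eye_id=eye_id, group="nuclear")
        eyes.append(SyntheticEye(eye_id, "nuclear", tuple(slices), truth))
        index += 1
    for i in range(n_cortical):
        sev = float(cortical_severities[i % len(cortical_severities)])
        spec = replace(
            base,
            nuclear_severity=0.0,
            cortical_severity=sev,
            noise_sd=noise_sd,
            angles=None,
            seed=_eye_seed(seed, index),
        )
        eye_id = f"cort{i:03d}"
        slices, truth = render_eye(spec, eye_id=eye_id, group="cortical")
        eyes.append(SyntheticEye(eye_id, "cortical", tuple(slices), truth))
        index += 1
    return eyes


def control_pixels_from_summary(
    median: float = 25.0,
    vmin: float = 4.0,
    vmax: float = 34.0,
    n_eyes: int = 74,
    pixels_per_eye: int = 200,
    seed: int = 0,
) -> List[np.ndarray]:
    """Synthesize per-eye clear-cortex pixel collections with a prescribed
    pooled summary (median, minimum, maximum) — exactly.

    Each eye contributes an equal count of pixels below and above the median
    plus two pixels at the median, so the pooled median equals ``median``
    exactly; one pixel is pinned to ``vmin`` and one to ``vmax``.  Intended
    for reconstructing a published clear-group summary when the underlying
    pixel data are unavailable.
    """
    if n_eyes < 1 or pixels_per_eye < 4 or pixels_per_eye % 2 != 0:
        raise ValueError("need >= 1 eye and an even pixels_per_eye >= 4")
    if not (vmin < median < vmax):
        raise ValueError("require min < median < max")
    rng = np.random.default_rng(seed)
    half = (pixels_per_eye - 2) // 2
    eyes = []
    for i in range(n_eyes):
        low = rng.integers(int(vmin), int(median), size=half)
        high = rng.integers(int(median) + 1, int(vmax) + 1, size=half)
        px = np.concatenate([low, high, [median, median]]).astype(float)
        if i == 0:
            px[0] = vmin
            px[half] = vmax
        rng.shuffle(px)
        eyes.append(px)
    return eyes
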