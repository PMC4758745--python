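"""File formats: 8-bit grayscale slice images, ROI configs, run manifests.

A *run manifest* (YAML) ties a run together: per-eye slice files with their
meridian angles, ROI parameters (nucleus ellipse, cortex outer/inner
contours), per-slice reflex-exclusion contours, the grade table, the
threshold source and the area-fraction list.  Angles always come from the
manifest, never from filename guessing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image

from .metrics import DEFAULT_FRACTIONS, SliceImage
from .roi import ContourROI, EllipseROI

__all__ = [
    "load_slice_image",
    "save_slice_image",
    "save_mask_png",
    "load_mask_png",
    "RunManifest",
    "ManifestEye",
    "ManifestSlice",
    "load_manifest",
    "write_manifest",
]


def load_slice_image(
    path: str | Path,
    meridian_angle: float,
    eye_id: str = "",
    group: str = "control",
) -> SliceImage:
    """Load one 8-bit grayscale PNG/TIFF slice.

    Multi-channel or 16-bit inputs are rejected with an error naming the
    offending property.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "L":
            raise ValueError(
                f"{path}: expected 8-bit single-channel grayscale (mode 'L'), "
                f"got mode {im.mode!r}"
            )
        pixels = np.asarray(im, dtype=np.uint8)
    return SliceImage(pixels=pixels, meridian_angle=meridian_angle, eye_id=eye_id, group=group)


def save_slice_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an intensity grid as an 8-bit grayscale PNG."""
    arr = np.asarray(pixels)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities outside [0, 255]")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path))


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 grayscale PNG (for inspection)."""
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8), mode="L").save(
        Path(path)
    )


def load_mask_png(path: str | Path) -> np.ndarray:
    with Image.open(Path(path)) as im:
        if im.mode != "L":
            raise ValueError(f"{path}: mask PNG must be grayscale mode 'L', got {im.mode!r}")
        return np.asarray(im) > 127


# --------------------------------------------------------------------------
# run manifest


@dataclass(frozen=True)
class ManifestSlice:
    angle: float
    file: str
    reflexes: Tuple[ContourROI, ...] = ()


@dataclass(frozen=True)
class ManifestEye:
    eye_id: str
    group: str
    locs_grade: float
    slices: Tuple[ManifestSlice, ...]
    nucleus: Optional[EllipseROI] = None
    cortex_outer: Optional[ContourROI] = None
    cortex_inner: Optional[ContourROI] = None


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to (re)run a cohort analysis."""

    root: Path
    eyes: Tuple[ManifestEye, ...]
    fractions: Tuple[float, ...] = DEFAULT_FRACTIONS
    threshold: Optional[float] = None  # None -> calibrate from control eyes
    aggregation: str = "pooled"
    seed: int = 0


def _contour_to_cfg(c: ContourROI) -> Dict:
    return {"points": [[float(x), float(y)] for x, y in c.control_points]}


def _contour_from_cfg(cfg: Dict) -> ContourROI:
    return ContourROI(cfg["points"])


def _ellipse_to_cfg(e: EllipseROI) -> Dict:
    return {
        "cx": e.center_x,
        "cy": e.center_y,
        "a": e.semi_axis_major,
        "b": e.semi_axis_minor,
        "rot": e.rotation,
    }


def _ellipse_from_cfg(cfg: Dict) -> EllipseROI:
    return EllipseROI(cfg["cx"], cfg["cy"], cfg["a"], cfg["b"], cfg.get("rot", 0.0))


def write_manifest(path: str | Path, manifest: RunManifest) -> None:
    """Serialize a manifest to YAML with slice paths relative to its directory."""
    path = Path(path)
    doc: Dict = {
        "seed": int(manifest.seed),
        "fractions": [float(f) for f in manifest.fractions],
        "threshold": None if manifest.threshold is None else float(manifest.threshold),
        "aggregation": manifest.aggregation,
        "eyes": [],
    }
    for eye in manifest.eyes:
        entry: Dict = {
            "id": eye.eye_id,
            "group": eye.group,
            "locs_grade": float(eye.locs_grade),
            "roi": {},
            "slices": [],
        }
        if eye.nucleus is not None:
            entry["roi"]["nucleus"] = _ellipse_to_cfg(eye.nucleus)
        if eye.cortex_outer is not None:
            entry["roi"]["cortex"] = _contour_to_cfg(eye.cortex_outer)
        if eye.cortex_inner is not None:
            entry["roi"]["cortex_inner"] = _contour_to_cfg(eye.cortex_inner)
        for sl in eye.slices:
            entry["slices"].append(
                {
                    "angle": float(sl.angle),
                    "file": sl.file,
                    "reflexes": [_contour_to_cfg(c) for c in sl.reflexes],
                }
            )
        doc["eyes"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_manifest(path: str | Path) -> RunManifest:
    """Load and validate a YAML run manifest.

    Every referenced slice file must exist and each eye's angles must be
    unique.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    root = path.parent
    eyes: List[ManifestEye] = []
    for entry in doc.get("eyes", []):
        eye_id = str(entry["id"])
        slices: List[ManifestSlice] = []
        angles_seen = set()
        for sl in entry.get("slices", []):
            angle = float(sl["angle"])
            if angle in angles_seen:
                raise ValueError(f"eye {eye_id}: duplicate slice angle {angle}")
            angles_seen.add(angle)
            file = str(sl["file"])
            if not (root / file).exists():
                raise FileNotFoundError(f"eye {eye_id}: slice file {root / file} does not exist")
            reflexes = tuple(_contour_from_cfg(c) for c in sl.get("reflexes", []))
            slices.append(ManifestSlice(angle=angle, file=file, reflexes=reflexes))
        roi = entry.get("roi", {}) or {}
        eyes.append(
            ManifestEye(
                eye_id=eye_id,
                group=str(entry["group"]),
                locs_grade=float(entry.get("locs_grade", 0.0)),
                slices=tuple(slices),
                nucleus=_ellipse_from_cfg(roi["nucleus"]) if "nucleus" in roi else None,
                cortex_outer=_contour_from_cfg(roi["cortex"]) if "cortex" in roi else None,
                cortex_inner=_contour_from_cfg(roi["cortex_inner"]) if "cortex_inner" in roi else None,
            )
        )
    threshold = doc.get("threshold")
    return RunManifest(
        root=root,
        eyes=tuple(eyes),
        fractions=tuple(float(f) for f in doc.get("fractions", DEFAULT_FRACTIONS)),
        threshold=None if threshold is None else float(threshold),
        aggregation=str(doc.get("aggregation", "pooled")),
        seed=int(doc.get("seed", 0)),
    )
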