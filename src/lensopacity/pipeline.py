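"""End-to-end cohort analysis: calibrate, measure, correlate, write CSVs.

The pipeline mirrors the study design: the clear/opaque cutoff is calibrated
on the control eyes' pooled cortex pixels (unless given explicitly), nuclear
eyes are measured on the four meridians, cortical and control eyes get the
percent-opaque metric per area fraction, and everything is joined with the
grade table for descriptive tables and Spearman correlations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .metrics import (
    DEFAULT_FRACTIONS,
    SliceImage,
    ThresholdCalibration,
    calibrate_threshold,
    eye_cortical_metrics,
    eye_nuclear_metrics,
    NUCLEAR_MERIDIANS,
    _match_meridian,
)
from .roi import (
    ContourROI,
    EllipseROI,
    PixelMask,
    ReflexExclusion,
    rasterize_contour,
    rasterize_ellipse,
    subtract_exclusions,
)
from .stats import descriptive_table, spearman_with_grade
from .synthetic import SyntheticEye

__all__ = [
    "EyeData",
    "SliceRecord",
    "CohortResult",
    "eye_from_synthetic",
    "eyes_from_manifest",
    "analyse_cohort",
    "cohort_statistics",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: Canonical output-column names for the default area fractions.
FRACTION_COLUMNS = {1.0: "pct_whole", 0.5: "pct_half", 1.0 / 3.0: "pct_third", 0.25: "pct_quarter"}

NUCLEAR_METRIC_COLUMNS = [f"max_{int(a)}" for a in NUCLEAR_MERIDIANS] + [
    f"mean_{int(a)}" for a in NUCLEAR_MERIDIANS
] + ["agg_max", "agg_mean"]


def fraction_column(fraction: float) -> str:
    for f, name in FRACTION_COLUMNS.items():
        if abs(fraction - f) < 1e-6:
            return name
    return f"pct_{fraction:.4f}"


@dataclass(frozen=True)
class SliceRecord:
    """One slice ready for measurement: image plus rasterized masks."""

    image: SliceImage
    nucleus_mask: Optional[PixelMask] = None
    cortex_mask: Optional[PixelMask] = None
    exclusions: Optional[ReflexExclusion] = None


@dataclass(frozen=True)
class EyeData:
    eye_id: str
    group: str
    locs_grade: float
    slices: Tuple[SliceRecord, ...]


@dataclass
class CohortResult:
    metrics: pd.DataFrame
    calibration: Optional[ThresholdCalibration]
    threshold: float
    descriptives: pd.DataFrame
    correlations: pd.DataFrame


class _MaskCache:
    """Rasterize each distinct ROI once per run (ROIs repeat across slices)."""

    def __init__(self) -> None:
        self._store: Dict = {}

    def ellipse(self, roi: EllipseROI, shape) -> PixelMask:
        key = ("e", roi, shape)
        if key not in self._store:
            self._store[key] = rasterize_ellipse(roi, shape)
        return self._store[key]

    def contour(self, roi: ContourROI, shape) -> PixelMask:
        key = ("c", roi, shape)
        if key not in self._store:
            self._store[key] = rasterize_contour(roi, shape)
        return self._store[key]

    def band(self, outer: ContourROI, inner: Optional[ContourROI], shape) -> PixelMask:
        key = ("b", outer, inner, shape)
        if key not in self._store:
            mask = self.contour(outer, shape)
            if inner is not None:
                mask = mask & ~self.contour(inner, shape)
            self._store[key] = mask
        return self._store[key]


def eye_from_synthetic(eye: SyntheticEye, cache: Optional[_MaskCache] = None) -> EyeData:
    """Build analysis-ready slice records from a phantom eye's *ROIs*.

    Masks are rasterized from the observer-style ROI parameters recorded in
    the phantom truth (not copied from the truth masks), so the full
    geometry path is exercised.
    """
    cache = cache or _MaskCache()
    rois = eye.truth.rois
    shape = eye.slices[0].shape
    nucleus = cache.ellipse(rois.nucleus, shape) if eye.group == "nuclear" else None
    cortex = (
        cache.band(rois.cortex_outer, rois.cortex_inner, shape)
        if eye.group in ("control", "cortical")
        else None
    )
    records = []
    for idx, image in enumerate(eye.slices):
        exclusions = ReflexExclusion.from_contours(rois.reflex_contours[idx], shape)
        records.append(
            SliceRecord(
                image=image, nucleus_mask=nucleus, cortex_mask=cortex, exclusions=exclusions
            )
        )
    return EyeData(
        eye_id=eye.eye_id,
        group=eye.group,
        locs_grade=eye.truth.grade,
        slices=tuple(records),
    )


def eyes_from_manifest(manifest: lio.RunManifest) -> List[EyeData]:
    """Load slice images and rasterize manifest ROIs into analysis records."""
    cache = _MaskCache()
    eyes: List[EyeData] = []
    for m_eye in manifest.eyes:
        records = []
        for sl in m_eye.slices:
            image = lio.load_slice_image(
                manifest.root / sl.file, sl.angle, eye_id=m_eye.eye_id, group=m_eye.group
            )
            shape = image.shape
            nucleus = cache.ellipse(m_eye.nucleus, shape) if m_eye.nucleus is not None else None
            cortex = (
                cache.band(m_eye.cortex_outer, m_eye.cortex_inner, shape)
                if m_eye.cortex_outer is not None
                else None
            )
            exclusions = ReflexExclusion.from_contours(sl.reflexes, shape)
            records.append(
                SliceRecord(
                    image=image, nucleus_mask=nucleus, cortex_mask=cortex, exclusions=exclusions
                )
            )
        eyes.append(
            EyeData(
                eye_id=m_eye.eye_id,
                group=m_eye.group,
                locs_grade=m_eye.locs_grade,
                slices=tuple(records),
            )
        )
    return eyes


def control_pixel_collections(eyes: Sequence[EyeData]) -> List[np.ndarray]:
    """Per-control-eye cortical pixel pools (reflexes removed) for calibration."""
    pools: List[np.ndarray] = []
    for eye in eyes:
        if eye.group != "control":
            continue
        chunks = []
        for rec in eye.slices:
            if rec.cortex_mask is None:
                continue
            effective = subtract_exclusions(rec.cortex_mask, rec.exclusions)
            chunks.append(rec.image.pixels[effective])
        if chunks:
            pools.append(np.concatenate(chunks))
    return pools


def analyse_cohort(
    eyes: Sequence[EyeData],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    threshold: Optional[float] = None,
    aggregation: str = "pooled",
) -> Tuple[pd.DataFrame, Optional[ThresholdCalibration], float]:
    """Measure every eye; returns (per-eye metrics table, calibration, threshold).

    If ``threshold`` is None it is calibrated from the control eyes' pooled
    cortex pixels.  Nuclear-group eyes must provide the four nuclear
    meridians; any failure aborts naming the eye.
    """
    calibration: Optional[ThresholdCalibration] = None
    if threshold is None:
        pools = control_pixel_collections(eyes)
        if not pools:
            raise ValueError(
                "no explicit threshold and no control eyes with a cortex ROI to calibrate from"
            )
        calibration = calibrate_threshold(pools)
        threshold = calibration.threshold
    threshold = float(threshold)

    rows = []
    for eye in eyes:
        logger.info("analysing eye %s (%s)", eye.eye_id, eye.group)
        row: Dict = {
            "eye_id": eye.eye_id,
            "group": eye.group,
            "locs_grade": eye.locs_grade,
            "threshold": threshold,
            "n_slices": len(eye.slices),
        }
        try:
            if eye.group == "nuclear":
                chosen = [
                    (rec.image, rec.nucleus_mask, rec.exclusions)
                    for rec in eye.slices
                    if _match_meridian(rec.image.meridian_angle) is not None
                ]
                nuc = eye_nuclear_metrics(chosen)
                for angle in NUCLEAR_MERIDIANS:
                    row[f"max_{int(angle)}"] = nuc.per_slice[angle].max_intensity
                    row[f"mean_{int(angle)}"] = nuc.per_slice[angle].mean_intensity
                row["agg_max"] = nuc.agg_max
                row["agg_mean"] = nuc.agg_mean
            if eye.group in ("control", "cortical"):
                slices = [
                    (rec.image, rec.cortex_mask, rec.exclusions)
                    for rec in eye.slices
                    if rec.cortex_mask is not None
                ]
                cort = eye_cortical_metrics(
                    slices, threshold, fractions=fractions, aggregation=aggregation
                )
                for f in fractions:
                    row[fraction_column(f)] = cort.percent_opaque[float(f)]
        except ValueError as err:
            raise ValueError(f"eye {eye.eye_id}: {err}") from err
        rows.append(row)

    columns = ["eye_id", "group", "locs_grade"] + NUCLEAR_METRIC_COLUMNS + [
        fraction_column(f) for f in fractions
    ] + ["threshold", "n_slices"]
    metrics = pd.DataFrame(rows)
    for col in columns:
        if col not in metrics.columns:
            metrics[col] = np.nan
    return metrics[columns], calibration, threshold


def cohort_statistics(
    metrics: pd.DataFrame, fractions: Sequence[float] = DEFAULT_FRACTIONS
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive tables (median [min-max] per grade) and Spearman results.

    Nuclear metrics are summarized over the nuclear cohort; cortical percent
    metrics over controls plus the cortical cohort (controls enter at grade
    0.0, below the LOCS range).
    """
    desc_rows = []
    corr_rows = []

    def add(cohort: str, metric: str, sub: pd.DataFrame) -> None:
        sub = sub.dropna(subset=[metric])
        if sub.empty:
            return
        table = descriptive_table(sub["locs_grade"], sub[metric])
        for grade, cells in table.iterrows():
            desc_rows.append(
                {
                    "cohort": cohort,
                    "metric": metric,
                    "grade": grade,
                    "n": int(cells["n"]),
                    "median": cells["median"],
                    "min": cells["min"],
                    "max": cells["max"],
                }
            )
        if sub["locs_grade"].nunique() > 1 and sub[metric].nunique() > 1 and len(sub) >= 3:
            res = spearman_with_grade(sub["locs_grade"], sub[metric])
            corr_rows.append(
                {
                    "cohort": cohort,
                    "metric": metric,
                    "n": res.n,
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "slope": res.slope,
                    "intercept": res.intercept,
                }
            )

    nuclear = metrics[metrics["group"] == "nuclear"]
    for col in NUCLEAR_METRIC_COLUMNS:
        add("nuclear", col, nuclear)
    cortical = metrics[metrics["group"].isin(["control", "cortical"])]
    for f in fractions:
        add("cortical", fraction_column(f), cortical)

    descriptives = pd.DataFrame(
        desc_rows, columns=["cohort", "metric", "grade", "n", "median", "min", "max"]
    )
    correlations = pd.DataFrame(
        corr_rows, columns=["cohort", "metric", "n", "rho", "p_value", "slope", "intercept"]
    )
    return descriptives, correlations


def run_pipeline(manifest_path: str | Path, out_dir: str | Path) -> CohortResult:
    """All-in-one run from a manifest: calibrate, measure, correlate, write.

    Writes ``metrics.csv`` (full precision), ``metrics_display.csv``
    (2-decimal, mirroring the clinical table formatting),
    ``descriptives.csv``, ``correlations.csv``, ``threshold.json`` and
    ``run.log`` into ``out_dir``; reruns are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    pkg_logger = logging.getLogger("lensopacity")
    pkg_logger.addHandler(log_handler)
    try:
        manifest = lio.load_manifest(manifest_path)
        eyes = eyes_from_manifest(manifest)
        metrics, calibration, threshold = analyse_cohort(
            eyes,
            fractions=manifest.fractions,
            threshold=manifest.threshold,
            aggregation=manifest.aggregation,
        )
        descriptives, correlations = cohort_statistics(metrics, fractions=manifest.fractions)

        metrics.to_csv(out_dir / "metrics.csv", index=False)
        display = metrics.copy()
        num_cols = display.select_dtypes(include=[np.number]).columns
        display[num_cols] = display[num_cols].round(2)
        display.to_csv(out_dir / "metrics_display.csv", index=False, float_format="%.2f")
        descriptives.to_csv(out_dir / "descriptives.csv", index=False)
        correlations.to_csv(out_dir / "correlations.csv", index=False)
        with open(out_dir / "threshold.json", "w") as fh:
            json.dump(
                {
                    "threshold": threshold,
                    "calibrated": calibration is not None,
                    "n_control_eyes": calibration.n_eyes if calibration else None,
                    "control_median": calibration.control_median if calibration else None,
                    "control_min": calibration.control_min if calibration else None,
                    "control_max": calibration.control_max if calibration else None,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        return CohortResult(
            metrics=metrics,
            calibration=calibration,
            threshold=threshold,
            descriptives=descriptives,
            correlations=correlations,
        )
    finally:
        pkg_logger.removeHandler(log_handler)
        log_handler.close()
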