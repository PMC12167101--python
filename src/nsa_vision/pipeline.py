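"""End-to-end orchestration over a cohort of AP/lateral image pairs.

For each hip the pipeline preprocesses both views, locates the
prosthesis by template matching, derives the femur region, extracts
line angles with the Hough transform and computes the per-view NSA.
Per-hip failures at any stage are recorded — never silently dropped —
so every discovered hip appears exactly once in the records or the
failure list, and a hip failing detection does not stop the rest of
the cohort.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import ground_truth as gt
from .angles import (
    HoughParams,
    NoLinesError,
    compute_nsa,
    detect_lines,
    exclude_orientation,
    median_angle,
)
from .config import PipelineConfig
from .detect import MatchResult, RegionOfInterest, derive_femur_roi, match_template
from .fusion import NsaRecord, predict_fused, records_to_csv, train_fusion
from .preprocess import FilterParams, bilateral_denoise, to_grayscale
from .synthetic_scene import load_template_bank, patient_of

logger = logging.getLogger(__name__)

__all__ = ["MeasurementError", "ViewMeasurement", "CohortRun", "measure_view", "run_cohort"]


class MeasurementError(RuntimeError):
    """A single hip/view could not be measured; carries the failing stage."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"[{stage}] {reason}")
        self.stage = stage
        self.reason = reason


@dataclass
class ViewMeasurement:
    """Everything measured on one view of one hip."""

    estimate: object  # NsaEstimate
    match: MatchResult
    femur_roi: RegionOfInterest


@dataclass
class CohortRun:
    """Outcome of a cohort run: per-hip records plus failure accounting."""

    records: list  # NsaRecord
    failures: list  # (hip_id, stage, reason)
    config: PipelineConfig
    hip_ids: list

    def conservation_holds(self) -> bool:
        return len(self.records) + len(self.failures) == len(self.hip_ids)


def measure_view(
    image: np.ndarray,
    templates,
    *,
    hough: HoughParams | None = None,
    filter_params: FilterParams | None = None,
    scales=None,
    normalize: bool = False,
    extent_factor: float = 2.0,
    femur_exclusion_deg: float = 15.0,
    view: str = "AP",
    seed: int = 0,
) -> ViewMeasurement:
    """Run preprocess -> detect -> angle extraction on a single view.

    The prosthesis box overlaps the proximal shaft by construction, so
    prosthesis-ROI lines within ``femur_exclusion_deg`` of the femur
    median orientation are attributed to the shaft and removed before
    the stem median is taken.
    """
    from .detect import DEFAULT_SCALES

    hough = hough or HoughParams()
    scales = scales if scales is not None else DEFAULT_SCALES
    try:
        gray = to_grayscale(np.asarray(image))
        smooth = bilateral_denoise(gray, filter_params or FilterParams())
    except ValueError as exc:
        raise MeasurementError("preprocess", str(exc)) from exc
    try:
        match = match_template(smooth, templates, scales, normalize=normalize)
        femur_roi = derive_femur_roi(match.roi, smooth.shape[0], extent_factor)
        # the prosthesis box is tight around the implant, so the shaft can
        # graze its lateral border; pad the femur box sideways to keep the
        # full shaft cross-section (both edges) in view
        pad = int(round(0.15 * femur_roi.width))
        x0 = max(0, femur_roi.x - pad)
        femur_roi = RegionOfInterest(
            x=x0,
            y=femur_roi.y,
            width=min(smooth.shape[1] - x0, femur_roi.width + pad + (femur_roi.x - x0)),
            height=femur_roi.height,
            label="femur",
        )
    except ValueError as exc:
        raise MeasurementError("detect", str(exc)) from exc
    # the shaft band spans the whole femur ROI while only the stem's
    # distal part protrudes from the cup, so the femur minimum segment
    # length is doubled: long segments bridge the pixel staircase of
    # near-vertical edges that otherwise yields spurious 90-degree lines
    femur_hough = dataclasses.replace(
        hough,
        min_line_length=int(
            np.clip(0.45 * femur_roi.height, 2 * hough.min_line_length, 75)
        ),
    )
    # blank the matched cup out of the prosthesis edge map: its boundary
    # is a circle whose short chords would otherwise pass for stem edges;
    # the margin covers the smoothed curl where the stem exits the cup
    masks = []
    margin = 3.0 + 4.0 * hough.canny_sigma
    if match.prosthesis_center is not None and np.isfinite(match.cup_radius):
        masks.append(
            (
                match.prosthesis_center[0] - match.roi.x,
                match.prosthesis_center[1] - match.roi.y,
                match.cup_radius + margin,
            )
        )
    if match.stem_tip is not None:
        # the stem-shaft junction: the smoothed corner there curls the
        # edge contour and would tilt the adjacent stem segments
        masks.append((match.stem_tip[0] - match.roi.x, match.stem_tip[1] - match.roi.y, margin))
    try:
        femur_lines = _detect_with_fallback(
            smooth,
            femur_roi,
            [
                femur_hough,
                dataclasses.replace(hough, min_line_length=2 * hough.min_line_length),
                hough,
            ],
            seed=seed,
        )
        pros_lines = _detect_with_fallback(
            smooth,
            match.roi,
            [hough, dataclasses.replace(hough, min_line_length=max(8, hough.min_line_length // 2))],
            seed=seed + 1,
            exclude_disk=masks or None,
        )
        if len(femur_lines) and femur_exclusion_deg > 0:
            pros_lines = exclude_orientation(
                pros_lines, median_angle(femur_lines), femur_exclusion_deg
            )
        estimate = compute_nsa(femur_lines, pros_lines, view=view)
    except (NoLinesError, ValueError) as exc:
        raise MeasurementError("angles", str(exc)) from exc
    return ViewMeasurement(estimate=estimate, match=match, femur_roi=femur_roi)


def _detect_with_fallback(image, roi, params_ladder, *, seed, exclude_disk=None):
    """Try successively shorter minimum line lengths before giving up.

    Long segments carry the most accurate angles, so the first rung is
    preferred; a hip is only marked unmeasurable when even the last
    rung finds nothing (mirroring the exclusion of inadequate imaging).
    """
    line_set = None
    for hp in params_ladder:
        line_set = detect_lines(image, roi, hp, seed=seed, exclude_disk=exclude_disk)
        if len(line_set):
            return line_set
    return line_set


def _discover_hips(image_dir: Path) -> list:
    return sorted(p.name[: -len("_AP.png")] for p in image_dir.glob("*_AP.png"))


def _load_truth(path) -> pd.Series:
    """Clinician AP NSA per hip, from a truth CSV or a landmark CSV."""
    df = pd.read_csv(Path(path), nrows=1)
    if "structure" in df.columns:
        table = gt.nsa_table(gt.read_landmarks(path))
        return table.set_index("hip_id")["nsa_ap_clinician"]
    full = pd.read_csv(Path(path))
    for col in ("nsa_ap_clinician", "true_nsa_ap"):
        if col in full.columns:
            return full.set_index(full["hip_id"].astype(str))[col].astype(float)
    raise ValueError(
        "truth file must provide nsa_ap_clinician/true_nsa_ap columns or landmark rows"
    )


def run_cohort(
    image_dir,
    templates,
    truth,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> CohortRun:
    """Measure every ``<hipID>_AP.png`` / ``<hipID>_LAT.png`` pair.

    ``templates`` may be a template-bank directory or an in-memory
    list; ``truth`` a per-hip NSA CSV or a landmark CSV.  When
    ``out_dir`` is given, writes ``records.csv``, ``failures.csv`` and
    ``run_config.resolved``; output is byte-identical across repeated
    runs with the same inputs, config and seed.
    """
    config = config or PipelineConfig()
    image_dir = Path(image_dir)
    if isinstance(templates, (str, Path)):
        templates = load_template_bank(templates)
    truth_by_hip = _load_truth(truth)

    hip_ids = _discover_hips(image_dir)
    records, failures = [], []
    for i, hip_id in enumerate(hip_ids):
        lat_path = image_dir / f"{hip_id}_LAT.png"
        if not lat_path.exists():
            failures.append((hip_id, "input", "missing lateral view"))
            continue
        if hip_id not in truth_by_hip.index:
            failures.append((hip_id, "input", "no ground-truth NSA"))
            continue
        try:
            ap = measure_view(
                iio.imread(image_dir / f"{hip_id}_AP.png"),
                templates,
                hough=config.hough,
                filter_params=config.preprocess,
                scales=config.detect.scales,
                normalize=config.detect.normalize,
                extent_factor=config.detect.extent_factor,
                femur_exclusion_deg=config.detect.femur_exclusion_deg,
                view="AP",
                seed=(config.seed * 1009 + 2 * i) % (2**31),
            )
            lat = measure_view(
                iio.imread(lat_path),
                templates,
                hough=config.hough,
                filter_params=config.preprocess,
                scales=config.detect.scales,
                normalize=config.detect.normalize,
                extent_factor=config.detect.extent_factor,
                femur_exclusion_deg=config.detect.femur_exclusion_deg,
                view="lateral",
                seed=(config.seed * 1009 + 2 * i + 1) % (2**31),
            )
        except MeasurementError as exc:
            logger.info("hip %s failed at %s: %s", hip_id, exc.stage, exc.reason)
            failures.append((hip_id, exc.stage, exc.reason))
            continue
        logger.info(
            "hip %s: AP NSA %.2f, lateral NSA %.2f",
            hip_id,
            ap.estimate.nsa,
            lat.estimate.nsa,
        )
        records.append(
            NsaRecord(
                hip_id=hip_id,
                patient_id=patient_of(hip_id),
                nsa_ap_cv=ap.estimate.nsa,
                nsa_lateral_cv=lat.estimate.nsa,
                nsa_ap_clinician=float(truth_by_hip.loc[hip_id]),
            )
        )

    run = CohortRun(records=records, failures=failures, config=config, hip_ids=hip_ids)
    if out_dir is not None:
        write_outputs(run, out_dir)
    return run


def fuse_cohort(run: CohortRun):
    """Train the fusion network on a cohort run and fill fused NSAs.

    Returns ``(model, report)``; every record within the scale range
    gets its ``nsa_ap_fused`` populated (including training records,
    for inspection — evaluation uses the held-out fold only).
    """
    model, report = train_fusion(run.records, run.config.fusion)
    excluded = set(report.excluded_ids)
    for rec in run.records:
        if rec.hip_id not in excluded:
            rec.nsa_ap_fused = predict_fused(model, rec.nsa_ap_cv, rec.nsa_lateral_cv)
    return model, report


def write_outputs(run: CohortRun, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records_to_csv(run.records, out_dir / "records.csv")
    pd.DataFrame(run.failures, columns=["hip_id", "stage", "reason"]).to_csv(
        out_dir / "failures.csv", index=False
    )
    (out_dir / "run_config.resolved").write_text(run.config.to_json())
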