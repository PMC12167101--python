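"""Line-angle extraction with the Hough transform and NSA computation.

Within each region of interest (femur band, prosthesis), edges are
extracted with a Canny detector and straight segments are found with
the probabilistic Hough transform, which returns finite segments so a
minimum detected-line length is directly meaningful.  Each region's
segment angles are reduced to their median — robust to stray background
lines — and the neck-shaft angle is the sum of the absolute median
femur and median prosthesis angles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

from .detect import RegionOfInterest
from .geometry import segment_angle

__all__ = [
    "HoughParams",
    "LineSet",
    "NsaEstimate",
    "NoLinesError",
    "detect_lines",
    "median_angle",
    "compute_nsa",
    "tune_hough",
]


class NoLinesError(RuntimeError):
    """No lines detected in a region; the hip cannot be measured.

    Mirrors the clinical exclusion of radiographs with inadequate
    imaging: the pipeline records the hip as failed rather than
    guessing an angle.
    """


@dataclass(frozen=True)
class HoughParams:
    """Edge and line detection parameters.

    ``min_line_length`` and ``vote_threshold`` are the two tunable
    knobs (see :func:`tune_hough`); ``canny_low``/``canny_high`` are
    hysteresis thresholds on the 0-255 intensity scale and
    ``canny_sigma`` the Gaussian pre-smoothing width in pixels.
    ``angle_resolution`` sets the Hough angle discretisation in
    degrees.  Segments are accumulated on the native pixel grid, so
    ``rho_resolution`` must be 1.
    """

    min_line_length: int = 20
    vote_threshold: int = 10
    canny_low: float = 50.0
    canny_high: float = 150.0
    angle_resolution: float = 1.0
    rho_resolution: float = 1.0
    line_gap: int = 3
    canny_sigma: float = 1.2

    def __post_init__(self):
        if self.min_line_length < 1:
            raise ValueError("min_line_length must be >= 1")
        if self.vote_threshold < 1:
            raise ValueError("vote_threshold must be >= 1")
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if self.angle_resolution <= 0:
            raise ValueError("angle_resolution must be positive")
        if self.rho_resolution != 1.0:
            raise ValueError("segment accumulation uses the pixel grid; rho_resolution must be 1")
        if self.line_gap < 0 or self.canny_sigma <= 0:
            raise ValueError("invalid line_gap or canny_sigma")


@dataclass
class LineSet:
    """Detected lines as (radius, signed angle) pairs plus provenance.

    ``radius`` is the perpendicular distance from the ROI-crop origin
    to the (infinite) line through the segment; ``angle`` is the signed
    from-horizontal angle in (-90, 90].  ``segments`` retains the raw
    endpoints for inspection.
    """

    lines: list  # (radius, angle) tuples
    source_roi: RegionOfInterest
    params: HoughParams
    segments: list  # ((x0, y0), (x1, y1)) tuples, ROI-local

    def __len__(self):
        return len(self.lines)

    @property
    def angles(self) -> np.ndarray:
        return np.array([a for _, a in self.lines], dtype=float)


@dataclass(frozen=True)
class NsaEstimate:
    """NSA from the median femur and median prosthesis line angles."""

    median_femur_angle: float
    median_prosthesis_angle: float
    nsa: float
    view: str

    def __post_init__(self):
        if self.view not in ("AP", "lateral"):
            raise ValueError(f"view must be 'AP' or 'lateral', got {self.view!r}")
        if not 0.0 <= self.nsa <= 180.0:
            raise ValueError(f"nsa {self.nsa:.2f} outside [0, 180]")


def _segment_radius(p0, p1) -> float:
    """Perpendicular distance from the crop origin to the segment's line."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    return float(abs(d[0] * p0[1] - d[1] * p0[0]) / np.hypot(*d))


def detect_lines(
    image: np.ndarray,
    roi: RegionOfInterest,
    params: HoughParams | None = None,
    *,
    seed: int = 0,
    exclude_disk=None,
) -> LineSet:
    """Canny edges + probabilistic Hough line search inside an ROI.

    The probabilistic transform samples edge pixels in random order, so
    a seed is required for reproducible output.  Returns all segments
    meeting the length and vote thresholds, with angles converted to
    the signed-from-horizontal convention.

    ``exclude_disk`` — an optional ``(cx, cy, radius)`` triple or list
    of triples in ROI-local coordinates — blanks discs out of the edge
    map before the line search.  The pipeline uses this to remove the
    hemispherical cup boundary (a curve, not a line) and the stem tip
    corner once template matching has located them, so cup chords and
    junction curl cannot masquerade as stem edges.
    """
    params = params or HoughParams()
    crop = roi.crop(np.asarray(image, dtype=np.float64))
    if crop.size == 0:
        raise ValueError("empty ROI crop")
    edges = canny(
        crop,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low,
        high_threshold=params.canny_high,
    )
    if exclude_disk is not None:
        disks = exclude_disk if isinstance(exclude_disk, list) else [exclude_disk]
        yy, xx = np.mgrid[: edges.shape[0], : edges.shape[1]]
        for cx, cy, radius in disks:
            edges[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = False
    theta = np.deg2rad(np.arange(-90.0, 90.0, params.angle_resolution))
    segments = probabilistic_hough_line(
        edges,
        threshold=params.vote_threshold,
        line_length=params.min_line_length,
        line_gap=params.line_gap,
        theta=theta,
        rng=np.random.default_rng(seed),
    )
    lines = [
        (_segment_radius(p0, p1), segment_angle(p0, p1)) for p0, p1 in segments
    ]
    return LineSet(lines=lines, source_roi=roi, params=params, segments=list(segments))


def orientation_distance(angle_a: float, angle_b: float) -> float:
    """Angular distance between two undirected line orientations, in [0, 90]."""
    d = abs(angle_a - angle_b) % 180.0
    return min(d, 180.0 - d)


def exclude_orientation(line_set: LineSet, angle: float, tolerance: float) -> LineSet:
    """Drop lines within ``tolerance`` degrees of a given orientation.

    The prosthesis search box necessarily overlaps the proximal
    femoral shaft (the stem tip sits on it), so shaft edges can leak
    into the prosthesis line set; once the femur axis is known, lines
    parallel to it are attributed to the femur and removed before the
    stem median is taken.  If every line would be removed the set is
    returned unchanged (better a contaminated median than none).
    """
    keep = [
        (line, seg)
        for line, seg in zip(line_set.lines, line_set.segments)
        if orientation_distance(line[1], angle) > tolerance
    ]
    if not keep:
        return line_set
    return LineSet(
        lines=[line for line, _ in keep],
        source_roi=line_set.source_roi,
        params=line_set.params,
        segments=[seg for _, seg in keep],
    )


def median_angle(line_set: LineSet) -> float:
    """Median of the detected line angles (mean of middle two for even counts)."""
    if len(line_set) == 0:
        raise NoLinesError(
            f"no lines detected in {line_set.source_roi.label} ROI"
        )
    return float(np.median(line_set.angles))


def compute_nsa(femur_lines: LineSet, prosthesis_lines: LineSet, view: str = "AP") -> NsaEstimate:
    """NSA = |median femur angle| + |median prosthesis angle|."""
    a_f = median_angle(femur_lines)
    a_p = median_angle(prosthesis_lines)
    return NsaEstimate(
        median_femur_angle=a_f,
        median_prosthesis_angle=a_p,
        nsa=abs(a_f) + abs(a_p),
        view=view,
    )


def tune_hough(
    tuning_scenes,
    grid: dict,
    *,
    templates,
    base_params: HoughParams | None = None,
    filter_params=None,
    scales=None,
    extent_factor: float = 2.0,
    seed: int = 0,
) -> HoughParams:
    """Grid-search the two Hough knobs against known-geometry scenes.

    ``grid`` maps ``min_line_length`` and/or ``vote_threshold`` to
    candidate values.  For each combination the full AP measurement
    (preprocess, detect, extract angles) is run on every tuning scene
    and the combination minimising the mean absolute NSA error is
    returned; a combination failing on any scene is discarded.  Ties
    break toward larger ``min_line_length``, then larger
    ``vote_threshold``.
    """
    from . import pipeline  # deferred: pipeline imports this module

    if not tuning_scenes:
        raise ValueError("at least one tuning scene required")
    base = base_params or HoughParams()
    lengths = list(grid.get("min_line_length", [base.min_line_length]))
    votes = list(grid.get("vote_threshold", [base.vote_threshold]))
    unknown = set(grid) - {"min_line_length", "vote_threshold"}
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")

    results = []
    for mll, vt in itertools.product(lengths, votes):
        params = replace(base, min_line_length=int(mll), vote_threshold=int(vt))
        errors = []
        try:
            for i, scene in enumerate(tuning_scenes):
                m = pipeline.measure_view(
                    scene.ap_image,
                    templates,
                    hough=params,
                    filter_params=filter_params,
                    scales=scales,
                    extent_factor=extent_factor,
                    view="AP",
                    seed=seed + i,
                )
                errors.append(abs(m.estimate.nsa - scene.true_nsa_ap))
        except (NoLinesError, ValueError, pipeline.MeasurementError):
            continue
        results.append((float(np.mean(errors)), -int(mll), -int(vt), params))
    if not results:
        raise RuntimeError("every grid point failed on the tuning scenes")
    results.sort(key=lambda r: r[:3])
    return results[0][3]
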