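"""Prosthesis localisation by exhaustive mean-squared-error template matching.

The implant is found by sliding every reference template (at a small
set of scales) over the image with stride 1 and taking the placement
with the lowest mean squared intensity error; the femur search region
is then the rectangle directly below the detected prosthesis.

The sliding-window MSE surface is computed with an FFT cross-correlation
plus integral-image window sums, and the near-minimal placements are
re-evaluated exactly, so the winner (including tie-breaks) is identical
to a brute-force scan over every (position, template, scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import resize

from .synthetic_scene import Template

__all__ = [
    "RegionOfInterest",
    "MatchResult",
    "mse_score",
    "match_template",
    "derive_femur_roi",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = (0.8, 1.0, 1.25)

# absolute slack on the fast MSE surface inside which candidates are
# re-scored exactly; far larger than FFT round-off, far smaller than the
# spacing of distinct MSE values on 8-bit images
_REFINE_TOL = 1e-3


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangle in image coordinates (x right, y down)."""

    x: int
    y: int
    width: int
    height: int
    label: str = "prosthesis"

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must have width and height >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.label not in ("prosthesis", "femur"):
            raise ValueError(f"unknown ROI label {self.label!r}")

    @property
    def bottom(self) -> int:
        return self.y + self.height

    @property
    def center(self) -> tuple:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    def crop(self, image: np.ndarray) -> np.ndarray:
        h, w = image.shape[:2]
        if self.bottom > h or self.x + self.width > w:
            raise ValueError("ROI exceeds image bounds")
        return image[self.y : self.bottom, self.x : self.x + self.width]


@dataclass(frozen=True)
class MatchResult:
    """Best template placement found by :func:`match_template`."""

    roi: RegionOfInterest
    template_index: int
    scale: float
    mse: float
    prosthesis_center: tuple | None = None  # (x, y) if the template knows its cup centre
    cup_radius: float = float("nan")  # scaled template cup radius, px
    stem_tip: tuple | None = None  # (x, y) scaled template stem tip

    def __post_init__(self):
        if self.mse < 0:
            raise ValueError("mse must be non-negative")


def mse_score(window: np.ndarray, template: np.ndarray) -> float:
    """Mean over pixels of the squared intensity difference."""
    window = np.asarray(window, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if window.shape != template.shape:
        raise ValueError(
            f"window shape {window.shape} != template shape {template.shape}"
        )
    return float(np.mean((window - template) ** 2))


def _window_sums(arr: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Sliding-window sums of ``arr`` for every th x tw placement."""
    s = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=s[1:, 1:])
    return s[th:, tw:] - s[:-th, tw:] - s[th:, :-tw] + s[:-th, :-tw]


def _mse_surface(image: np.ndarray, template: np.ndarray, normalize: bool) -> np.ndarray:
    """Approximate sliding MSE for every valid placement (row-major grid)."""
    template = np.asarray(template, dtype=np.float64)
    th, tw = template.shape
    n = th * tw
    cross = fftconvolve(image, template[::-1, ::-1], mode="valid")
    win_sq = _window_sums(image**2, th, tw)
    ssd = win_sq - 2.0 * cross + float(np.sum(template**2))
    if normalize:
        win_mean = _window_sums(image, th, tw) / n
        ssd = ssd - n * (win_mean - float(np.mean(template))) ** 2
    return np.maximum(ssd, 0.0) / n


def _exact_mse(image, template, y, x, normalize):
    template = np.asarray(template, dtype=np.float64)
    th, tw = template.shape
    w = image[y : y + th, x : x + tw]
    if normalize:
        return mse_score(w - np.mean(w), template - np.mean(template))
    return mse_score(w, template)


def _as_template(obj) -> Template:
    if isinstance(obj, Template):
        return obj
    arr = np.asarray(obj)
    return Template(image=arr, cup_center=None, cup_radius=float("nan"), stem_angle=float("nan"))


def _rescale_template(t: Template, scale: float) -> Template:
    if scale == 1.0:
        return t
    h = max(1, int(round(t.image.shape[0] * scale)))
    w = max(1, int(round(t.image.shape[1] * scale)))
    img = resize(
        t.image.astype(np.float64),
        (h, w),
        order=1,
        anti_aliasing=scale < 1.0,
        preserve_range=True,
    )
    sx, sy = w / t.image.shape[1], h / t.image.shape[0]
    center = None if t.cup_center is None else (t.cup_center[0] * sx, t.cup_center[1] * sy)
    tip = None if t.stem_tip is None else (t.stem_tip[0] * sx, t.stem_tip[1] * sy)
    return Template(
        image=img,
        cup_center=center,
        cup_radius=t.cup_radius * scale,
        stem_angle=t.stem_angle,
        stem_tip=tip,
    )


def match_template(
    image: np.ndarray,
    templates,
    scales=DEFAULT_SCALES,
    *,
    normalize: bool = False,
) -> MatchResult:
    """Exhaustive minimum-MSE placement over positions, templates and scales.

    Ties are broken by row-major position (first encounter), then lower
    template index, then smaller scale.  ``normalize=True`` subtracts
    the window and template means before scoring (useful when real
    images and references differ in brightness).

    Raises ``ValueError`` when no scaled template fits inside the image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("match_template expects a grayscale image")
    scales = sorted(float(s) for s in scales)
    if not scales or min(scales) <= 0:
        raise ValueError("scales must be positive")

    candidates = []  # (approx_mse, y, x, t_idx, scale, scaled_template)
    best_fast = np.inf
    surfaces = []
    for t_idx, raw in enumerate(templates):
        base = _as_template(raw)
        for scale in scales:
            st = _rescale_template(base, scale)
            th, tw = st.image.shape
            if th > image.shape[0] or tw > image.shape[1]:
                continue
            surf = _mse_surface(image, st.image, normalize)
            surfaces.append((surf, t_idx, scale, st))
            best_fast = min(best_fast, float(surf.min()))
    if not surfaces:
        raise ValueError("no template fits inside the image at any scale")

    for surf, t_idx, scale, st in surfaces:
        ys, xs = np.nonzero(surf <= best_fast + _REFINE_TOL)
        for y, x in zip(ys.tolist(), xs.tolist()):
            exact = _exact_mse(image, st.image, y, x, normalize)
            candidates.append((exact, y, x, t_idx, scale, st))

    exact, y, x, t_idx, scale, st = min(candidates, key=lambda c: c[:5])
    th, tw = st.image.shape
    center = None
    if st.cup_center is not None:
        center = (x + st.cup_center[0], y + st.cup_center[1])
    tip = None if st.stem_tip is None else (x + st.stem_tip[0], y + st.stem_tip[1])
    return MatchResult(
        roi=RegionOfInterest(x=x, y=y, width=tw, height=th, label="prosthesis"),
        template_index=t_idx,
        scale=scale,
        mse=exact,
        prosthesis_center=center,
        cup_radius=st.cup_radius,
        stem_tip=tip,
    )


def derive_femur_roi(
    prosthesis_roi: RegionOfInterest,
    image_height: int,
    extent_factor: float = 2.0,
) -> RegionOfInterest:
    """Femur search region: the area directly under the prosthesis.

    Same x-extent as the prosthesis box, starting at its bottom edge,
    ``extent_factor`` times its height tall, clipped to the image.
    """
    if extent_factor <= 0:
        raise ValueError("extent_factor must be positive")
    y = prosthesis_roi.bottom
    if y >= image_height:
        raise ValueError(
            "prosthesis reaches the image bottom; no room to locate the femur"
        )
    height = min(int(round(extent_factor * prosthesis_roi.height)), image_height - y)
    return RegionOfInterest(
        x=prosthesis_roi.x,
        y=y,
        width=prosthesis_roi.width,
        height=height,
        label="femur",
    )
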