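"""Dye-front detection: rectify, crop, saturation, binarize, localize.

The pipeline mirrors the imaging workflow of the indicator-based dye front
analysis (IDA) setup: frames are projectively rectified, each vial's gel
column is cropped via its ROI, the HSV saturation channel is extracted
(yellow gel and blue gel are both saturated, but differently so under the
yellow backlight), Otsu-binarized, reduced to a per-row foreground-fraction
profile, and the blue/yellow interface is localized at the topmost sub-pixel
crossing of the profile through the configured level.

Positions are reported both in pixels (absolute image rows) and in mm of
displacement below the reference position x0, which is taken from the
pre-gassing first frame (falling back to the gel surface row when that frame
shows no interface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .synth import FrameSeries

__all__ = [
    "CalibrationModel",
    "VialROI",
    "DetectionConfig",
    "InterfaceHit",
    "InterfaceTrack",
    "NoInterfaceError",
    "otsu_threshold",
    "rectify",
    "saturation_image",
    "binarize",
    "row_profile",
    "detect_interface",
    "track_series",
    "px_to_mm",
    "mm_to_px",
    "estimate_homography",
]

OK = "ok"
NO_INTERFACE = "no_interface"


class NoInterfaceError(ValueError):
    """Binarization cannot separate two classes (constant image)."""


@dataclass(frozen=True)
class CalibrationModel:
    """Geometric rectification plus the pixel-to-mm conversion factor."""

    mm_per_px: float = 0.0681
    homography: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be > 0, got {self.mm_per_px}")
        h = np.asarray(self.homography, dtype=float)
        if h.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(h)) < 1e-12:
            raise ValueError("homography is singular")
        object.__setattr__(self, "homography", h)

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.homography, np.eye(3))


@dataclass(frozen=True)
class VialROI:
    """Half-open, 0-based pixel bounds of one vial's gel column."""

    col_start: int
    col_end: int
    row_start: int
    row_end: int
    gel_top_row: int

    def __post_init__(self) -> None:
        if not (self.col_start < self.col_end and self.row_start < self.row_end):
            raise ValueError("ROI start must precede end on both axes")
        if not self.row_start <= self.gel_top_row < self.row_end:
            raise ValueError("gel_top_row must lie within the ROI rows")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start


@dataclass(frozen=True)
class DetectionConfig:
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.5
    smooth_window_rows: int = 5
    min_contrast: float = 0.2
    crossing_level: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.smooth_window_rows < 1 or self.smooth_window_rows % 2 == 0:
            raise ValueError("smooth_window_rows must be an odd integer >= 1")
        for name in ("fixed_threshold", "min_contrast", "crossing_level"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class InterfaceHit:
    """Result of localizing the interface in one profile."""

    row: float | None  # absolute sub-pixel image row, None when not found
    flag: str  # "ok" | "no_interface"
    n_crossings: int = 0


@dataclass
class InterfaceTrack:
    """Per-vial interface positions over a frame series.

    ``position_mm`` is the displacement below the reference x0 (downward
    positive); ``position_px`` the absolute sub-pixel row (nan when the
    frame had no detectable interface).
    """

    vial_id: int
    times_s: np.ndarray
    position_px: np.ndarray
    position_mm: np.ndarray
    x0_px: float
    flags: list[str]
    mm_per_px: float

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if not (len(self.position_px) == len(self.position_mm) == len(self.flags) == n):
            raise ValueError("track arrays must have equal length")


def rectify(image: np.ndarray, cal: CalibrationModel) -> np.ndarray:
    """Undo projective distortion by warping with the inverse homography.

    Bilinear sampling onto a same-size canvas; an identity homography is an
    exact no-op.
    """
    if cal.is_identity:
        return np.array(image, copy=True)
    tf = ProjectiveTransform(matrix=cal.homography)
    return warp(image, tf.inverse, order=1, mode="edge", preserve_range=True)


def saturation_image(rgb: np.ndarray) -> np.ndarray:
    """HSV saturation channel: S = (max - min) / max, with S = 0 where max = 0."""
    rgb = np.asarray(rgb, dtype=float)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return s


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold by exact between-class variance maximization.

    Candidate cuts are the midpoints between consecutive distinct values, so
    the maximization is exhaustive rather than limited to a binned histogram
    — on the near-noise-free synthetic frames a coarse histogram makes the
    threshold snap unpredictably inside the inter-mode gap.  Ties are broken
    by the middle of the maximizing cut range.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    uniq, counts = np.unique(vals, return_counts=True)
    if len(uniq) < 2:
        raise NoInterfaceError("constant image: Otsu cannot separate classes")
    w = np.cumsum(counts)[:-1]  # pixels at or below each candidate cut
    total = vals.size
    csum = np.cumsum(uniq * counts)[:-1]
    mean0 = csum / w
    mean1 = (csum[-1] + uniq[-1] * counts[-1] - csum) / (total - w)
    sigma_b = (w / total) * (1 - w / total) * (mean0 - mean1) ** 2
    best = sigma_b >= sigma_b.max() * (1.0 - 1e-12)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    lo, hi = cuts[best][0], cuts[best][-1]
    return float((lo + hi) / 2.0)


def binarize(gray: np.ndarray, config: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Threshold a [0,1] grayscale image; foreground = above threshold.

    Otsu (exhaustive between-class variance maximization) by default, or the
    configured fixed threshold.

    Raises
    ------
    NoInterfaceError
        Under Otsu when the image is constant (no threshold separates
        two classes).
    """
    gray = np.asarray(gray, dtype=float)
    if config.threshold_method == "fixed":
        return gray > config.fixed_threshold
    if np.ptp(gray) < 1e-6:  # constant up to float round-off
        raise NoInterfaceError("constant image: Otsu cannot separate classes")
    return gray > otsu_threshold(gray)


def row_profile(
    binary: np.ndarray, roi: VialROI, config: DetectionConfig = DetectionConfig()
) -> np.ndarray:
    """Per-row foreground fraction across the ROI columns, smoothed.

    Moving-average smoothing over ``smooth_window_rows`` rows; edge rows use
    the truncated window.  ``binary`` may be the full frame or already the
    ROI crop (matching the ROI's height and width).
    """
    if binary.shape[0] == roi.height and binary.shape[1] == roi.col_end - roi.col_start:
        crop = binary
    else:
        crop = binary[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    if crop.size == 0:
        raise ValueError("empty ROI")
    p = crop.mean(axis=1).astype(float)
    w = config.smooth_window_rows
    if w == 1:
        return p
    kernel = np.ones(w)
    sums = np.convolve(p, kernel, mode="same")
    counts = np.convolve(np.ones_like(p), kernel, mode="same")
    return sums / counts


def detect_interface(
    profile: np.ndarray, roi: VialROI, config: DetectionConfig = DetectionConfig()
) -> InterfaceHit:
    """Localize the interface as the topmost sub-pixel crossing of the profile.

    Scanning downward from the gel surface row, the first place the profile
    crosses ``crossing_level`` from above is linearly interpolated between the
    bracketing rows.  A profile whose total range falls below ``min_contrast``
    is treated as interface-free (uniformly blue or fully converted gel).
    Multiple crossings keep the topmost; their count is recorded.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) != roi.height:
        raise ValueError("profile length must equal the ROI height")
    if np.ptp(profile) < config.min_contrast:
        return InterfaceHit(None, NO_INTERFACE)

    start = roi.gel_top_row - roi.row_start
    lvl = config.crossing_level
    rows = []
    for i in range(start, len(profile) - 1):
        a, b = profile[i], profile[i + 1]
        if a >= lvl > b:
            frac = (a - lvl) / (a - b) if a != b else 0.5
            rows.append(roi.row_start + i + frac)
    if not rows:
        return InterfaceHit(None, NO_INTERFACE)
    return InterfaceHit(rows[0], OK, n_crossings=len(rows))


def _locate_in_frame(
    frame: np.ndarray, roi: VialROI, cal: CalibrationModel, config: DetectionConfig
) -> InterfaceHit:
    rect = rectify(frame, cal)
    sat = saturation_image(rect)
    crop = sat[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    try:
        binary = binarize(crop, config)
    except NoInterfaceError:
        return InterfaceHit(None, NO_INTERFACE)
    # Genuine blue/yellow frames separate into classes ~0.25 apart in
    # saturation; a threshold that merely splits the noise of a uniformly
    # coloured gel (pre-gassing, or fully converted) yields classes far
    # closer together and only spurious crossings.
    if config.threshold_method == "otsu":
        sep = float(crop[binary].mean() - crop[~binary].mean())
        if sep < config.min_contrast:
            return InterfaceHit(None, NO_INTERFACE)
    profile = row_profile(binary, roi, config)
    return detect_interface(profile, roi, config)


def track_series(
    series: FrameSeries,
    rois: list[VialROI],
    cal: CalibrationModel = CalibrationModel(),
    config: DetectionConfig = DetectionConfig(),
) -> list[InterfaceTrack]:
    """Run detection over a whole series and build per-vial tracks.

    The reference x0 per vial comes from the t=0 pre-gassing frame; when that
    frame shows no interface (the normal case: uniformly blue gel) x0 falls
    back to the vial's gel surface row.  Later frames are localized
    independently; depths are ``(row - x0) * mm_per_px``.
    """
    if series.times_s[0] != 0:
        raise ValueError("first frame must be the t=0 reference")

    tracks = []
    for v, roi in enumerate(rois):
        hit0 = _locate_in_frame(series.frames[0], roi, cal, config)
        x0 = hit0.row if hit0.flag == OK else float(roi.gel_top_row)

        pos_px, pos_mm, flags = [], [], []
        for frame in series.frames:
            hit = _locate_in_frame(frame, roi, cal, config)
            if hit.flag == OK:
                pos_px.append(hit.row)
                pos_mm.append((hit.row - x0) * cal.mm_per_px)
                flags.append(OK)
            else:
                pos_px.append(np.nan)
                pos_mm.append(np.nan)
                flags.append(hit.flag)
        tracks.append(
            InterfaceTrack(
                vial_id=v,
                times_s=np.asarray(series.times_s, dtype=float),
                position_px=np.asarray(pos_px),
                position_mm=np.asarray(pos_mm),
                x0_px=float(x0),
                flags=flags,
                mm_per_px=cal.mm_per_px,
            )
        )
    return tracks


def px_to_mm(px: float | np.ndarray, cal: CalibrationModel) -> float | np.ndarray:
    """Pixels to millimetres via the calibration conversion factor."""
    return px * cal.mm_per_px


def mm_to_px(mm: float | np.ndarray, cal: CalibrationModel) -> float | np.ndarray:
    return mm / cal.mm_per_px


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Estimate a 3x3 projective matrix from >= 4 corresponding point pairs."""
    tf = ProjectiveTransform()
    if not tf.estimate(np.asarray(src, float), np.asarray(dst, float)):
        raise ValueError("homography estimation failed")
    return tf.params
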