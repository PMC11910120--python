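"""Synthetic time-lapse renderer for indicator-doped hydrogel vials.

Stands in for the confidential original recordings: a blue (alkaline) gel
column acidifies from the top down, the colour interface depth growing with
the square root of time.  The renderer reproduces the optical features the
detection pipeline has to cope with — a sigmoidal blue-to-yellow colour
transition, the yellow backlight filter that merges the green transition
colour with the background, a vertical illumination gradient, additive sensor
noise, and a slowly dropping water meniscus — and records exact per-frame
ground truth so detection accuracy can be scored.

Coordinate convention (used everywhere in this package): row 0 is the image
top, depth increases downward, ROIs are half-open and 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chemistry import BROMOTHYMOL_BLUE, IndicatorSpec, front_position

__all__ = [
    "VialGeometry",
    "RenderConfig",
    "FrameSeries",
    "render_frame",
    "apply_yellow_filter",
    "render_series",
    "render_series_from_depths",
    "render_multivial",
    "DEFAULT_TIMES_S",
]

#: Acquisition protocol: one pre-gassing reference frame, then every 5 min
#: for an hour (13 frames).
DEFAULT_TIMES_S = np.arange(0, 3601, 300)

# Backlight (through the filter it reads yellow) and supernatant water.
_BACKGROUND_COLOR = np.array([0.95, 0.95, 0.92])
_WATER_COLOR = np.array([0.88, 0.92, 0.95])


@dataclass(frozen=True)
class VialGeometry:
    """Pixel/physical layout of one vial image.

    Defaults model a 6 mm inner-diameter vial holding 150 uL of gel
    (5.3 mm column) under ~200 uL of water, imaged at 0.0681 mm/px.
    """

    width_px: int = 88
    height_px: int = 220
    gel_top_row: int = 120
    gel_height_mm: float = 5.3
    mm_per_px: float = 0.0681
    water_rows: int = 104

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be > 0, got {self.mm_per_px}")
        if self.gel_top_row + self.gel_height_mm / self.mm_per_px > self.height_px:
            raise ValueError("gel column does not fit below gel_top_row")

    @property
    def gel_height_px(self) -> float:
        return self.gel_height_mm / self.mm_per_px

    @property
    def gel_bottom_row(self) -> int:
        return int(round(self.gel_top_row + self.gel_height_px))


@dataclass(frozen=True)
class RenderConfig:
    """Optical and noise parameters of the synthetic camera/light path.

    ``transition_width_mm`` is the visible width of the colour gradient; the
    logistic mixing scale is one sixth of it, so the acid fraction runs from
    ~5% to ~95% across one transition width.

    The default filter strength is matched to the indicator colours so that
    the row whose mixed colour sits at the saturation-space Otsu boundary is
    the 50/50-mix row; this keeps the rendered front and the detected front
    consistent to within pixel quantization.
    """

    transition_width_mm: float = 0.4
    noise_sd: float = 0.02
    illum_gradient: float = 0.05
    yellow_filter_strength: float = 0.76
    meniscus_drop_mm_per_h: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.yellow_filter_strength <= 1.0:
            raise ValueError("yellow_filter_strength must lie in [0, 1]")
        if self.transition_width_mm <= 0:
            raise ValueError("transition_width_mm must be > 0")


@dataclass
class FrameSeries:
    """Ordered, timestamped frames with synthetic ground truth.

    ``truth_depth_mm`` has shape (n_frames,) for a single vial or
    (n_frames, n_vials) for a composite; ``truth_flags`` marks frames whose
    true front was clamped at the gel bottom.
    """

    frames: list[np.ndarray]
    times_s: np.ndarray
    truth_depth_mm: np.ndarray
    truth_flags: np.ndarray  # "ok" | "clamped", same shape as truth_depth_mm

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (len(self.frames) == len(self.times_s) == len(self.truth_depth_mm)):
            raise ValueError("frames, times and truth must have equal length")


def apply_yellow_filter(image: np.ndarray, strength: float) -> np.ndarray:
    """Emulate the yellow filter foil: attenuate blue, keep red/green.

    Multiplies the blue channel by ``1 - strength``; strength 0 is the
    identity, strength 1 removes blue entirely.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    out = np.array(image, dtype=float, copy=True)
    out[..., 2] *= 1.0 - strength
    return out


def _scene(
    front_depth_mm: float,
    geometry: VialGeometry,
    indicator: IndicatorSpec,
    config: RenderConfig,
    meniscus_drop_mm: float,
) -> np.ndarray:
    """Noise- and filter-free scene colours (float RGB in [0,1])."""
    g = geometry
    img = np.tile(_BACKGROUND_COLOR, (g.height_px, g.width_px, 1))

    # Supernatant water band, its surface dropping with evaporation.
    drop_px = meniscus_drop_mm / g.mm_per_px
    water_top = int(round(g.gel_top_row - g.water_rows + drop_px))
    water_top = min(max(water_top, 0), g.gel_top_row)
    img[water_top : g.gel_top_row] = _WATER_COLOR

    rows = np.arange(g.gel_top_row, g.gel_bottom_row)
    depth_mm = (rows - g.gel_top_row) * g.mm_per_px
    acid = np.asarray(indicator.acid_color)
    base = np.asarray(indicator.base_color)
    if front_depth_mm <= 0.0:
        w = np.zeros_like(depth_mm)
    elif front_depth_mm >= g.gel_height_mm:
        w = np.ones_like(depth_mm)
    else:
        scale = config.transition_width_mm / 6.0
        w = 1.0 / (1.0 + np.exp((depth_mm - front_depth_mm) / scale))
    img[rows] = w[:, None, None] * acid + (1.0 - w[:, None, None]) * base
    return img


def render_frame(
    front_depth_mm: float,
    geometry: VialGeometry = VialGeometry(),
    indicator: IndicatorSpec = BROMOTHYMOL_BLUE,
    config: RenderConfig = RenderConfig(),
    *,
    meniscus_drop_mm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one vial frame at the given front depth.

    Gel rows mix the indicator's acid and base colours with a logistic
    weight in (row depth - front depth); the yellow filter, illumination
    gradient and Gaussian noise are applied afterwards, in that order.
    Depths outside [0, gel height] are clamped with a warning.
    """
    g = geometry
    if not 0.0 <= front_depth_mm <= g.gel_height_mm:
        warnings.warn(
            f"front depth {front_depth_mm:.3g} mm outside gel [0, "
            f"{g.gel_height_mm:.3g}] mm; clamped",
            stacklevel=2,
        )
        front_depth_mm = min(max(front_depth_mm, 0.0), g.gel_height_mm)

    img = _scene(front_depth_mm, g, indicator, config, meniscus_drop_mm)
    img = apply_yellow_filter(img, config.yellow_filter_strength)

    if config.illum_gradient:
        frac = np.arange(g.height_px) / max(g.height_px - 1, 1)
        img *= (1.0 + config.illum_gradient * (0.5 - frac))[:, None, None]

    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sd, img.shape)

    return np.clip(img, 0.0, 1.0)


def _truth(times_s: np.ndarray, d_pseudo: float, gel_height_mm: float):
    depth = front_position(np.asarray(times_s, dtype=float), d_pseudo) * 1e3
    flags = np.where(depth > gel_height_mm, "clamped", "ok")
    return np.minimum(depth, gel_height_mm), flags


def render_series(
    times_s: np.ndarray,
    d_pseudo: float,
    geometry: VialGeometry = VialGeometry(),
    indicator: IndicatorSpec = BROMOTHYMOL_BLUE,
    config: RenderConfig = RenderConfig(),
) -> FrameSeries:
    """Render a full time-lapse for one vial under the square-root law.

    Frame ``i`` is rendered at depth ``front_position(times[i], d_pseudo)``;
    the first frame (t = 0) is the pre-gassing reference.  Fronts that would
    exceed the gel height are clamped and flagged in the truth metadata.
    """
    times_s = np.asarray(times_s, dtype=float)
    if times_s[0] != 0:
        raise ValueError("first frame must be the t=0 pre-gassing reference")
    depths, flags = _truth(times_s, d_pseudo, geometry.gel_height_mm)
    return render_series_from_depths(times_s, depths, geometry, indicator, config, flags=flags)


def render_series_from_depths(
    times_s: np.ndarray,
    depths_mm: np.ndarray,
    geometry: VialGeometry = VialGeometry(),
    indicator: IndicatorSpec = BROMOTHYMOL_BLUE,
    config: RenderConfig = RenderConfig(),
    *,
    flags: np.ndarray | None = None,
) -> FrameSeries:
    """Render a time-lapse from an explicit per-frame front-depth trajectory.

    Used with :func:`idafront.chemistry.pde_front_depths` to build series
    whose fronts follow the diffusion/chemistry model rather than the exact
    square-root law.
    """
    times_s = np.asarray(times_s, dtype=float)
    depths_mm = np.asarray(depths_mm, dtype=float)
    if flags is None:
        flags = np.where(depths_mm > geometry.gel_height_mm, "clamped", "ok")
    depths_mm = np.minimum(depths_mm, geometry.gel_height_mm)
    rng = np.random.default_rng(config.seed)
    frames = []
    for t, d in zip(times_s, depths_mm):
        drop = config.meniscus_drop_mm_per_h * t / 3600.0
        frames.append(
            render_frame(float(d), geometry, indicator, config, meniscus_drop_mm=drop, rng=rng)
        )
    return FrameSeries(frames, times_s, depths_mm, np.asarray(flags))


def render_multivial(
    series_specs: list[tuple[float, VialGeometry]],
    times_s: np.ndarray = DEFAULT_TIMES_S,
    indicator: IndicatorSpec = BROMOTHYMOL_BLUE,
    config: RenderConfig = RenderConfig(),
    *,
    gap_px: int = 12,
):
    """Render up to ten vials side by side into composite frames.

    Each entry is ``(d_pseudo, geometry)``; every vial gets an independent
    noise stream derived from the config seed.  Returns the composite
    :class:`FrameSeries` (truth shape (n_frames, n_vials)) and the list of
    gel-column ROIs, as ``(col_start, col_end, row_start, row_end,
    gel_top_row)`` tuples ready for the detection module.
    """
    if not 1 <= len(series_specs) <= 10:
        raise ValueError("between 1 and 10 vials supported")
    times_s = np.asarray(times_s, dtype=float)

    singles = []
    for v, (d_pseudo, geom) in enumerate(series_specs):
        seed_v = int(np.random.SeedSequence([config.seed, v]).generate_state(1)[0] % 2**31)
        cfg_v = replace(config, seed=seed_v)
        singles.append(render_series(times_s, d_pseudo, geom, indicator, cfg_v))

    heights = [g.height_px for _, g in series_specs]
    widths = [g.width_px for _, g in series_specs]
    height = max(heights)
    total_w = sum(widths) + gap_px * (len(series_specs) + 1)

    rois = []
    col = gap_px
    for (d_pseudo, geom) in series_specs:
        rois.append(
            (col, col + geom.width_px, geom.gel_top_row, geom.gel_bottom_row, geom.gel_top_row)
        )
        col += geom.width_px + gap_px
    for a, b in zip(rois, rois[1:]):
        if a[1] > b[0]:
            raise ValueError("vial ROIs overlap")

    frames = []
    for i in range(len(times_s)):
        canvas = np.tile(_BACKGROUND_COLOR, (height, total_w, 1))
        canvas = apply_yellow_filter(canvas, config.yellow_filter_strength)
        if config.illum_gradient:
            frac = np.arange(height) / max(height - 1, 1)
            canvas *= (1.0 + config.illum_gradient * (0.5 - frac))[:, None, None]
        canvas = np.clip(canvas, 0.0, 1.0)
        for (c0, c1, *_), s, g in zip(rois, singles, (sp[1] for sp in series_specs)):
            canvas[: g.height_px, c0:c1] = s.frames[i]
        frames.append(canvas)

    truth = np.stack([s.truth_depth_mm for s in singles], axis=1)
    flags = np.stack([s.truth_flags for s in singles], axis=1)
    return FrameSeries(frames, times_s, truth, flags), rois
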