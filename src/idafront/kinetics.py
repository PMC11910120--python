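"""Interface kinetics: velocities, pseudo-diffusion coefficients, porosity.

From a per-vial interface track the method derives, at every usable
timepoint, the interface velocity ``Vi = |x0 - xt| / t`` and the pseudo
diffusion coefficient ``D_pseudo = (x0 - xt)^2 / (2 t)`` (a Stokes-Einstein
style effective coefficient; a comparative quantity, not an absolute
effective diffusivity).  Replicate vials are aggregated as mean over
timepoints within a vial, then mean +/- sample standard deviation over vials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import OK, InterfaceTrack

__all__ = [
    "DiffusionResult",
    "PorosityInput",
    "ReplicateSummary",
    "InsufficientDataError",
    "interface_velocity",
    "pseudo_diffusion",
    "porosity",
    "analyze_track",
    "summarize_replicates",
    "fold_ratio",
]


class InsufficientDataError(ValueError):
    """Fewer than two usable (ok, t > 0) points in a track."""


@dataclass(frozen=True)
class DiffusionResult:
    """Per-vial kinetic quantities.

    ``per_time`` rows are ``(t_s, displacement_m, vi_m_per_s, d_pseudo_m2_per_s)``
    for every usable point after t = 0; ``replicate_mean_d`` averages the
    per-time coefficients; ``fitted_d`` is the through-origin least-squares
    slope of displacement^2 = 2 D t.
    """

    vial_id: int
    per_time: list[tuple[float, float, float, float]]
    replicate_mean_d: float
    fitted_d: float


@dataclass(frozen=True)
class PorosityInput:
    """Wet and dry gel weights (g) for the gravimetric porosity estimate."""

    wet_weight: float
    dry_weight: float

    def __post_init__(self) -> None:
        if not 0 < self.dry_weight <= self.wet_weight:
            raise ValueError("need 0 < dry_weight <= wet_weight")


@dataclass(frozen=True)
class ReplicateSummary:
    hydrogel_label: str
    n: int
    mean_d: float
    sd_d: float


def interface_velocity(x0: float, xt: float, t: float) -> float:
    """Interface velocity |x0 - xt| / t in m/s (downward displacement positive)."""
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    return abs(x0 - xt) / t


def pseudo_diffusion(x0: float, xt: float, t: float) -> float:
    """Pseudo diffusion coefficient (x0 - xt)^2 / (2 t) in m^2/s."""
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    return (x0 - xt) ** 2 / (2.0 * t)


def porosity(inp: PorosityInput) -> float:
    """Gravimetric porosity (wet - dry) / wet, in [0, 1)."""
    return (inp.wet_weight - inp.dry_weight) / inp.wet_weight


def analyze_track(track: InterfaceTrack) -> DiffusionResult:
    """Per-time and aggregate kinetics for one vial.

    Uses every point flagged ok with t > 0 (t = 0 is the reference and is
    excluded; flagged points — no_interface, clamped — are dropped).
    """
    usable = [
        (t, d_mm * 1e-3)
        for t, d_mm, fl in zip(track.times_s, track.position_mm, track.flags)
        if fl == OK and t > 0 and np.isfinite(d_mm)
    ]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"vial {track.vial_id}: {len(usable)} usable points; flags={track.flags}"
        )

    per_time = [
        (t, d, interface_velocity(0.0, d, t), pseudo_diffusion(0.0, d, t))
        for t, d in usable
    ]
    d_values = np.array([row[3] for row in per_time])

    t_arr = np.array([row[0] for row in per_time])
    d2 = np.array([row[1] for row in per_time]) ** 2
    fitted = float(np.sum(t_arr * d2) / (2.0 * np.sum(t_arr**2)))

    return DiffusionResult(
        vial_id=track.vial_id,
        per_time=per_time,
        replicate_mean_d=float(d_values.mean()),
        fitted_d=fitted,
    )


def summarize_replicates(
    results: list[DiffusionResult], label: str = ""
) -> ReplicateSummary:
    """Mean +/- sample sd (n-1) of the per-vial mean coefficients."""
    if not results:
        raise ValueError("no replicate results to summarize")
    d = np.array([r.replicate_mean_d for r in results])
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return ReplicateSummary(hydrogel_label=label, n=len(d), mean_d=float(d.mean()), sd_d=sd)


def fold_ratio(a: ReplicateSummary, b: ReplicateSummary) -> float:
    """Ratio of mean pseudo-diffusion coefficients, a over b."""
    if b.mean_d <= 0:
        raise ValueError("denominator summary has non-positive mean")
    return a.mean_d / b.mean_d
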