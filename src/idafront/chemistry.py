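"""Carbonate equilibrium chemistry and 1-D diffusion forward models.

Dissolved CO2 entering an indicator-doped hydrogel hydrates to carbonic acid
and dissociates, releasing protons that flip the indicator from its basic to
its acidic colour.  This module models that speciation (charge balance on H+),
the indicator protonation fraction (Henderson-Hasselbalch), and two forward
models for front motion: the closed-form square-root law implied by the
pseudo-diffusion definition D_pseudo = d^2 / (2 t), and a semi-infinite
diffusion model (erfc closed form plus an explicit finite-difference solver)
coupled to the chemistry, used to generate physically grounded benchmark
fronts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc

__all__ = [
    "EquilibriumSystem",
    "IndicatorSpec",
    "SpeciationState",
    "DiffusionField",
    "BROMOTHYMOL_BLUE",
    "SolverError",
    "StabilityError",
    "speciate",
    "fraction_protonated",
    "front_position",
    "concentration_profile",
    "diffuse_1d",
    "indicator_front_depth",
    "pde_front_depths",
]


class SolverError(RuntimeError):
    """Root search for the charge balance failed to converge."""


class StabilityError(ValueError):
    """Explicit time step violates the FTCS stability bound."""


@dataclass(frozen=True)
class EquilibriumSystem:
    """Equilibrium constants of the aqueous CO2 system.

    The second dissociation (bicarbonate -> carbonate) has a much smaller
    constant than the first and is off by default; switching it on adds the
    carbonate term to the charge balance.

    An optional immobile weak-base buffer (e.g. the TRIS used to activate the
    gel at pH 8) and a fixed background charge extend the charge balance so
    the pre-gassing gel can sit above pH 7; with the defaults (no buffer, no
    background charge) the system is plain CO2-in-water.

    Parameters
    ----------
    ka1, ka2 : float
        First and second dissociation constants, mol/L.
    kw : float
        Water autoionization constant, mol^2/L^2.
    use_second_dissociation : bool
        Include the carbonate term in the charge balance.
    buffer_total, buffer_pka : float
        Total concentration (mol/L) and pKa of an immobile weak base B whose
        protonated form BH+ enters the charge balance.
    background_charge : float
        Net fixed ionic background (cationic positive), mol/L.
    """

    ka1: float = 4.45e-7
    ka2: float = 4.69e-11
    kw: float = 1.0e-14
    use_second_dissociation: bool = False
    buffer_total: float = 0.0
    buffer_pka: float = 8.07
    background_charge: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ka1", "ka2", "kw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.buffer_total < 0:
            raise ValueError("buffer_total must be >= 0")

    @classmethod
    def buffered(
        cls,
        ph0: float = 8.0,
        buffer_total: float = 0.024,
        buffer_pka: float = 8.07,
        **kwargs,
    ) -> "EquilibriumSystem":
        """System whose CO2-free equilibrium sits at ``ph0``.

        The background charge is solved from the CO2-free charge balance, so
        it represents the counter-ions introduced when the gel's pH was
        adjusted.  Defaults model a gel activated with ~24 mM TRIS.
        """
        sys0 = cls(buffer_total=buffer_total, buffer_pka=buffer_pka, **kwargs)
        h0 = 10.0**-ph0
        bh = buffer_total * h0 / (h0 + 10.0**-buffer_pka)
        z = sys0.kw / h0 - h0 - bh
        return cls(
            buffer_total=buffer_total,
            buffer_pka=buffer_pka,
            background_charge=z,
            **kwargs,
        )


@dataclass(frozen=True)
class IndicatorSpec:
    """A pH indicator: protonation constant and the two limiting colours."""

    name: str
    pka: float
    acid_color: tuple[float, float, float]
    base_color: tuple[float, float, float]
    ideal_ph_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 < self.pka < 14:
            raise ValueError(f"pKa must lie in (0, 14), got {self.pka}")
        for c in (*self.acid_color, *self.base_color):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colour channels must lie in [0, 1]")
        lo, hi = self.ideal_ph_range
        if not lo < hi:
            raise ValueError("ideal_ph_range must satisfy low < high")


#: Bromothymol blue: yellow below ~pH 6, blue above ~pH 7.6.  The colours are
#: nominal sRGB values for the backlit vials, not spectrophotometric data.
BROMOTHYMOL_BLUE = IndicatorSpec(
    name="bromothymol blue",
    pka=7.10,
    acid_color=(0.92, 0.85, 0.15),
    base_color=(0.10, 0.35, 0.70),
    ideal_ph_range=(6.0, 7.6),
)


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium composition at a given dissolved-CO2 level (mol/L)."""

    co2_aq: float
    h_plus: float
    hco3: float
    co3: float
    ph: float


@dataclass(frozen=True)
class DiffusionField:
    """Configuration of the 1-D semi-infinite diffusion problem.

    ``c0`` is held fixed at the top boundary (gas-saturated water layer);
    the bottom boundary is zero-flux (vial bottom).
    """

    d: float = 1.9e-9
    c0: float = 0.033
    length: float = 6.0e-3
    n_nodes: int = 121
    dt: float = 0.5

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"diffusion coefficient must be > 0, got {self.d}")
        if self.c0 < 0:
            raise ValueError(f"boundary concentration must be >= 0, got {self.c0}")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 grid nodes")

    @property
    def dx(self) -> float:
        return self.length / (self.n_nodes - 1)

    @property
    def max_stable_dt(self) -> float:
        return self.dx**2 / (2.0 * self.d)


def speciate(co2_aq: float, sys: EquilibriumSystem = EquilibriumSystem()) -> SpeciationState:
    """Solve the proton charge balance for a given dissolved CO2 level.

    The balance ``h = hco3 + 2*co3 + kw/h`` (carbonate term only when the
    second dissociation is enabled) has a unique positive root because the
    right-hand side is strictly decreasing in ``h``.  Solved by a bracketed
    root search on [1e-14, 1] mol/L.

    Raises
    ------
    ValueError
        If ``co2_aq`` is negative.
    SolverError
        If the root search does not converge (the residual is reported).
    """
    if co2_aq < 0:
        raise ValueError(f"co2_aq must be >= 0, got {co2_aq}")

    ka1, ka2, kw = sys.ka1, sys.ka2, sys.kw
    use2 = sys.use_second_dissociation
    ka_buf = 10.0**-sys.buffer_pka

    def balance(h: float) -> float:
        cations = h + sys.background_charge
        if sys.buffer_total:
            cations += sys.buffer_total * h / (h + ka_buf)
        anions = ka1 * co2_aq / h + kw / h
        if use2:
            anions += 2.0 * ka2 * ka1 * co2_aq / h**2
        return cations - anions

    lo, hi = 1e-14, 1.0
    try:
        h = brentq(balance, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise SolverError(f"charge balance root search failed: {exc}") from exc

    scale = h + kw / h + ka1 * co2_aq / h + sys.buffer_total + abs(sys.background_charge)
    residual = balance(h)
    if abs(residual) > 1e-9 * scale:
        raise SolverError(
            f"charge balance did not converge: residual {residual:.3e} at h={h:.3e}"
        )

    hco3 = ka1 * co2_aq / h
    co3 = ka2 * hco3 / h if use2 else 0.0
    return SpeciationState(
        co2_aq=co2_aq, h_plus=h, hco3=hco3, co3=co3, ph=-math.log10(h)
    )


def fraction_protonated(ph: float | np.ndarray, indicator: IndicatorSpec) -> float | np.ndarray:
    """Fraction of indicator in the (acid-coloured) protonated form.

    Henderson-Hasselbalch: ``1 / (1 + 10**(pH - pKa))``; strictly decreasing
    in pH, 0.5 at pH = pKa.
    """
    ph = np.asarray(ph, dtype=float)
    if np.any(ph < 0) or np.any(ph > 14):
        raise ValueError("pH must lie in [0, 14]")
    frac = 1.0 / (1.0 + 10.0 ** (ph - indicator.pka))
    return float(frac) if frac.ndim == 0 else frac


def front_position(t: float | np.ndarray, d_pseudo: float) -> float | np.ndarray:
    """Front depth (m) after time ``t`` (s) under the square-root law.

    Inverse of the pseudo-diffusion definition: ``depth = sqrt(2 * D * t)``.
    """
    if d_pseudo <= 0:
        raise ValueError(f"d_pseudo must be > 0, got {d_pseudo}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    depth = np.sqrt(2.0 * d_pseudo * t)
    return float(depth) if depth.ndim == 0 else depth


def concentration_profile(
    x: float | np.ndarray, t: float, fld: DiffusionField
) -> float | np.ndarray:
    """Semi-infinite constant-boundary solution ``c0 * erfc(x / (2 sqrt(D t)))``."""
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    c = fld.c0 * erfc(x / (2.0 * math.sqrt(fld.d * t)))
    return float(c) if c.ndim == 0 else c


def diffuse_1d(fld: DiffusionField, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the 1-D diffusion equation to ``t_end`` with explicit FTCS.

    Top node held at ``c0`` (Dirichlet), bottom node zero-flux (mirror).
    Returns ``(x, c)`` grids.  The time step must satisfy the explicit
    stability bound ``dt <= dx^2 / (2 D)``.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if fld.dt > fld.max_stable_dt:
        raise StabilityError(
            f"dt={fld.dt:.4g} s violates the explicit stability bound; "
            f"maximal admissible dt is {fld.max_stable_dt:.4g} s"
        )

    n_steps = int(round(t_end / fld.dt))
    if abs(n_steps * fld.dt - t_end) > 1e-9 * t_end:
        n_steps = math.ceil(t_end / fld.dt)

    x = np.linspace(0.0, fld.length, fld.n_nodes)
    c = np.zeros(fld.n_nodes)
    c[0] = fld.c0
    r = fld.d * fld.dt / fld.dx**2
    for _ in range(n_steps):
        lap = np.empty_like(c)
        lap[1:-1] = c[:-2] - 2.0 * c[1:-1] + c[2:]
        lap[-1] = 2.0 * (c[-2] - c[-1])  # zero-flux mirror
        lap[0] = 0.0
        c = c + r * lap
        c[0] = fld.c0
    return x, c


def indicator_front_depth(
    x: np.ndarray,
    c: np.ndarray,
    sys: EquilibriumSystem,
    indicator: IndicatorSpec,
) -> float:
    """Depth (m) at which the indicator is half protonated, i.e. pH = pKa.

    The pH profile follows from speciating the local dissolved-CO2 level at
    every node; the pKa crossing is linearly interpolated.  Returns ``nan``
    when the whole column is on one side of the crossing.
    """
    ph = np.array([speciate(max(ci, 0.0), sys).ph for ci in c])
    below = ph < indicator.pka  # acidified region (top)
    if not below.any() or below.all():
        return math.nan
    i = int(np.nonzero(~below)[0][0])  # first node back above pKa
    if i == 0:
        return math.nan
    ph0, ph1 = ph[i - 1], ph[i]
    w = (indicator.pka - ph0) / (ph1 - ph0)
    return float(x[i - 1] + w * (x[i] - x[i - 1]))


def pde_front_depths(
    times_s: np.ndarray,
    fld: DiffusionField,
    sys: EquilibriumSystem | None = None,
    indicator: IndicatorSpec = BROMOTHYMOL_BLUE,
) -> np.ndarray:
    """Indicator front depth (m) at each requested time, from the PDE solver.

    The default chemistry is the pH-8 buffered gel; plain CO2-in-water never
    rises above pH 7 and would show no bromothymol-blue front at all.
    A time of 0 yields depth 0; times must be non-decreasing.
    """
    if sys is None:
        sys = EquilibriumSystem.buffered()
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) < 0):
        raise ValueError("times_s must be non-decreasing")
    depths = np.empty_like(times_s)
    for k, t in enumerate(times_s):
        if t == 0:
            depths[k] = 0.0
            continue
        _, c = diffuse_1d(fld, float(t))
        depths[k] = indicator_front_depth(np.linspace(0, fld.length, fld.n_nodes), c, sys, indicator)
    return depths
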