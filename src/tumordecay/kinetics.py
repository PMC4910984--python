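"""Fractional-cell-kill kinetics of immune-mediated tumor lysis.

The central object is the saturating kill law

    K(E, T) = d * E**lambda / (s * T**nu + E**lambda)

a Hill-type function of both the effector (immune) population ``E`` and the
tumor population ``T``, with both exponents at most one.  The tumor decays as

    dT/dt = -K(E, T) * T**nu

which interpolates between three geometric regimes for a fixed effector
count ``E0``:

* ``E0**lambda << s*T**nu`` — *linear* decay at constant speed
  ``d*E0**lambda/s`` (a thin rim of effectors eating a huge tumor);
* ``E0**lambda >> s*T**nu`` with ``nu < 1`` — *power-law* decay
  ``dT/dt = -d*T**nu`` (surface erosion; ``nu = 1/2`` for a 2-D tumor,
  ``nu = 2/3`` for a 3-D ball);
* ``nu = 1`` in the same limit — *exponential* decay ``dT/dt = -d*T``
  (well-mixed effectors, e.g. infiltrated or haematological tumors).

``d`` is the maximal fractional kill rate (units cell**(1-nu)/hr), ``lambda``
and ``nu`` encode tumor geometry/dimension, and ``s`` scales immune
effectiveness (larger ``s`` = less effective effectors).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .series import LysisSeries

__all__ = [
    "KillParams",
    "PopulationState",
    "fractional_cell_kill",
    "decay_rhs",
    "linear_limit_rate",
    "integrate_decay",
    "closed_form_power_decay",
    "exponential_decay",
    "effectiveness_rescale",
]


@dataclass(frozen=True)
class KillParams:
    """Parameters (d, lambda, s, nu) of the generalized kill law.

    ``d > 0`` maximal fractional kill rate; ``0 < lambda_ <= 1`` effector
    geometry exponent; ``s > 0`` immune-effectiveness scale (larger = less
    effective); ``0 < nu <= 1`` tumor exponent (1/2 for 2-D surface erosion,
    2/3 for 3-D, 1 for well-mixed populations).
    """

    d: float
    lambda_: float
    s: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"d must be > 0, got {self.d}")
        if not 0 < self.lambda_ <= 1:
            raise ValueError(f"lambda_ must be in (0, 1], got {self.lambda_}")
        if not self.s > 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")

    @classmethod
    def from_dict(cls, mapping: dict) -> "KillParams":
        """Build from a flat mapping with keys d, lambda (or lambda_), s, nu."""
        m = dict(mapping)
        if "lambda" in m:
            m["lambda_"] = m.pop("lambda")
        return cls(**m)

    @classmethod
    def from_yaml(cls, path) -> "KillParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {"d": self.d, "lambda": self.lambda_, "s": self.s, "nu": self.nu}


@dataclass(frozen=True)
class PopulationState:
    """Tumor and effector cell counts (real-valued, non-negative)."""

    T: float
    E: float

    def __post_init__(self) -> None:
        if self.T < 0 or self.E < 0:
            raise ValueError(f"populations must be non-negative, got T={self.T}, E={self.E}")


def fractional_cell_kill(params: KillParams, state: PopulationState) -> float:
    """Evaluate K(E, T) = d E^lambda / (s T^nu + E^lambda).

    Defined as 0 when E = 0 (no effectors, no kill; this also covers the
    removable singularity at E = T = 0).  Bounded by ``d``, increasing in E
    and decreasing in T.
    """
    if state.E == 0:
        return 0.0
    e_lam = state.E**params.lambda_
    return params.d * e_lam / (params.s * state.T**params.nu + e_lam)


def decay_rhs(params: KillParams, state: PopulationState) -> float:
    """Tumor decay rate dT/dt = -K(E, T) * T^nu (cells/hr, always <= 0)."""
    if state.T == 0 or state.E == 0:
        return 0.0
    e_lam = state.E**params.lambda_
    t_nu = state.T**params.nu
    return -params.d * e_lam * t_nu / (params.s * t_nu + e_lam)


def linear_limit_rate(params: KillParams, E0: float) -> float:
    """Constant decay speed d E0^lambda / s of the big-tumor limit.

    This is the limit of |dT/dt| as T -> infinity at fixed E0, for any nu:
    a fixed rim of effectors lyses at a size-independent speed (one effector
    with d = lambda = s = 1 lyses one tumor cell per hour).
    """
    if E0 < 0:
        raise ValueError("E0 must be non-negative")
    if E0 == 0:
        return 0.0
    return params.d * E0**params.lambda_ / params.s


def closed_form_power_decay(d: float, nu: float, T0: float, t) -> np.ndarray | float:
    """Solution of dT/dt = -d T^nu for 0 < nu < 1, clamped at extinction.

    T(t) = (T0^(1-nu) - d (1-nu) t)^(1/(1-nu)) while positive, 0 afterwards;
    the tumor vanishes exactly at t* = T0^(1-nu) / (d (1-nu)).  For nu = 1
    use :func:`exponential_decay` instead (different functional form).
    """
    if not 0 < nu < 1:
        raise ValueError("closed_form_power_decay requires 0 < nu < 1")
    if d <= 0:
        raise ValueError("d must be > 0")
    if T0 < 0:
        raise ValueError("T0 must be non-negative")
    t = np.asarray(t, dtype=float)
    core = np.maximum(T0 ** (1.0 - nu) - d * (1.0 - nu) * t, 0.0)
    out = core ** (1.0 / (1.0 - nu))
    return out if out.ndim else float(out)


def exponential_decay(d: float, T0: float, t) -> np.ndarray | float:
    """Solution T0 e^{-dt} of dT/dt = -dT (the nu = 1 / well-mixed limit)."""
    if d <= 0:
        raise ValueError("d must be > 0")
    t = np.asarray(t, dtype=float)
    out = T0 * np.exp(-d * t)
    return out if out.ndim else float(out)


def power_extinction_time(d: float, nu: float, T0: float) -> float:
    """Finite extinction time T0^(1-nu) / (d (1-nu)) of the nu < 1 decay."""
    if not 0 < nu < 1:
        raise ValueError("extinction time is finite only for 0 < nu < 1")
    return T0 ** (1.0 - nu) / (d * (1.0 - nu))


def integrate_decay(
    params: KillParams,
    T0: float,
    E0: float,
    t_grid,
    rtol: float = 1e-10,
    atol: float = 1e-9,
) -> LysisSeries:
    """Numerically integrate dT/dt = -d E0^l T^nu / (s T^nu + E0^l).

    The effector count is held fixed at ``E0`` (the lysis experiments start
    from a prepared immune configuration and track only the tumor).  The
    trajectory is clamped at zero after extinction — for ``nu < 1`` the ODE
    reaches T = 0 in finite time and the integrator must not step into
    negative populations.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if T0 <= 0:
        raise ValueError("T0 must be > 0")
    if E0 < 0:
        raise ValueError("E0 must be non-negative")
    if t_grid.ndim != 1 or t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing from 0")

    if E0 == 0:
        return LysisSeries(t_grid, np.full_like(t_grid, float(T0)))

    e_lam = E0**params.lambda_

    def rhs(t, y):
        T = max(y[0], 0.0)
        t_nu = T**params.nu
        return (-params.d * e_lam * t_nu / (params.s * t_nu + e_lam),)

    def extinct(t, y):
        return y[0]

    extinct.terminal = True
    extinct.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [float(T0)],
        t_eval=t_grid,
        events=extinct,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"decay integration failed: {sol.message}")
    T = np.zeros_like(t_grid)
    T[: len(sol.t)] = np.maximum(sol.y[0], 0.0)
    # times past the terminal (extinction) event stay clamped at zero
    series = LysisSeries(t_grid, np.minimum.accumulate(T))
    series.meta.update({"params": params.to_dict(), "T0": T0, "E0": E0})
    return series


def effectiveness_rescale(params: KillParams, f: float) -> KillParams:
    """Absorb an effective fraction f of the effectors into s.

    When only a fraction ``f`` of the effector population actually engages
    the tumor, replacing E by f*E in the kill law is equivalent to keeping E
    and redefining ``s -> s / f**lambda``: a large ineffective population
    equals a small effective one.
    """
    if not 0 < f <= 1:
        raise ValueError(f"f must be in (0, 1], got {f}")
    return replace(params, s=params.s / f**params.lambda_)


def _saturation_gap(params: KillParams, T: float, E: float) -> float:
    """d - K(E, T); positive for finite E when T > 0 (used in tests)."""
    return params.d - fractional_cell_kill(params, PopulationState(T=T, E=E))
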