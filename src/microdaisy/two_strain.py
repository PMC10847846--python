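"""Two-strain pH-regulating consortium: dynamics, steady states, scans, range.

Two engineered strains share a growth niche but push the free pH of the
chemostat in opposite directions.  Their abundances follow replicator-like
logistic competition,

    dX_s/dt = X_s * (phi(X) * beta_s - delta),      phi(X) = 1 - X_up - X_down

where each strain's growth response ``beta_s`` is evaluated at its *perceived*
pH (free pH shifted by its own product cloud), and the free pH itself is the
algebraic quasi-steady-state relation

    pH_f = pH_in + X_up * (gamma_up / delta) + X_down * (gamma_down / delta).

Because the two pushes oppose each other, the population balance shifts with
the external input ``pH_in`` so that ``pH_f`` is held near the shared optimum
over a wide input interval — the homeostatic range — until the input is so
extreme that both strains collapse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._steady import EXTINCTION_SNAP, batch_steady_state
from .core import (
    GrowthNiche,
    StrainSpec,
    external_level,
    free_pH_qss,
    growth_rate,
    perceived_pH,
)
from .trajectory import Trajectory

__all__ = [
    "TwoStrainParams",
    "SystemState",
    "SteadyStateResult",
    "HomeostaticRange",
    "symmetric_consortium",
    "free_ph",
    "rhs_two",
    "integrate",
    "steady_state",
    "scan_surface",
    "homeostatic_range",
    "DEFAULT_PH_IN_GRID",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_X0",
]

#: default scan grids: pH_in in [0, 16] step 0.1, gamma in [0, 0.05] step 0.002
DEFAULT_PH_IN_GRID = np.round(np.arange(0.0, 16.0 + 1e-9, 0.1), 10)
DEFAULT_GAMMA_GRID = np.round(np.arange(0.0, 0.05 + 1e-12, 0.002), 12)
#: default initial abundance per strain in every scan cell
DEFAULT_X0 = 0.01


@dataclass(frozen=True)
class TwoStrainParams:
    """Parameters of the two-strain consortium.

    ``strain_up`` must push the free pH up (``gamma > 0``) and ``strain_down``
    down (``gamma < 0``).  ``delta`` is the chemostat dilution rate and
    ``pH_in`` the external input pH.
    """

    strain_up: StrainSpec
    strain_down: StrainSpec
    delta: float
    pH_in: float

    def __post_init__(self) -> None:
        if not (self.strain_up.gamma > 0 > self.strain_down.gamma):
            raise ValueError(
                "strain_up must have gamma > 0 and strain_down gamma < 0; got "
                f"{self.strain_up.gamma!r} and {self.strain_down.gamma!r}"
            )
        if not (math.isfinite(self.delta) and self.delta > 0):
            raise ValueError(f"delta must be finite and > 0, got {self.delta!r}")

    @property
    def strains(self) -> tuple[StrainSpec, StrainSpec]:
        return (self.strain_up, self.strain_down)


@dataclass
class SystemState:
    """Abundances plus current free pH (algebraic for the 2/3-species models)."""

    abundances: np.ndarray
    pH_f: float

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if (self.abundances < 0).any():
            raise ValueError(f"abundances must be >= 0, got {self.abundances!r}")


@dataclass
class SteadyStateResult:
    """Outcome of relaxation to stationarity; non-convergence is reported, not raised."""

    state: SystemState
    converged: bool
    residual: float
    iterations: int


@dataclass(frozen=True)
class HomeostaticRange:
    """Maximal contiguous pH_in interval of regulated, populated steady states."""

    pH_in_low: float
    pH_in_high: float
    criteria: dict

    @property
    def width(self) -> float:
        return self.pH_in_high - self.pH_in_low

    def to_dict(self) -> dict:
        return {
            "pH_in_low": self.pH_in_low,
            "pH_in_high": self.pH_in_high,
            "criteria": dict(self.criteria),
        }


def symmetric_consortium(
    gamma: float = 0.04,
    pH_in: float = 7.0,
    *,
    delta: float = 0.01,
    omega: float = 0.5,
    pH_opt: float = 7.0,
    delta_H: float = 9.0,
) -> TwoStrainParams:
    """The reference experiment: shared niche, equal and opposite push rates.

    Defaults are the baseline two-strain configuration (delta = 0.01,
    omega = 0.5, pH_opt = 7, half-width 9, |gamma| = 0.04).
    """
    niche = GrowthNiche(pH_opt=pH_opt, delta_H=delta_H)
    return TwoStrainParams(
        strain_up=StrainSpec(niche=niche, gamma=+gamma, omega=omega, label="up-pusher"),
        strain_down=StrainSpec(niche=niche, gamma=-gamma, omega=omega, label="down-pusher"),
        delta=delta,
        pH_in=pH_in,
    )


def free_ph(abundances, params: TwoStrainParams) -> float:
    """Quasi-steady-state free pH for given abundances ``(X_up, X_down)``."""
    x = np.asarray(abundances, dtype=float)
    return free_pH_qss(
        params.pH_in,
        [(x[i], external_level(s, params.delta)) for i, s in enumerate(params.strains)],
    )


def rhs_two(state: SystemState, params: TwoStrainParams) -> np.ndarray:
    """Abundance derivatives; the free pH is recomputed algebraically first."""
    x = state.abundances
    pH_f = free_ph(x, params)
    phi = 1.0 - x.sum()
    dx = np.empty(2)
    for i, s in enumerate(params.strains):
        beta = growth_rate(s.niche, perceived_pH(pH_f, s, params.delta))
        dx[i] = x[i] * (phi * beta - params.delta)
    return dx


def integrate(
    rhs,
    initial,
    dt: float,
    t_end: float,
    method: str = "euler",
    *,
    free_ph_fn=None,
    record_every: int = 1,
    meta: dict | None = None,
) -> Trajectory:
    """Fixed-step integration of an abundance ODE with algebraic free pH.

    Parameters
    ----------
    rhs :
        Callable ``f(x) -> dx`` on the abundance vector.
    initial :
        Abundance vector or :class:`SystemState`.
    method :
        ``"euler"`` (default for the 2–3 species models) or ``"rk4"``
        (used for the multispecies model).
    free_ph_fn :
        Optional callable ``x -> pH_f`` recorded at every stored point;
        ``pH_f`` is NaN when omitted.

    Abundances are floored at zero after every step and sub-extinction values
    are snapped to zero (extinction is absorbing: there is no immigration in
    these models).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    if method not in ("euler", "rk4"):
        raise ValueError(f"method must be 'euler' or 'rk4', got {method!r}")
    x = np.array(
        initial.abundances if isinstance(initial, SystemState) else initial,
        dtype=float,
    )
    n_steps = int(round(t_end / dt))
    rec_idx = list(range(0, n_steps + 1, record_every))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    rec = np.zeros((len(rec_idx), x.size))
    rec_t = np.asarray(rec_idx, dtype=float) * dt
    pos = 0

    for k in range(n_steps + 1):
        if k == rec_idx[pos]:
            rec[pos] = x
            pos += 1
        if k == n_steps:
            break
        if method == "euler":
            x = x + dt * rhs(x)
        else:
            k1 = rhs(x)
            k2 = rhs(x + 0.5 * dt * k1)
            k3 = rhs(x + 0.5 * dt * k2)
            k4 = rhs(x + dt * k3)
            x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.maximum(x, 0.0, out=x)
        x[x < EXTINCTION_SNAP] = 0.0
        if not np.isfinite(x).all():
            raise FloatingPointError(
                f"non-finite state at t={k * dt:.6g} (dt={dt}, method={method}): {x!r}"
            )

    pH = (
        np.array([free_ph_fn(row) for row in rec])
        if free_ph_fn is not None
        else np.full(len(rec_idx), np.nan)
    )
    info = {"dt": dt, "t_end": t_end, "method": method, "integrator": "fixed-step"}
    if meta:
        info.update(meta)
    return Trajectory(t=rec_t, abundances=rec, pH_f=pH, meta=info)


def _cell_arrays(params: TwoStrainParams):
    """Per-species (levels, shifts, pH_opt, delta_H) rows for the batch engine."""
    lev = [external_level(s, params.delta) for s in params.strains]
    shf = [s.omega * s.gamma / params.delta for s in params.strains]
    opt = [s.niche.pH_opt for s in params.strains]
    dH = [s.niche.delta_H for s in params.strains]
    return lev, shf, opt, dH


def steady_state(
    params: TwoStrainParams,
    initial=None,
    tol: float = 1e-9,
    t_max: float = 1e5,
    *,
    dt: float = 0.01,
) -> SteadyStateResult:
    """Relax the consortium to stationarity (``max |dX/dt| < tol``) or ``t_max``."""
    x0 = np.full(2, DEFAULT_X0) if initial is None else np.array(
        initial.abundances if isinstance(initial, SystemState) else initial, dtype=float
    )
    lev, shf, opt, dH = _cell_arrays(params)
    out = batch_steady_state(
        pH_in=np.array([params.pH_in]),
        levels=np.array([lev]),
        shifts=np.array([shf]),
        pH_opt=np.array([opt]),
        delta_H=np.array([dH]),
        alpha=np.ones((1, 2)),
        delta=params.delta,
        x0=x0[None, :],
        dt=dt,
        tol=tol,
        t_max=t_max,
    )
    return SteadyStateResult(
        state=SystemState(abundances=out["X"][0], pH_f=float(out["pH_f"][0])),
        converged=bool(out["converged"][0]),
        residual=float(out["residual"][0]),
        iterations=int(out["steps"][0]),
    )


def scan_surface(
    params: TwoStrainParams,
    pH_in_grid=None,
    gamma_grid=None,
    *,
    x0: float = DEFAULT_X0,
    dt: float = 0.01,
    tol: float = 1e-9,
    t_max: float = 1e5,
) -> pd.DataFrame:
    """Steady-state surface over a (gamma, pH_in) grid.

    Every cell is solved independently from the fixed initial condition
    ``X_up = X_down = x0`` (no continuation between cells, so hysteresis cannot
    leak across the scan).  ``params`` supplies the niche, ``omega`` and
    ``delta``; its ``gamma`` and ``pH_in`` are overridden by the grids.

    Returns a rectangular table, gamma-major then pH_in, with columns
    ``pH_in, gamma, pH_f, X_a, X_b, converged``; ``X_a`` is the up-pusher.
    The ``gamma = 0`` rows satisfy ``pH_f = pH_in`` exactly.
    """
    pH_in_grid = np.asarray(DEFAULT_PH_IN_GRID if pH_in_grid is None else pH_in_grid, float)
    gamma_grid = np.asarray(DEFAULT_GAMMA_GRID if gamma_grid is None else gamma_grid, float)
    if not (np.isfinite(pH_in_grid).all() and np.isfinite(gamma_grid).all()):
        raise ValueError("scan grids must be finite")

    G, P = np.meshgrid(gamma_grid, pH_in_grid, indexing="ij")
    g = G.ravel()
    pin = P.ravel()
    B = g.size
    omega = params.strain_up.omega
    opt_u, opt_d = (s.niche.pH_opt for s in params.strains)
    dH_u, dH_d = (s.niche.delta_H for s in params.strains)

    out = batch_steady_state(
        pH_in=pin,
        levels=np.column_stack([g / params.delta, -g / params.delta]),
        shifts=np.column_stack([omega * g / params.delta, -omega * g / params.delta]),
        pH_opt=np.column_stack([np.full(B, opt_u), np.full(B, opt_d)]),
        delta_H=np.column_stack([np.full(B, dH_u), np.full(B, dH_d)]),
        alpha=np.ones((B, 2)),
        delta=params.delta,
        x0=np.full((B, 2), x0),
        dt=dt,
        tol=tol,
        t_max=t_max,
    )
    return pd.DataFrame(
        {
            "pH_in": pin,
            "gamma": g,
            "pH_f": out["pH_f"],
            "X_a": out["X"][:, 0],
            "X_b": out["X"][:, 1],
            "converged": out["converged"],
        }
    )


def homeostatic_range(
    slice_table: pd.DataFrame,
    pop_floor: float = 0.05,
    pH_tolerance: float = 2.0,
    pH_opt: float = 7.0,
) -> HomeostaticRange | None:
    """Maximal contiguous pH_in interval around the optimum that stays regulated.

    A grid point qualifies when total steady abundance (all ``X_*`` columns)
    exceeds ``pop_floor`` and ``|pH_f - pH_opt| <= pH_tolerance``.  The
    returned interval is the maximal qualifying run containing the grid point
    nearest ``pH_opt``; ``None`` when that point does not qualify or the slice
    does not reach ``pH_opt``.
    """
    df = slice_table.sort_values("pH_in").reset_index(drop=True)
    pin = df["pH_in"].to_numpy()
    x_cols = [c for c in df.columns if c.startswith("X_")]
    total = df[x_cols].to_numpy().sum(axis=1)
    ok = (total > pop_floor) & (np.abs(df["pH_f"].to_numpy() - pH_opt) <= pH_tolerance)

    step = np.diff(pin).max() if pin.size > 1 else np.inf
    anchor = int(np.argmin(np.abs(pin - pH_opt)))
    criteria = {"pop_floor": pop_floor, "pH_tolerance": pH_tolerance, "pH_opt": pH_opt}
    if abs(pin[anchor] - pH_opt) > step:
        warnings.warn(
            f"slice does not contain a grid point near pH_opt={pH_opt}; empty range",
            stacklevel=2,
        )
        return None
    if not ok[anchor]:
        return None
    lo = anchor
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = anchor
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return HomeostaticRange(pH_in_low=float(pin[lo]), pH_in_high=float(pin[hi]), criteria=criteria)
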