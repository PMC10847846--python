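"""Three-species model: the regulating pair plus a non-regulating parasite.

The parasite competes for the same finite space (shared logistic term) and
benefits from the regulated environment, but excretes nothing: it contributes
no push to the free pH and perceives the free pH directly, with no
self-product shift.  Its growth is weighted by a dimensionless advantage
``alpha``:

    dX_c/dt = X_c * (phi(X) * beta_c(pH_f) * alpha - delta)

with ``phi(X) = 1 - X_a - X_b - X_c``.  The regulator equations are unchanged
apart from the shared space term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._steady import batch_steady_state
from .core import GrowthNiche, external_level, growth_rate, perceived_pH
from .two_strain import (
    DEFAULT_PH_IN_GRID,
    DEFAULT_X0,
    SteadyStateResult,
    SystemState,
    TwoStrainParams,
    free_pH_qss,
    symmetric_consortium,
)

__all__ = [
    "ParasiteParams",
    "default_parasite",
    "free_ph_three",
    "rhs_three",
    "steady_state_three",
    "scan_parasite",
    "sigma_sections",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_PARASITE_OPT_GRID",
]

#: default scan grids: alpha in [0, 2] step 0.05; parasite pH_opt in [3, 11] step 0.2
DEFAULT_ALPHA_GRID = np.round(np.arange(0.0, 2.0 + 1e-9, 0.05), 10)
DEFAULT_PARASITE_OPT_GRID = np.round(np.arange(3.0, 11.0 + 1e-9, 0.2), 10)


@dataclass(frozen=True)
class ParasiteParams:
    """Two regulating strains plus one parasite niche and its advantage ``alpha``."""

    base: TwoStrainParams
    parasite_niche: GrowthNiche
    alpha: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha!r}")


def default_parasite(
    alpha: float = 1.0,
    parasite_opt: float = 7.0,
    *,
    parasite_delta_H: float = 2.5,
    **consortium_kwargs,
) -> ParasiteParams:
    """Reference three-species setup: baseline consortium plus a narrow-niche parasite.

    The parasite's niche half-width defaults to 2.5 pH units, much narrower
    than the regulators' 9.
    """
    return ParasiteParams(
        base=symmetric_consortium(**consortium_kwargs),
        parasite_niche=GrowthNiche(pH_opt=parasite_opt, delta_H=parasite_delta_H),
        alpha=alpha,
    )


def free_ph_three(abundances, params: ParasiteParams) -> float:
    """Free pH with zero push from the parasite: independent of ``X_c`` exactly."""
    x = np.asarray(abundances, dtype=float)
    base = params.base
    pushes = [
        (x[i], external_level(s, base.delta)) for i, s in enumerate(base.strains)
    ] + [(x[2], 0.0)]
    return free_pH_qss(base.pH_in, pushes)


def rhs_three(state: SystemState, params: ParasiteParams) -> np.ndarray:
    """Derivatives of ``(X_a, X_b, X_c)``; reduces to the two-strain model at X_c = 0."""
    x = state.abundances
    base = params.base
    pH_f = free_ph_three(x, params)
    phi = 1.0 - x.sum()
    dx = np.empty(3)
    for i, s in enumerate(base.strains):
        beta = growth_rate(s.niche, perceived_pH(pH_f, s, base.delta))
        dx[i] = x[i] * (phi * beta - base.delta)
    beta_c = growth_rate(params.parasite_niche, pH_f)
    dx[2] = x[2] * (phi * beta_c * params.alpha - base.delta)
    return dx


def _batch_rows(params: ParasiteParams, B: int):
    base = params.base
    lev = [external_level(s, base.delta) for s in base.strains] + [0.0]
    shf = [s.omega * s.gamma / base.delta for s in base.strains] + [0.0]
    opt = [s.niche.pH_opt for s in base.strains] + [params.parasite_niche.pH_opt]
    dH = [s.niche.delta_H for s in base.strains] + [params.parasite_niche.delta_H]
    al = [1.0, 1.0, params.alpha]
    tile = lambda row: np.tile(np.asarray(row, float), (B, 1))  # noqa: E731
    return tile(lev), tile(shf), tile(opt), tile(dH), tile(al)


def steady_state_three(
    params: ParasiteParams,
    initial=None,
    tol: float = 1e-9,
    t_max: float = 1e5,
    *,
    dt: float = 0.01,
) -> SteadyStateResult:
    """Relax the three-species system to stationarity."""
    x0 = np.full(3, DEFAULT_X0) if initial is None else np.array(
        initial.abundances if isinstance(initial, SystemState) else initial, dtype=float
    )
    lev, shf, opt, dH, al = _batch_rows(params, 1)
    out = batch_steady_state(
        pH_in=np.array([params.base.pH_in]),
        levels=lev,
        shifts=shf,
        pH_opt=opt,
        delta_H=dH,
        alpha=al,
        delta=params.base.delta,
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


def scan_parasite(
    params: ParasiteParams,
    pH_in_grid=None,
    axis: str = "alpha",
    axis_grid=None,
    *,
    x0: float = DEFAULT_X0,
    parasite_x0: float | None = None,
    dt: float = 0.01,
    tol: float = 1e-9,
    t_max: float = 1e5,
) -> pd.DataFrame:
    """Steady-state table varying pH_in against one parasite axis.

    ``axis`` is either ``"alpha"`` (parasite optimum held at its value in
    ``params``) or ``"parasite_opt"`` (``alpha`` held).  Each cell starts from
    ``X_a = X_b = x0`` and ``X_c = parasite_x0`` (default: same as ``x0``).
    Columns: ``pH_in, axis_name, axis_value, pH_f, X_a, X_b, X_c, converged``,
    axis-major then pH_in.
    """
    if axis not in ("alpha", "parasite_opt"):
        raise ValueError(f"axis must be 'alpha' or 'parasite_opt', got {axis!r}")
    pH_in_grid = np.asarray(DEFAULT_PH_IN_GRID if pH_in_grid is None else pH_in_grid, float)
    if axis_grid is None:
        axis_grid = DEFAULT_ALPHA_GRID if axis == "alpha" else DEFAULT_PARASITE_OPT_GRID
    axis_grid = np.asarray(axis_grid, dtype=float)

    A, P = np.meshgrid(axis_grid, pH_in_grid, indexing="ij")
    av = A.ravel()
    pin = P.ravel()
    B = av.size
    lev, shf, opt, dH, al = _batch_rows(params, B)
    if axis == "alpha":
        al[:, 2] = av
    else:
        opt[:, 2] = av

    x0_arr = np.full((B, 3), x0)
    x0_arr[:, 2] = x0 if parasite_x0 is None else parasite_x0

    out = batch_steady_state(
        pH_in=pin,
        levels=lev,
        shifts=shf,
        pH_opt=opt,
        delta_H=dH,
        alpha=al,
        delta=params.base.delta,
        x0=x0_arr,
        dt=dt,
        tol=tol,
        t_max=t_max,
    )
    return pd.DataFrame(
        {
            "pH_in": pin,
            "axis_name": axis,
            "axis_value": av,
            "pH_f": out["pH_f"],
            "X_a": out["X"][:, 0],
            "X_b": out["X"][:, 1],
            "X_c": out["X"][:, 2],
            "converged": out["converged"],
        }
    )


def sigma_sections(
    table: pd.DataFrame, optima: tuple[float, ...] = (7.0, 4.0, 10.0)
) -> dict[str, pd.DataFrame]:
    """Fixed-parasite-optimum sections of a ``parasite_opt``-axis scan.

    Returns ``{"sigma1": ..., "sigma2": ..., ...}`` in the order of ``optima``
    (defaults: neutral 7, acidic 4, alkaline 10), each a row-filter of the
    scan table at the grid value nearest the requested optimum.
    """
    if (table["axis_name"] != "parasite_opt").any():
        raise ValueError("sigma sections are defined on a parasite_opt-axis scan")
    values = np.unique(table["axis_value"].to_numpy())
    out: dict[str, pd.DataFrame] = {}
    for i, opt in enumerate(optima, start=1):
        nearest = values[np.argmin(np.abs(values - opt))]
        out[f"sigma{i}"] = table[table["axis_value"] == nearest].reset_index(drop=True)
    return out
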