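"""Growth niches, pH perception and excretion chemistry shared by every model tier.

The model world is a chemostat: a bioreactor diluted at a constant per-capita
rate ``delta``, inhabited by engineered strains that excrete an acid or a base
and thereby push the pH of the shared medium (the *free pH*, ``pH_f``) up or
down.  Three abstractions defined here are reused by the two-strain consortium,
the parasite extension and the random multispecies communities:

* an inverted-parabola growth response of each strain to the pH it perceives,
  maximal at the strain's optimum and vanishing at the edges of its viable
  interval;
* a *perceived pH*: each cell experiences the free pH shifted by the local
  cloud of its own excreted product, ``pH_f + omega * gamma / delta``, where
  ``gamma`` is the signed production rate and ``omega`` the sensitivity to the
  product (the shift equals ``omega`` times the equilibrium excreted level
  ``gamma / delta``);
* linear production/exchange/dilution kinetics for the excreted compound,
  whose fast equilibrium justifies the quasi-steady-state reductions used by
  the population models.

Sign convention: ``gamma > 0`` means the strain pushes the free pH *up*,
``gamma < 0`` means it pushes it *down*; the perception shift points in the
same direction as the push.  Chemical labels ("acid-producing",
"base-producing") are free text and carry no semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthNiche",
    "StrainSpec",
    "ChemistryParams",
    "ChemistryState",
    "growth_rate",
    "perceived_pH",
    "perception_shift",
    "external_level",
    "chemistry_rhs",
    "chemistry_equilibrium",
    "free_pH_qss",
]


@dataclass(frozen=True)
class GrowthNiche:
    """Symmetric single-peaked growth response to pH.

    ``beta(pH) = 1 - ((pH_opt - pH) / delta_H)**2`` equals 1 at the optimum
    ``pH_opt`` and 0 at ``pH_opt +/- delta_H``.  ``delta_H`` is the half-width
    of the viable interval, in pH units.

    The response is *not* clamped at zero: outside the viable interval it is
    negative, meaning net decay on top of dilution.  Population non-negativity
    is guaranteed by the multiplicative form of the population equations.
    """

    pH_opt: float
    delta_H: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pH_opt):
            raise ValueError(f"pH_opt must be finite, got {self.pH_opt!r}")
        if not (math.isfinite(self.delta_H) and self.delta_H > 0):
            raise ValueError(f"delta_H must be a finite positive half-width, got {self.delta_H!r}")


@dataclass(frozen=True)
class StrainSpec:
    """One strain: its niche, its signed push on the medium, and its self-perception.

    Parameters
    ----------
    niche :
        Growth response to perceived pH.
    gamma :
        Signed production rate of the excreted compound per unit time.
        ``gamma > 0`` pushes the free pH up, ``gamma < 0`` pushes it down.
    omega :
        Dimensionless sensitivity to the strain's own product; sets the size
        of the perception shift ``omega * gamma / delta``.
    label :
        Free-text tag (e.g. ``"base-producing"``); never interpreted.
    """

    niche: GrowthNiche
    gamma: float
    omega: float
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.gamma):
            raise ValueError(f"gamma must be finite, got {self.gamma!r}")
        if not (math.isfinite(self.omega) and self.omega >= 0):
            raise ValueError(f"omega must be finite and >= 0, got {self.omega!r}")


@dataclass(frozen=True)
class ChemistryParams:
    """Rates for production, membrane exchange and dilution of one excreted compound.

    The compound is produced inside the cell at rate ``gamma``, exchanged
    across the membrane at rates ``k_in`` (inside -> outside) and ``k_out``
    (outside -> inside), and the external pool is washed out at the chemostat
    dilution rate ``delta``.
    """

    gamma: float
    k_in: float
    k_out: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("k_in", "k_out", "delta"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.gamma):
            raise ValueError(f"gamma must be finite, got {self.gamma!r}")


@dataclass(frozen=True)
class ChemistryState:
    """Intracellular and extracellular concentration of one excreted compound."""

    internal: float
    external: float


def growth_rate(niche: GrowthNiche, perceived_pH):
    """Growth response ``1 - ((pH_opt - pH) / delta_H)**2`` at a perceived pH.

    Total function of real inputs; vectorizes over array-valued ``perceived_pH``.
    Negative values (outside the viable interval) mean net decay before dilution.
    """
    p = np.asarray(perceived_pH, dtype=float)
    out = 1.0 - ((niche.pH_opt - p) / niche.delta_H) ** 2
    return float(out) if out.ndim == 0 else out


def perception_shift(strain: StrainSpec, delta: float) -> float:
    """Signed shift ``omega * gamma / delta`` between free and perceived pH."""
    if delta == 0:
        raise ZeroDivisionError(
            "delta = 0 is an unphysical chemostat: the excreted compound has no "
            "finite equilibrium level and the perception shift diverges"
        )
    return strain.omega * strain.gamma / delta


def perceived_pH(pH_f: float, strain: StrainSpec, delta: float) -> float:
    """pH experienced locally by a strain: free pH shifted by its own product cloud.

    At chemistry equilibrium the external product level is ``gamma / delta``,
    so the shift is ``omega * gamma / delta``, in the same direction as the
    strain's push on the free pH.
    """
    return pH_f + perception_shift(strain, delta)


def external_level(strain: StrainSpec, delta: float) -> float:
    """Signed equilibrium external product level ``gamma / delta`` of one strain."""
    if delta == 0:
        raise ZeroDivisionError("delta = 0: no finite equilibrium external level")
    return strain.gamma / delta


def chemistry_rhs(state: ChemistryState, params: ChemistryParams) -> tuple[float, float]:
    """Time derivatives ``(d internal/dt, d external/dt)`` of the excretion kinetics.

    ``d internal/dt = gamma - k_in * internal + k_out * external``
    ``d external/dt = k_in * internal - k_out * external - delta * external``
    """
    exchange = params.k_in * state.internal - params.k_out * state.external
    return (params.gamma - exchange, exchange - params.delta * state.external)


def chemistry_equilibrium(params: ChemistryParams) -> ChemistryState:
    """Unique equilibrium of the excretion kinetics.

    Setting both derivatives of :func:`chemistry_rhs` to zero gives

    ``external* = gamma / delta``
    ``internal* = gamma * (k_out + delta) / (delta * k_in)``

    ``external*`` is the level that enters the quasi-steady-state free-pH
    relation; ``internal*`` plays no further role downstream.
    """
    if params.delta == 0 or params.k_in == 0:
        raise ZeroDivisionError(
            "no finite chemistry equilibrium for delta = 0 or k_in = 0"
        )
    external = params.gamma / params.delta
    internal = params.gamma * (params.k_out + params.delta) / (params.delta * params.k_in)
    return ChemistryState(internal=internal, external=external)


def free_pH_qss(pH_in, pushes) -> float:
    """Quasi-steady-state free pH: input pH plus the summed biotic pushes.

    ``pH_f = pH_in + sum_s abundance_s * level_s`` where ``level_s`` is the
    signed equilibrium external product level of strain ``s`` (positive for an
    up-pusher, negative for a down-pusher).  Linear in each abundance and equal
    to ``pH_in`` when all levels vanish.

    Parameters
    ----------
    pH_in :
        External input pH.
    pushes :
        Iterable of ``(abundance, signed_external_level)`` pairs.
    """
    total = float(pH_in)
    for abundance, level in pushes:
        if abundance < 0:
            raise ValueError(f"abundances must be >= 0, got {abundance!r}")
        total += abundance * level
    return total
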