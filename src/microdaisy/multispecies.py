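"""Random n-species communities with immigration and dynamical, saturating pH.

Unlike the two- and three-species models, the free pH is now a state variable:
there is no external input term, and the community itself is the only driver,

    dX_i/dt  = X_i * (phi(X) * beta_i - delta) + epsilon
    dpH_f/dt = (sum_i X_i * gamma_i * omega / delta) * S(pH_f)

with ``beta_i`` evaluated at each species' perceived pH
``pH_f + omega * gamma_i / delta`` and the saturation factor

    S(pH_f) = pH_f * (2b - pH_f) / b**2

which vanishes at 0 and ``2b`` (confining the pH to ``[0, 2b]``) and is
normalized to 1 at the range midpoint ``b``, so the biotic push retains the
same scale as in the two-species model.  A small immigration rate ``epsilon``
keeps every species nonzero — a mean-field proxy for dispersal and
evolutionary rescue that prevents absorbing extinctions.

Communities are sampled at random: niche optima, half-widths and push-rate
magnitudes uniform on fixed intervals, push direction a fair coin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GrowthNiche, StrainSpec
from .trajectory import Trajectory
from .two_strain import SystemState

__all__ = [
    "CommunitySpec",
    "sample_community",
    "saturation",
    "rhs_community",
    "integrate_community",
    "integrate_batch",
    "DEFAULT_DT",
    "DEFAULT_T_END",
]

#: default integration step and horizon for community runs
DEFAULT_DT = 0.05
DEFAULT_T_END = 5000.0


@dataclass(frozen=True)
class CommunitySpec:
    """An n-species community and its shared environment parameters.

    ``omega`` (product sensitivity), the dilution rate ``delta``, the
    immigration rate ``epsilon`` and the pH-range midpoint ``b`` are shared by
    all members; each strain carries its own niche and signed push rate.
    """

    strains: tuple[StrainSpec, ...]
    delta: float = 0.1
    epsilon: float = 1e-3
    b: float = 7.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if len(self.strains) < 1:
            raise ValueError("a community needs at least one strain")
        if not (math.isfinite(self.delta) and self.delta > 0):
            raise ValueError(f"delta must be finite and > 0, got {self.delta!r}")
        if not (math.isfinite(self.epsilon) and self.epsilon >= 0):
            raise ValueError(f"epsilon must be finite and >= 0, got {self.epsilon!r}")
        if not (math.isfinite(self.b) and self.b > 0):
            raise ValueError(f"b must be finite and > 0, got {self.b!r}")

    @property
    def n(self) -> int:
        return len(self.strains)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked per-species ``(pH_opt, delta_H, gamma)`` arrays."""
        return (
            np.array([s.niche.pH_opt for s in self.strains]),
            np.array([s.niche.delta_H for s in self.strains]),
            np.array([s.gamma for s in self.strains]),
        )

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "epsilon": self.epsilon,
            "b": self.b,
            "omega": self.omega,
            "strains": [
                {
                    "pH_opt": s.niche.pH_opt,
                    "delta_H": s.niche.delta_H,
                    "gamma": s.gamma,
                    "omega": s.omega,
                    "label": s.label,
                }
                for s in self.strains
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunitySpec":
        strains = tuple(
            StrainSpec(
                niche=GrowthNiche(pH_opt=s["pH_opt"], delta_H=s["delta_H"]),
                gamma=s["gamma"],
                omega=s.get("omega", d.get("omega", 1.0)),
                label=s.get("label", ""),
            )
            for s in d["strains"]
        )
        return cls(
            strains=strains,
            delta=d["delta"],
            epsilon=d["epsilon"],
            b=d["b"],
            omega=d["omega"],
        )


def sample_community(
    n: int,
    *,
    seed=None,
    rng: np.random.Generator | None = None,
    pH_opt_range: tuple[float, float] = (4.0, 9.0),
    delta_H_range: tuple[float, float] = (1.0, 4.0),
    gamma_range: tuple[float, float] = (0.05, 0.2),
    delta: float = 0.1,
    omega: float = 1.0,
    epsilon: float = 1e-3,
    b: float = 7.0,
) -> CommunitySpec:
    """Draw a random community specification, reproducibly.

    Per strain: ``pH_opt ~ U[4, 9]``, half-width ``delta_H ~ U[1, 4]``,
    ``|gamma| ~ U[0.05, 0.2]`` with an equiprobable sign.  Community-level
    defaults: ``delta = 0.1``, ``omega = 1``, ``epsilon = 1e-3``, ``b = 7``.

    Draw order is fixed (optima, half-widths, magnitudes, signs) so a given
    generator state always yields the same community.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    for name, (lo, hi) in (
        ("pH_opt_range", pH_opt_range),
        ("delta_H_range", delta_H_range),
        ("gamma_range", gamma_range),
    ):
        if lo > hi:
            raise ValueError(f"{name} has min > max: {(lo, hi)!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    opts = rng.uniform(*pH_opt_range, size=n)
    widths = rng.uniform(*delta_H_range, size=n)
    mags = rng.uniform(*gamma_range, size=n)
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    strains = tuple(
        StrainSpec(
            niche=GrowthNiche(pH_opt=float(o), delta_H=float(w)),
            gamma=float(s * m),
            omega=omega,
            label=f"sp{i + 1}",
        )
        for i, (o, w, m, s) in enumerate(zip(opts, widths, mags, signs))
    )
    return CommunitySpec(strains=strains, delta=delta, epsilon=epsilon, b=b, omega=omega)


def saturation(pH, b: float):
    """Saturation factor ``pH (2b - pH) / b**2``: 0 at the range edges, 1 at b."""
    return pH * (2.0 * b - pH) / b**2


def rhs_community(state, spec: CommunitySpec) -> tuple[np.ndarray, float]:
    """Derivatives ``(dX, dpH_f)`` of one community at one state.

    ``state`` is a :class:`~microdaisy.two_strain.SystemState` or an
    ``(abundances, pH_f)`` pair.
    """
    if isinstance(state, SystemState):
        x, pH = state.abundances, state.pH_f
    else:
        x, pH = state
        x = np.asarray(x, dtype=float)
    opt, dH, gam = spec.arrays()
    shift = spec.omega * gam / spec.delta
    beta = 1.0 - ((opt - (pH + shift)) / dH) ** 2
    phi = 1.0 - x.sum()
    dx = x * (phi * beta - spec.delta) + spec.epsilon
    dpH = (x * gam).sum() * (spec.omega / spec.delta) * saturation(pH, spec.b)
    return dx, float(dpH)


class _BatchParams:
    """Stacked per-species arrays for a batch of same-size communities."""

    __slots__ = ("pH_opt", "delta_H", "gamma", "shift", "delta", "epsilon", "b", "omega")

    def __init__(self, specs: Sequence[CommunitySpec]):
        first = specs[0]
        for s in specs[1:]:
            if (s.delta, s.epsilon, s.b, s.omega, s.n) != (
                first.delta,
                first.epsilon,
                first.b,
                first.omega,
                first.n,
            ):
                raise ValueError(
                    "batched communities must share n, delta, epsilon, b and omega"
                )
        stacked = [s.arrays() for s in specs]
        self.pH_opt = np.stack([a[0] for a in stacked])
        self.delta_H = np.stack([a[1] for a in stacked])
        self.gamma = np.stack([a[2] for a in stacked])
        self.delta = first.delta
        self.epsilon = first.epsilon
        self.b = first.b
        self.omega = first.omega
        self.shift = self.omega * self.gamma / self.delta


def _batch_rhs(X, pH, P: _BatchParams):
    # stage arguments are projected onto the invariant region (X >= 0,
    # pH in [0, 2b]) so that intermediate RK4 stages cannot leave it and
    # explode through the logistic term; a no-op for interior trajectories
    X = np.maximum(X, 0.0)
    pH = np.clip(pH, 0.0, 2.0 * P.b)
    beta = 1.0 - ((P.pH_opt - (pH[:, None] + P.shift)) / P.delta_H) ** 2
    phi = 1.0 - X.sum(axis=1)
    dX = X * (phi[:, None] * beta - P.delta) + P.epsilon
    dpH = (X * P.gamma).sum(axis=1) * (P.omega / P.delta) * saturation(pH, P.b)
    return dX, dpH


def integrate_batch(
    specs: Sequence[CommunitySpec],
    X0: np.ndarray,
    pH0: np.ndarray,
    dt: float = DEFAULT_DT,
    t_end: float = DEFAULT_T_END,
    *,
    record_every: int = 1,
    record_start: int = 0,
    forcing: np.ndarray | None = None,
    on_nonfinite: str = "raise",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4 for ``B`` same-size communities at once.

    After each full step abundances are floored at zero (immigration keeps
    them positive) and the pH is clipped to ``[0, 2b]`` — a safety net for the
    finite step, since the saturation factor already vanishes at the edges.
    ``forcing`` is an optional ``(B, n_steps)`` array of additive pH increments
    applied (then re-clipped) after each step.

    Recording starts at step ``record_start`` and keeps every
    ``record_every``-th step from there (plus the final step).  Returns
    ``(t_rec, X_rec, pH_rec)`` with shapes ``(R,)``, ``(R, B, n)``, ``(R, B)``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    P = _BatchParams(specs)
    X = np.array(X0, dtype=float, copy=True)
    pH = np.array(pH0, dtype=float, copy=True)
    B, n = X.shape
    n_steps = int(round(t_end / dt))
    if forcing is not None and forcing.shape != (B, n_steps):
        raise ValueError(f"forcing must have shape {(B, n_steps)}, got {forcing.shape}")

    rec_idx = [k for k in range(record_start, n_steps + 1) if (k - record_start) % record_every == 0]
    if not rec_idx or rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    X_rec = np.empty((len(rec_idx), B, n))
    pH_rec = np.empty((len(rec_idx), B))
    t_rec = np.asarray(rec_idx, dtype=float) * dt
    pos = 0
    two_b = 2.0 * P.b
    h = dt

    for k in range(n_steps + 1):
        if pos < len(rec_idx) and k == rec_idx[pos]:
            X_rec[pos] = X
            pH_rec[pos] = pH
            pos += 1
        if k == n_steps:
            break
        with np.errstate(over="ignore", invalid="ignore"):
            k1X, k1p = _batch_rhs(X, pH, P)
            k2X, k2p = _batch_rhs(X + 0.5 * h * k1X, pH + 0.5 * h * k1p, P)
            k3X, k3p = _batch_rhs(X + 0.5 * h * k2X, pH + 0.5 * h * k2p, P)
            k4X, k4p = _batch_rhs(X + h * k3X, pH + h * k3p, P)
            X += (h / 6.0) * (k1X + 2.0 * k2X + 2.0 * k3X + k4X)
            pH += (h / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            np.maximum(X, 0.0, out=X)
            np.clip(pH, 0.0, two_b, out=pH)
            if forcing is not None:
                pH += forcing[:, k]
                np.clip(pH, 0.0, two_b, out=pH)

    if on_nonfinite == "raise" and not (
        np.isfinite(X).all() and np.isfinite(pH).all()
    ):
        bad = np.where(~(np.isfinite(X).all(axis=1) & np.isfinite(pH)))[0]
        raise FloatingPointError(
            f"non-finite state in batch members {bad.tolist()} "
            f"(dt={dt}, t_end={t_end}); first bad spec: {specs[bad[0]].to_dict()!r}"
        )
    return t_rec, X_rec, pH_rec


def initial_state(spec: CommunitySpec, pH0: float = 7.0) -> SystemState:
    """Default initial condition: ``X_i = 1/(2n)`` each, medium at pH 7."""
    return SystemState(abundances=np.full(spec.n, 1.0 / (2 * spec.n)), pH_f=pH0)


def integrate_community(
    spec: CommunitySpec,
    initial: SystemState | None = None,
    dt: float = DEFAULT_DT,
    t_end: float = DEFAULT_T_END,
    *,
    record_every: int = 1,
    meta: dict | None = None,
) -> Trajectory:
    """RK4 trajectory of one community from the standard initial condition.

    By default all species start at ``1/(2n)`` in a pH 7 medium.
    """
    if initial is None:
        initial = initial_state(spec)
    t, X_rec, pH_rec = integrate_batch(
        [spec],
        X0=initial.abundances[None, :],
        pH0=np.array([initial.pH_f]),
        dt=dt,
        t_end=t_end,
        record_every=record_every,
    )
    info = {"dt": dt, "t_end": t_end, "method": "rk4", "spec": spec.to_dict()}
    if meta:
        info.update(meta)
    return Trajectory(t=t, abundances=X_rec[:, 0, :], pH_f=pH_rec[:, 0], meta=info)
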