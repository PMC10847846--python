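"""Regime classification, ensemble statistics and attractor reconstruction.

A community trajectory ends in one of three regimes:

* ``fixed_point`` — at least one species survives and all surviving series are
  flat (relative amplitude below tolerance) in the analysis window;
* ``oscillatory_chaotic`` — some surviving series still fluctuates; periodic,
  quasi-periodic and chaotic motion are deliberately not distinguished;
* ``collapse`` — no species stays above the survival floor (with immigration
  on, abundances settle at the immigration-sustained level epsilon/delta,
  which lies below the floor by construction).

Classification looks only at the final fraction of the trajectory, discarding
the transient, and is invariant to species relabelling and to uniform time
rescaling.  The ensemble driver repeats sample -> integrate -> classify over
many random communities per community size and aggregates regime frequencies
and survivor statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .multispecies import (
    DEFAULT_DT,
    DEFAULT_T_END,
    CommunitySpec,
    integrate_batch,
    sample_community,
)
from .trajectory import Trajectory

__all__ = [
    "LABELS",
    "Classification",
    "EnsembleSummary",
    "classify_trajectory",
    "ensemble_experiment",
    "smooth_frequencies",
    "delay_embed",
]

LABELS = ("fixed_point", "oscillatory_chaotic", "collapse")

#: default analysis window (final fraction of the trajectory)
DEFAULT_WINDOW_FRACTION = 0.2
#: default relative-amplitude threshold separating flat from fluctuating
DEFAULT_AMPLITUDE_TOL = 0.01


@dataclass
class Classification:
    """Regime label plus survivor and amplitude diagnostics for one trajectory."""

    label: str
    survivors: int
    survivor_fraction: float
    per_species_amplitude: np.ndarray
    per_species_mean: np.ndarray


@dataclass
class EnsembleSummary:
    """Aggregated regime frequencies and survivor statistics per community size."""

    sizes: tuple[int, ...]
    replicas: int
    master_seed: int
    frequencies: pd.DataFrame  # index n, columns LABELS (+ "failed" if any)
    survivor_mean: pd.Series
    survivor_sd: pd.Series
    records: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "replicas": self.replicas,
            "master_seed": self.master_seed,
            "frequencies": {
                str(n): {c: float(v) for c, v in row.items()}
                for n, row in self.frequencies.iterrows()
            },
            "survivor_fraction_mean": {
                str(n): float(v) for n, v in self.survivor_mean.items()
            },
            "survivor_fraction_sd": {
                str(n): float(v) for n, v in self.survivor_sd.items()
            },
        }


def default_survival_floor(spec: CommunitySpec) -> float:
    """Twice the immigration-sustained abundance ``epsilon / delta``.

    Immigrants alone hold a species near ``epsilon / delta``; doubling that
    level ensures pure immigration never counts as survival.
    """
    return 2.0 * spec.epsilon / spec.delta


def _classify_window(
    X_window: np.ndarray, survival_floor: float, amplitude_tol: float
) -> Classification:
    """Shared classification core on a ``(T, n)`` window of abundances."""
    means = X_window.mean(axis=0)
    mx = X_window.max(axis=0)
    mn = X_window.min(axis=0)
    span = mx + mn
    amps = np.where(span > 0, (mx - mn) / np.where(span > 0, span, 1.0), 0.0)
    alive = means > survival_floor
    survivors = int(alive.sum())
    n = X_window.shape[1]
    if survivors == 0:
        label = "collapse"
    elif (amps[alive] > amplitude_tol).any():
        label = "oscillatory_chaotic"
    else:
        label = "fixed_point"
    return Classification(
        label=label,
        survivors=survivors,
        survivor_fraction=survivors / n,
        per_species_amplitude=amps,
        per_species_mean=means,
    )


def classify_trajectory(
    traj: Trajectory,
    spec: CommunitySpec,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    survival_floor: float | None = None,
    amplitude_tol: float = DEFAULT_AMPLITUDE_TOL,
) -> Classification:
    """Classify one trajectory from its final ``window_fraction``.

    A species survives when its time-averaged abundance in the window exceeds
    ``survival_floor`` (default ``2 * epsilon / delta``); the trajectory is
    ``oscillatory_chaotic`` when any survivor's relative amplitude
    ``(max - min) / (max + min)`` exceeds ``amplitude_tol``.
    """
    if survival_floor is None:
        survival_floor = default_survival_floor(spec)
    win = traj.window(window_fraction)
    if len(win) < 2:
        raise ValueError(
            f"analysis window has {len(win)} stored point(s); "
            "integrate longer or record more densely"
        )
    return _classify_window(win.abundances, survival_floor, amplitude_tol)


def replica_seed_sequence(master_seed: int, n: int, replica: int) -> np.random.SeedSequence:
    """Deterministic per-replica seed stream, independent across (n, replica)."""
    return np.random.SeedSequence(master_seed, spawn_key=(n, replica))


def ensemble_experiment(
    sizes: Sequence[int] = tuple(range(1, 31)),
    replicas: int = 200,
    master_seed: int = 0,
    *,
    dt: float = DEFAULT_DT,
    t_end: float = DEFAULT_T_END,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    survival_floor: float | None = None,
    amplitude_tol: float = DEFAULT_AMPLITUDE_TOL,
    record_every: int = 10,
    sampler_kwargs: dict | None = None,
) -> EnsembleSummary:
    """Sample, integrate and classify ``replicas`` random communities per size.

    All replicas of one size are integrated as a single vectorized RK4 batch;
    only the analysis window is stored (thinned by ``record_every``).  Rare
    integration failures (non-finite states) are recorded under a ``failed``
    label and excluded from the three-regime frequencies, which always sum
    to 1 over the successful replicas.

    The full per-replica table is retained in ``EnsembleSummary.records``.
    """
    sampler_kwargs = dict(sampler_kwargs or {})
    rows = []
    n_steps = int(round(t_end / dt))
    record_start = int(np.floor((1.0 - window_fraction) * n_steps))

    for n in sizes:
        specs = []
        seeds = []
        for r in range(replicas):
            seq = replica_seed_sequence(master_seed, n, r)
            seeds.append(int(seq.generate_state(1)[0]))
            specs.append(sample_community(n, rng=np.random.default_rng(seq), **sampler_kwargs))
        floor = (
            default_survival_floor(specs[0]) if survival_floor is None else survival_floor
        )
        X0 = np.full((replicas, n), 1.0 / (2 * n))
        pH0 = np.full(replicas, 7.0)
        _, X_rec, _ = integrate_batch(
            specs,
            X0,
            pH0,
            dt=dt,
            t_end=t_end,
            record_every=record_every,
            record_start=record_start,
            on_nonfinite="ignore",
        )
        for r in range(replicas):
            Xw = X_rec[:, r, :]
            if not np.isfinite(Xw).all():
                rows.append((n, r, seeds[r], "failed", 0, np.nan))
                continue
            c = _classify_window(Xw, floor, amplitude_tol)
            rows.append((n, r, seeds[r], c.label, c.survivors, c.survivor_fraction))

    records = pd.DataFrame(
        rows, columns=["n", "replica", "seed", "label", "survivors", "survivor_fraction"]
    )
    ok = records[records["label"] != "failed"]
    freq = (
        ok.groupby("n")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(LABELS), fill_value=0.0)
    )
    n_failed = int((records["label"] == "failed").sum())
    if n_failed:
        freq["failed"] = (
            records.groupby("n")["label"].apply(lambda s: (s == "failed").mean())
        )
    return EnsembleSummary(
        sizes=tuple(int(n) for n in sizes),
        replicas=replicas,
        master_seed=master_seed,
        frequencies=freq,
        survivor_mean=ok.groupby("n")["survivor_fraction"].mean(),
        survivor_sd=ok.groupby("n")["survivor_fraction"].std(ddof=0),
        records=records,
    )


def smooth_frequencies(freq, degree: int, x=None) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial smoothing of a frequency curve, for presentation.

    Returns ``(fitted_values, coefficients)`` with coefficients in ascending
    power order.  Degree 4 is the convention for raw regime-frequency curves
    and degree 3 for the survivor curve; raw frequencies should always be
    reported alongside the fit.
    """
    y = np.asarray(freq, dtype=float)
    x = np.arange(y.size, dtype=float) if x is None else np.asarray(x, dtype=float)
    if y.size < degree + 1:
        raise ValueError(
            f"need at least degree+1 = {degree + 1} points to fit degree {degree}, got {y.size}"
        )
    poly = np.polynomial.Polynomial.fit(x, y, deg=degree)
    return poly(x), poly.convert().coef


def delay_embed(series, T: int) -> np.ndarray:
    """Three-dimensional delay embedding ``(X(t), X(t+T), X(t+2T))``.

    ``T`` is the delay in samples; a series of length ``L`` yields ``L - 2T``
    embedded points.
    """
    x = np.asarray(series, dtype=float).ravel()
    T = int(T)
    if T < 1:
        raise ValueError(f"delay T must be a positive number of samples, got {T!r}")
    L = x.size
    if L <= 2 * T:
        raise ValueError(f"series of length {L} is too short for delay T={T} (need L > 2T)")
    return np.column_stack([x[: L - 2 * T], x[T : L - T], x[2 * T :]])
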