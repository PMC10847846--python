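"""Time-series container shared by all integrators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A fixed-step integration record: time grid, abundances, free pH.

    Attributes
    ----------
    t :
        Time points, shape ``(T,)``.
    abundances :
        Species abundances, shape ``(T, n)``.
    pH_f :
        Free pH of the medium at each time point, shape ``(T,)``.
    forcing :
        Cumulative external forcing path ``pH_in(t)`` for stochastically
        forced runs, shape ``(T,)``; ``None`` for unforced runs.
    meta :
        Provenance: parameters, seed, integrator, ``dt`` — whatever the
        producing driver chooses to record.
    """

    t: np.ndarray
    abundances: np.ndarray
    pH_f: np.ndarray
    forcing: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.abundances = np.atleast_2d(np.asarray(self.abundances, dtype=float))
        self.pH_f = np.asarray(self.pH_f, dtype=float)
        if self.abundances.shape[0] != self.t.shape[0]:
            raise ValueError(
                f"abundances has {self.abundances.shape[0]} rows for "
                f"{self.t.shape[0]} time points"
            )

    @property
    def n_species(self) -> int:
        return self.abundances.shape[1]

    def __len__(self) -> int:
        return self.t.shape[0]

    def window(self, fraction: float) -> "Trajectory":
        """The final ``fraction`` of the trajectory, by elapsed time."""
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction!r}")
        start = self.t[-1] - fraction * (self.t[-1] - self.t[0])
        idx = np.searchsorted(self.t, start, side="left")
        return Trajectory(
            t=self.t[idx:],
            abundances=self.abundances[idx:],
            pH_f=self.pH_f[idx:],
            forcing=None if self.forcing is None else self.forcing[idx:],
            meta=self.meta,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: ``t, pH_f, X_1..X_n`` (plus ``pH_in`` when forced)."""
        data = {"t": self.t, "pH_f": self.pH_f}
        if self.forcing is not None:
            data["pH_in"] = self.forcing
        for i in range(self.n_species):
            data[f"X_{i + 1}"] = self.abundances[:, i]
        return pd.DataFrame(data)
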