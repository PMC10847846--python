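"""Experiment configuration, dispatch and provenance-carrying serialization.

Every experiment kind (``scan2``, ``scan3``, ``ensemble``, ``forced``) has a
flat schema of known keys with defaults equal to the reference parameter sets
of the corresponding study; unknown keys are rejected by name.  Every numeric
output file gets a JSON sidecar carrying the resolved configuration, the seed,
the package version and a configuration hash, so any output can be regenerated
from its sidecar alone.  Timestamps live only in the sidecar: CSV bodies are
byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import classify_trajectory, ensemble_experiment, smooth_frequencies
from .forcing import NoiseSpec, buffering_stats, integrate_forced
from .multispecies import CommunitySpec, sample_community
from .parasite import default_parasite, scan_parasite, sigma_sections
from .trajectory import Trajectory
from .two_strain import homeostatic_range, scan_surface, symmetric_consortium

__all__ = ["ExperimentConfig", "load_config", "run_experiment", "SCHEMAS"]

#: per-kind known keys and defaults (reference parameter sets; grids as
#: (min, max, step) triples)
SCHEMAS: dict[str, dict] = {
    "scan2": {
        "gamma_grid": [0.0, 0.05, 0.002],
        "pH_in_grid": [0.0, 16.0, 0.1],
        "delta": 0.01,
        "omega": 0.5,
        "pH_opt": 7.0,
        "delta_H": 9.0,
        "x0": 0.01,
        "dt": 0.01,
        "tol": 1e-9,
        "t_max": 1e5,
        "pop_floor": 0.05,
        "pH_tolerance": 2.0,
        "slice_gamma": None,
    },
    "scan3": {
        "axis": "alpha",
        "axis_grid": None,  # default depends on axis
        "pH_in_grid": [0.0, 16.0, 0.1],
        "alpha": 1.0,
        "parasite_opt": 7.0,
        "parasite_delta_H": 2.5,
        "gamma": 0.04,
        "delta": 0.01,
        "omega": 0.5,
        "pH_opt": 7.0,
        "delta_H": 9.0,
        "x0": 0.01,
        "dt": 0.01,
        "tol": 1e-9,
        "t_max": 1e5,
    },
    "ensemble": {
        "sizes": list(range(1, 31)),
        "replicas": 200,
        "seed": 0,
        "dt": 0.05,
        "t_end": 5000.0,
        "window_fraction": 0.2,
        "amplitude_tol": 0.01,
        "survival_floor": None,
        "record_every": 10,
        "fit_degree_regimes": 4,
        "fit_degree_survivors": 3,
    },
    "forced": {
        "n": 10,
        "seed": 0,
        "increment_bound": 0.5,
        "excursion_bound": 5.0,
        "t_end": 2000.0,
        "dt": 0.05,
        "record_every": 10,
        "window_fraction": 0.5,
    },
}


@dataclass
class ExperimentConfig:
    """One fully-resolved experiment: kind plus validated settings."""

    kind: str
    settings: dict

    def to_dict(self) -> dict:
        return {"kind": self.kind, "settings": dict(self.settings)}

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(
    kind: str | None = None,
    path: str | Path | None = None,
    overrides: dict | None = None,
) -> ExperimentConfig:
    """Resolve an experiment configuration from a YAML file and/or overrides.

    The YAML document may carry a top-level ``kind`` key; flag overrides win
    over the file, which wins over the schema defaults.  Unknown keys are
    rejected with their key path.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping, got {type(loaded).__name__}")
        raw.update(loaded)
    file_kind = raw.pop("kind", None)
    kind = kind or file_kind
    if kind not in SCHEMAS:
        raise ValueError(f"unknown experiment kind: {kind!r} (choose from {sorted(SCHEMAS)})")
    settings = dict(SCHEMAS[kind])
    for source in (raw, overrides or {}):
        for key, value in source.items():
            if value is None and key in settings:
                continue
            if key not in settings:
                raise ValueError(f"unknown config key: {kind}.{key}")
            settings[key] = value
    return ExperimentConfig(kind=kind, settings=settings)


def _grid(triple) -> np.ndarray:
    lo, hi, step = triple
    return np.round(np.arange(lo, hi + step * 1e-6, step), 10)


def write_table(df: pd.DataFrame, path: Path) -> None:
    """CSV dialect: comma, '.' decimal, header, UTF-8, LF, 12 significant digits."""
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n", encoding="utf-8")


def write_sidecar(path: Path, config: ExperimentConfig, outputs: list[str], extra: dict | None = None) -> None:
    record = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "package": "microdaisy",
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "outputs": outputs,
    }
    if extra:
        record.update(extra)
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def _run_scan2(cfg: ExperimentConfig, outdir: Path) -> list[Path]:
    s = cfg.settings
    params = symmetric_consortium(
        gamma=max(float(_grid(s["gamma_grid"])[-1]), 1e-6),
        delta=s["delta"],
        omega=s["omega"],
        pH_opt=s["pH_opt"],
        delta_H=s["delta_H"],
    )
    table = scan_surface(
        params,
        pH_in_grid=_grid(s["pH_in_grid"]),
        gamma_grid=_grid(s["gamma_grid"]),
        x0=s["x0"],
        dt=s["dt"],
        tol=s["tol"],
        t_max=s["t_max"],
    )
    paths = [outdir / "scan2_surface.csv"]
    write_table(table, paths[0])
    slice_gamma = s["slice_gamma"]
    if slice_gamma is not None:
        gammas = table["gamma"].unique()
        g = gammas[np.argmin(np.abs(gammas - slice_gamma))]
        sl = table[table["gamma"] == g].reset_index(drop=True)
        slice_path = outdir / "scan2_slice.csv"
        write_table(sl, slice_path)
        paths.append(slice_path)
        rng = homeostatic_range(sl, s["pop_floor"], s["pH_tolerance"], s["pH_opt"])
        range_path = outdir / "scan2_range.json"
        range_path.write_text(
            json.dumps(
                {"gamma": float(g), **(rng.to_dict() if rng else {"empty": True})},
                indent=2,
            )
            + "\n"
        )
        paths.append(range_path)
    return paths


def _run_scan3(cfg: ExperimentConfig, outdir: Path) -> list[Path]:
    s = cfg.settings
    params = default_parasite(
        alpha=s["alpha"],
        parasite_opt=s["parasite_opt"],
        parasite_delta_H=s["parasite_delta_H"],
        gamma=s["gamma"],
        delta=s["delta"],
        omega=s["omega"],
        pH_opt=s["pH_opt"],
        delta_H=s["delta_H"],
    )
    table = scan_parasite(
        params,
        pH_in_grid=_grid(s["pH_in_grid"]),
        axis=s["axis"],
        axis_grid=None if s["axis_grid"] is None else _grid(s["axis_grid"]),
        x0=s["x0"],
        dt=s["dt"],
        tol=s["tol"],
        t_max=s["t_max"],
    )
    paths = [outdir / "scan3_surface.csv"]
    write_table(table, paths[0])
    if s["axis"] == "parasite_opt":
        sections = sigma_sections(table)
        payload = {
            name: {
                "parasite_opt": float(sec["axis_value"].iloc[0]),
                "rows": sec.drop(columns=["axis_name"]).to_dict(orient="list"),
            }
            for name, sec in sections.items()
        }
        sec_path = outdir / "scan3_sections.json"
        sec_path.write_text(json.dumps(payload, indent=2) + "\n")
        paths.append(sec_path)
    return paths


def _run_ensemble(cfg: ExperimentConfig, outdir: Path) -> list[Path]:
    s = cfg.settings
    summary = ensemble_experiment(
        sizes=[int(n) for n in s["sizes"]],
        replicas=int(s["replicas"]),
        master_seed=int(s["seed"]),
        dt=s["dt"],
        t_end=s["t_end"],
        window_fraction=s["window_fraction"],
        survival_floor=s["survival_floor"],
        amplitude_tol=s["amplitude_tol"],
        record_every=int(s["record_every"]),
    )
    paths = [outdir / "ensemble_replicas.csv", outdir / "ensemble_summary.json"]
    write_table(summary.records, paths[0])
    payload = summary.to_dict()
    fits = {}
    x = np.asarray(summary.sizes, dtype=float)
    for label in summary.frequencies.columns:
        y = summary.frequencies[label].reindex(summary.sizes).to_numpy()
        if y.size >= s["fit_degree_regimes"] + 1:
            _, coef = smooth_frequencies(y, s["fit_degree_regimes"], x=x)
            fits[label] = [float(c) for c in coef]
    surv = summary.survivor_mean.reindex(summary.sizes).to_numpy()
    if surv.size >= s["fit_degree_survivors"] + 1:
        _, coef = smooth_frequencies(surv, s["fit_degree_survivors"], x=x)
        fits["survivor_fraction"] = [float(c) for c in coef]
    payload["polynomial_fits"] = fits
    paths[1].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths


def _run_forced(cfg: ExperimentConfig, outdir: Path) -> list[Path]:
    s = cfg.settings
    seed = int(s["seed"])
    spec = sample_community(int(s["n"]), seed=seed)
    noise = NoiseSpec(
        t_end=s["t_end"],
        dt=s["dt"],
        increment_bound=s["increment_bound"],
        excursion_bound=s["excursion_bound"],
        seed=seed + 1,
    )
    traj = integrate_forced(spec, noise, record_every=int(s["record_every"]))
    stats = buffering_stats(traj, window_fraction=s["window_fraction"])
    paths = [outdir / "forced_trajectory.csv", outdir / "forced_buffering.json"]
    write_table(traj.to_frame(), paths[0])
    paths[1].write_text(
        json.dumps(
            {"stats": stats, "seed": seed, "spec": spec.to_dict()}, indent=2, sort_keys=True
        )
        + "\n"
    )
    return paths


_RUNNERS = {
    "scan2": _run_scan2,
    "scan3": _run_scan3,
    "ensemble": _run_ensemble,
    "forced": _run_forced,
}


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> list[Path]:
    """Dispatch a configuration to its driver; every output gets a sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = _RUNNERS[config.kind](config, outdir)
    sidecar = outdir / f"{config.kind}_provenance.json"
    write_sidecar(sidecar, config, [p.name for p in paths])
    return paths + [sidecar]


def trajectory_from_csv(csv_path: str | Path, spec_path: str | Path | None = None):
    """Rehydrate a stored trajectory (and optionally its community spec)."""
    df = pd.read_csv(csv_path)
    x_cols = [c for c in df.columns if c.startswith("X_")]
    traj = Trajectory(
        t=df["t"].to_numpy(),
        abundances=df[x_cols].to_numpy(),
        pH_f=df["pH_f"].to_numpy(),
        forcing=df["pH_in"].to_numpy() if "pH_in" in df.columns else None,
    )
    spec = None
    if spec_path is not None:
        payload = json.loads(Path(spec_path).read_text())
        spec = CommunitySpec.from_dict(payload.get("spec", payload))
    return traj, spec


def classify_stored(csv_path, spec_path, **kwargs) -> dict:
    """Re-classify a stored trajectory; returns a JSON-ready record."""
    traj, spec = trajectory_from_csv(csv_path, spec_path)
    c = classify_trajectory(traj, spec, **kwargs)
    return {
        "label": c.label,
        "survivors": c.survivors,
        "survivor_fraction": c.survivor_fraction,
        "per_species_amplitude": [float(a) for a in c.per_species_amplitude],
    }
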