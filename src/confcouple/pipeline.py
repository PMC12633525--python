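"""End-to-end pipeline: simulate → PCA → coupling → FES → reports.

A :class:`RunConfig` (flat key=value text file or JSON; unknown keys
rejected) drives a deterministic run whose outputs are CSV files with
floats at 9 significant digits, a serialized copy of the config, and a
manifest listing every produced file with its SHA-256 digest.  Running
twice with the same config and seed reproduces the outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling, essential_dynamics, synthetic, trajio

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]

log = logging.getLogger("confcouple")

FLOAT_FMT = "%.9g"


class ConfigError(ValueError):
    """Invalid or unknown run configuration."""


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    preset: str = "coupled-demo"
    topology: str | None = None  # PDB path (optional when simulating)
    trajectory: str | None = None  # frames-text path
    selection: str = "name CA"
    fit_selection: str | None = None
    n_modes: int = 10
    n_pcs: int = 10
    temperature: float = 310.0
    fes_bins: int = 100
    basin_depth_threshold: float = 0.5
    n_frames: int = 20_000
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.preset not in ("coupled-demo", "from-files"):
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.preset == "from-files":
            for key in ("topology", "trajectory"):
                path = getattr(self, key)
                if path is None:
                    raise ConfigError(f"preset 'from-files' requires {key}")
                if not Path(path).exists():
                    raise ConfigError(f"{key} path does not exist: {path}")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if self.fes_bins < 2:
            raise ConfigError("fes_bins must be >= 2")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")


_FIELD_TYPES = {
    "out_dir": str,
    "seed": int,
    "preset": str,
    "topology": str,
    "trajectory": str,
    "selection": str,
    "fit_selection": str,
    "n_modes": int,
    "n_pcs": int,
    "temperature": float,
    "fes_bins": int,
    "basin_depth_threshold": float,
    "n_frames": int,
    "log_level": str,
}


def load_config(path) -> RunConfig:
    """Load a config from JSON or flat ``key = value`` text."""
    text = Path(path).read_text()
    raw: dict[str, str]
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"bad config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key] = value
    return make_config(raw)


def make_config(raw: dict) -> RunConfig:
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError("config requires out_dir")
    kwargs = {}
    for key, value in raw.items():
        typ = _FIELD_TYPES[key]
        try:
            kwargs[key] = typ(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for {key!r}: {value!r}") from exc
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("START %s", self.name)
        return self

    def __exit__(self, *exc):
        log.info("END %s (%.2f s)", self.name, time.perf_counter() - self.t0)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the manifest dict.

    Raises :class:`ConfigError` for configuration problems; data-level
    failures propagate as their own exceptions (the CLI maps these to
    exit statuses 2 and 1).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    with _Stage("inputs"):
        if config.preset == "coupled-demo":
            params = synthetic.CoupledTrajectoryParams(
                n_frames=config.n_frames,
                pairs=[
                    synthetic.PairSpec(jump=10.0, d0=4.0),
                    synthetic.PairSpec(jump=-10.0, d0=14.0),
                ],
                seed=config.seed,
            )
            traj, truth = synthetic.generate_coupled_trajectory(params)
            pairs = truth.pair_members
            ring_rule = truth.ring_rule
            sel = trajio.select(traj.topology, config.selection)
        else:
            topology = trajio.read_structure(config.topology)
            traj = trajio.read_trajectory(topology, config.trajectory)
            truth = None
            ring_rule = coupling.DEFAULT_RING_ATOMS
            pairs = []
            sel = trajio.select(traj.topology, config.selection)

    with _Stage("pca"):
        fit_sel = (
            trajio.select(traj.topology, config.fit_selection)
            if config.fit_selection
            else None
        )
        # the synthetic preset plants no rigid-body diffusion; superposing
        # would eat part of the planted mode
        pca = essential_dynamics.compute_pca(
            traj,
            sel,
            align=(config.preset != "coupled-demo"),
            fit_selection=fit_sel,
        )
        n_modes = min(config.n_modes, pca.n_modes)
        eig = pd.DataFrame(
            {
                "mode": np.arange(1, n_modes + 1),
                "eigenvalue": pca.eigenvalues[:n_modes],
                "cumulative_fraction": np.cumsum(pca.variance_fractions())[
                    :n_modes
                ],
            }
        )
        _write_csv(eig, out / "eigenvalues.csv")
        produced.append(out / "eigenvalues.csv")

        profile = essential_dynamics.displacement_along_pc(pca, 1)
        top = traj.topology
        disp = pd.DataFrame(
            {
                "atom_index": list(sel.indices),
                "residue_number": [
                    top.atoms[i].residue_number for i in sel.indices
                ],
                "chain": [top.atoms[i].chain_id for i in sel.indices],
                "displacement": profile.displacements,
            }
        )
        _write_csv(disp, out / "displacement_pc1.csv")
        produced.append(out / "displacement_pc1.csv")

        proj = pd.DataFrame(
            pca.projections[:, :n_modes],
            columns=[f"PC{k}" for k in range(1, n_modes + 1)],
        )
        proj.insert(0, "frame", np.arange(traj.n_frames))
        _write_csv(proj, out / "projections.csv")
        produced.append(out / "projections.csv")

    series_list = []
    if pairs:
        with _Stage("coupling"):
            for a, b in pairs:
                series_list.append(
                    coupling.pair_distance_series(traj, a, b, ring_rule)
                )
            dist = pd.DataFrame({s.label: s.values for s in series_list})
            dist.insert(0, "frame", np.arange(traj.n_frames))
            _write_csv(dist, out / "distances.csv")
            produced.append(out / "distances.csv")

            corr = coupling.distance_pc_correlation(
                series_list, pca, n_pcs=config.n_pcs
            )
            corr_df = corr.r.reset_index(names="pair")
            _write_csv(corr_df, out / "correlations.csv")
            produced.append(out / "correlations.csv")

        with _Stage("fes"):
            basins_rows = []
            pc1 = pca.projections[:, 0]
            for s in series_list:
                fes = coupling.free_energy_surface(
                    pc1,
                    s.values,
                    n_bins=(config.fes_bins, config.fes_bins),
                    temperature=config.temperature,
                    x_label="PC1",
                    y_label=s.label,
                )
                name = s.label.replace(":", "_")
                _write_csv(fes.to_frame(), out / f"fes_pc1_{name}.csv")
                produced.append(out / f"fes_pc1_{name}.csv")
                for b in coupling.find_basins(
                    fes, config.basin_depth_threshold
                ):
                    basins_rows.append(
                        {
                            "surface": f"PC1 vs {s.label}",
                            "x_center": b.x_center,
                            "y_center": b.y_center,
                            "free_energy": b.free_energy,
                            "depth": b.depth,
                        }
                    )
            if len(series_list) >= 2:
                fes2 = coupling.free_energy_surface(
                    series_list[0],
                    series_list[1],
                    n_bins=(config.fes_bins, config.fes_bins),
                    temperature=config.temperature,
                )
                _write_csv(fes2.to_frame(), out / "fes_pair_pair.csv")
                produced.append(out / "fes_pair_pair.csv")
                score = coupling.compensation_score(
                    series_list[0], series_list[1]
                )
                pd.DataFrame(
                    [
                        {
                            "pair_a": series_list[0].label,
                            "pair_b": series_list[1].label,
                            "compensation_score": score,
                        }
                    ]
                ).to_csv(
                    out / "compensation.csv", index=False, float_format=FLOAT_FMT
                )
                produced.append(out / "compensation.csv")
            basins = pd.DataFrame(
                basins_rows,
                columns=["surface", "x_center", "y_center", "free_energy", "depth"],
            )
            _write_csv(basins, out / "basins.csv")
            produced.append(out / "basins.csv")

    with _Stage("manifest"):
        cfg_path = out / "config.json"
        cfg_path.write_text(json.dumps(asdict(config), indent=2, sort_keys=True))
        produced.append(cfg_path)
        manifest = {
            "files": {
                p.name: _sha256(p) for p in sorted(produced, key=lambda p: p.name)
            }
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return manifest
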