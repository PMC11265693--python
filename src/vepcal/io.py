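"""Plain-text file formats for problem bundles and run artifacts.

Conventions: matrices are whitespace-delimited text (connectome rows are
source regions, TVB ``weights.txt`` style); time series are TSV tables with
a leading ``time`` column; metadata travels as JSON.  Every writer records
enough provenance (seeds, configuration) to regenerate its input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmarks import ObservedDataset, ProblemSpec, EpileptogenicityMap
from .dynamics import NetworkModel, Trajectory
from .forward import GainMatrix, SensorSeries
from .optimizer import OptimizationResult, SolutionArchive

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "write_trajectory",
    "read_trajectory",
    "write_sensor_series",
    "read_sensor_series",
    "save_problem_dir",
    "load_problem_dir",
    "write_result",
    "read_result",
    "write_archive",
    "read_archive",
    "write_bands",
]


class MatrixParseError(ValueError):
    """Malformed delimited matrix file (reports the offending line)."""


def read_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited numeric matrix; errors name the line."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                raise MatrixParseError(
                    f"{path}: non-numeric token on line {lineno}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise MatrixParseError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(row)} columns, expected {width})")
            rows.append(row)
    if not rows:
        raise MatrixParseError(f"{path}: no numeric rows")
    return np.asarray(rows, dtype=float)


def write_matrix(matrix, path) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, float)), fmt="%.17g")


def write_trajectory(traj: Trajectory, path) -> None:
    cols = {"time": traj.times}
    for i in range(traj.n_regions):
        cols[f"x_{i}"] = traj.x[:, i]
    for i in range(traj.n_regions):
        cols[f"z_{i}"] = traj.z[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    xs = [c for c in df.columns if c.startswith("x_")]
    zs = [c for c in df.columns if c.startswith("z_")]
    return Trajectory(times=df["time"].to_numpy(),
                      x=df[xs].to_numpy(), z=df[zs].to_numpy())


def write_sensor_series(series: SensorSeries, path) -> None:
    cols = {"time": series.times}
    for i in range(series.n_channels):
        cols[f"s_{i}"] = series.values[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sensor_series(path) -> SensorSeries:
    df = pd.read_csv(path, sep="\t")
    chans = [c for c in df.columns if c.startswith("s_")]
    return SensorSeries(times=df["time"].to_numpy(), values=df[chans].to_numpy())


# ---------------------------------------------------------------------------
# problem bundles
# ---------------------------------------------------------------------------


def save_problem_dir(problem: ProblemSpec, observed: ObservedDataset,
                     out_dir, seed: int | None = None) -> Path:
    """Write a problem bundle: weights.txt, gain.txt, truth.json,
    observed.tsv and a flat problem.toml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(problem.model.connectome, out / "weights.txt")
    write_matrix(problem.gain.values, out / "gain.txt")
    truth = {
        "labels": problem.truth.labels.tolist(),
        "eta_true": problem.truth.eta_true.tolist(),
        "K_true": problem.K_true,
        "eta_c": problem.truth.eta_c,
        "delta_eta": problem.truth.delta_eta,
        "generator_seed": observed.generator_seed,
        "seed": seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    write_sensor_series(
        SensorSeries(times=observed.times, values=observed.series),
        out / "observed.tsv")
    cfg = {
        "problem_id": problem.problem_id,
        "observation_level": problem.observation_level,
        "coupling_regime": problem.coupling_regime,
        "stochastic": problem.stochastic,
        "n_regions": problem.n_regions,
        "n_sensors": problem.gain.n_sensors,
        "rank_deficient": problem.gain.rank_deficient,
        "coupling": problem.model.coupling,
        "timescale": problem.model.timescale,
        "current": problem.model.current,
        "dt": problem.model.dt,
        "x0": problem.model.x0z0[0],
        "z0": problem.model.x0z0[1],
        "noise_std": problem.model.noise_std,
        "obs_noise_std": problem.model.obs_noise_std,
        "duration": problem.duration,
        "stride": problem.stride,
        "cost_mode": problem.cost_mode,
        "eta_lower": float(problem.lower_bounds[0]),
        "eta_upper": float(problem.upper_bounds[0]),
        "K_lower": float(problem.lower_bounds[-1]),
        "K_upper": float(problem.upper_bounds[-1]),
    }
    with open(out / "problem.toml", "w") as fh:
        for k, v in cfg.items():
            if isinstance(v, bool):
                fh.write(f"{k} = {str(v).lower()}\n")
            elif isinstance(v, str):
                fh.write(f'{k} = "{v}"\n')
            else:
                fh.write(f"{k} = {v}\n")
    return out


def load_problem_dir(path) -> tuple[ProblemSpec, ObservedDataset]:
    import tomllib

    p = Path(path)
    cfg = tomllib.loads((p / "problem.toml").read_text())
    truth_d = json.loads((p / "truth.json").read_text())
    C = read_matrix(p / "weights.txt")
    G = read_matrix(p / "gain.txt")
    n = cfg["n_regions"]
    truth = EpileptogenicityMap(
        labels=np.asarray(truth_d["labels"]),
        eta_true=np.asarray(truth_d["eta_true"], float),
        eta_c=truth_d["eta_c"], delta_eta=truth_d["delta_eta"])
    model = NetworkModel(
        connectome=C, excitability=truth.eta_true.copy(),
        coupling=cfg["coupling"], timescale=cfg["timescale"],
        current=cfg["current"], dt=cfg["dt"], x0z0=(cfg["x0"], cfg["z0"]),
        noise_std=cfg["noise_std"], obs_noise_std=cfg["obs_noise_std"])
    gain = GainMatrix(values=G, rank_deficient=cfg["rank_deficient"])
    lb = np.concatenate([np.full(n, cfg["eta_lower"]), [cfg["K_lower"]]])
    ub = np.concatenate([np.full(n, cfg["eta_upper"]), [cfg["K_upper"]]])
    problem = ProblemSpec(
        problem_id=cfg["problem_id"],
        observation_level=cfg["observation_level"],
        coupling_regime=cfg["coupling_regime"], stochastic=cfg["stochastic"],
        model=model, gain=gain, truth=truth, K_true=truth_d["K_true"],
        duration=cfg["duration"], lower_bounds=lb, upper_bounds=ub,
        stride=cfg["stride"], cost_mode=cfg["cost_mode"])
    series = read_sensor_series(p / "observed.tsv")
    observed = ObservedDataset(
        level=cfg["observation_level"], times=series.times,
        series=series.values, generator_seed=truth_d["generator_seed"],
        problem_id=cfg["problem_id"])
    return problem, observed


# ---------------------------------------------------------------------------
# optimizer artifacts
# ---------------------------------------------------------------------------


def write_result(result: OptimizationResult, path, seed=None, extra=None) -> None:
    payload = {
        "best_theta": result.best_theta.tolist(),
        "best_cost": result.best_cost,
        "n_evals": result.n_evals,
        "trace": [[int(e), float(c)] for e, c in result.trace],
        "worker_stats": result.worker_stats,
        "seed": seed,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_result(path) -> dict:
    d = json.loads(Path(path).read_text())
    d["best_theta"] = np.asarray(d["best_theta"], float)
    return d


def write_archive(archive: SolutionArchive, path) -> None:
    archive.to_dataframe().to_csv(path, sep="\t", index=False,
                                  float_format="%.17g")


def read_archive(path) -> SolutionArchive:
    df = pd.read_csv(path, sep="\t")
    theta_cols = [c for c in df.columns if c.startswith("theta_")]
    theta_cols.sort(key=lambda c: int(c.split("_")[1]))
    return SolutionArchive.from_arrays(
        df[theta_cols].to_numpy(), df["cost"].to_numpy(),
        df["worker"].to_numpy(), df["eval_index"].to_numpy(),
        df["eval_seed"].to_numpy())


def write_bands(summaries, path) -> None:
    rows = []
    for s in summaries:
        for p, v in zip(s.percentiles, s.band_values):
            rows.append({"parameter": s.parameter_index, "percentile": p,
                         "value": v, "n_members": s.n_members})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")
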