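"""Synthetic ground truth and the six benchmark estimation problems.

The benchmark grid crosses three factors:

* coupling regime — weak (no seizure recruitment) vs strong (propagating);
* observation level — source (gain = identity) vs sensor (rank-deficient
  SEEG gain);
* dynamics — deterministic ODE vs stochastic SDE with a large timescale
  separation (long seizure envelope) and process-noise std 0.1.

Problem ids: 1/2 weak det source/sensor, 3/4 strong det source/sensor,
5/6 strong stochastic source/sensor.  The estimation target is
theta = (eta_1..eta_N, K), an (N+1)-vector, scored by the RMSE between the
observed series and a fresh forward simulation under theta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .dynamics import NetworkModel, simulate_ode, simulate_sde
from .forward import GainMatrix, SensorGeometry, build_gain_matrix, project_to_sensors, seeg_envelope, SensorSeries
from .evaluation import classify_regions

__all__ = [
    "ETA_C",
    "DELTA_ETA",
    "EpileptogenicityMap",
    "ProblemSpec",
    "ObservedDataset",
    "synth_connectome",
    "synth_truth_map",
    "synth_geometry",
    "make_problem",
    "make_cost_function",
    "cost_rmse",
]

ETA_C = -2.05
DELTA_ETA = 1.0

#: per-problem configuration: (level, coupling regime, stochastic)
_PROBLEM_TABLE = {
    1: ("source", "weak", False),
    2: ("sensor", "weak", False),
    3: ("source", "strong", False),
    4: ("sensor", "strong", False),
    5: ("source", "strong", True),
    6: ("sensor", "strong", True),
}

# study conditions not printed in the benchmark table; all overridable
K_WEAK = 0.1
K_STRONG = 1.0
TAU_DEFAULT = 10.0
TAU_STIFF = 90.0
SIGMA_STOCHASTIC = 0.1
DURATION_DET = 100.0
DURATION_STOCH = 900.0
OBS_STRIDE = 10
ETA_BOUNDS = (-5.0, -1.0)
K_BOUNDS = (0.0, 2.0)
EZ_BAND = (-1.9, -1.5)
PZ_BAND = (-2.4, -2.1)
HZ_BAND = (-3.8, -3.2)


@dataclass
class EpileptogenicityMap:
    """Ground-truth spatial map of excitability with EZ/PZ/HZ labels."""

    labels: np.ndarray
    eta_true: np.ndarray
    eta_c: float = ETA_C
    delta_eta: float = DELTA_ETA

    def __post_init__(self):
        self.eta_true = np.asarray(self.eta_true, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.delta_eta <= 0:
            raise ValueError("delta_eta must be positive (band misconfiguration)")
        expected = classify_regions(self.eta_true, self.eta_c, self.delta_eta)
        if not np.array_equal(expected, self.labels):
            raise ValueError("labels inconsistent with eta_true and thresholds")

    @classmethod
    def from_eta(cls, eta_true, eta_c: float = ETA_C, delta_eta: float = DELTA_ETA):
        eta_true = np.asarray(eta_true, dtype=float)
        return cls(labels=classify_regions(eta_true, eta_c, delta_eta),
                   eta_true=eta_true, eta_c=eta_c, delta_eta=delta_eta)

    @property
    def n_regions(self) -> int:
        return self.eta_true.shape[0]


@dataclass
class ProblemSpec:
    """One benchmark estimation problem (model, gain, truth, bounds)."""

    problem_id: int
    observation_level: str
    coupling_regime: str
    stochastic: bool
    model: NetworkModel
    gain: GainMatrix
    truth: EpileptogenicityMap
    K_true: float
    duration: float
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    stride: int = OBS_STRIDE
    cost_mode: str = "raw"
    envelope_window: int = 101

    @property
    def n_regions(self) -> int:
        return self.model.n_regions

    @property
    def n_params(self) -> int:
        return self.n_regions + 1

    @property
    def theta_true(self) -> np.ndarray:
        return np.concatenate([self.truth.eta_true, [self.K_true]])

    @property
    def bounds(self):
        return self.lower_bounds, self.upper_bounds


@dataclass
class ObservedDataset:
    """The (fixed) observation a problem is calibrated against."""

    level: str
    times: np.ndarray
    series: np.ndarray  # (T, M): M = N_n at source level, N_s at sensor level
    generator_seed: int
    problem_id: int

    def __post_init__(self):
        self.series = np.atleast_2d(np.asarray(self.series, float))
        if not np.all(np.isfinite(self.series)):
            raise ValueError("observed series contains non-finite values")


# ---------------------------------------------------------------------------
# synthesizers
# ---------------------------------------------------------------------------


def _child_seeds(seed: int, problem_id: int, n_regions: int, n: int):
    ss = np.random.SeedSequence([int(seed), int(problem_id), int(n_regions)])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def synth_connectome(n_regions: int, seed: int) -> np.ndarray:
    """Symmetric heavy-tailed (log-normal) connectome, zero diagonal,
    rescaled so the maximum entry is exactly 1."""
    if n_regions < 2:
        raise ValueError("a connectome needs at least 2 regions")
    rng = np.random.default_rng(seed)
    W = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    W[iu] = rng.lognormal(mean=0.0, sigma=2.5, size=len(iu[0]))
    W = W + W.T
    W /= W.max()
    return W


def synth_truth_map(n_regions: int, n_ez: int = 2, n_pz: int = 3,
                    seed: int = 0, eta_c: float = ETA_C,
                    delta_eta: float = DELTA_ETA,
                    connectome: np.ndarray | None = None) -> EpileptogenicityMap:
    """Randomly placed epileptogenicity map.

    EZ excitabilities are drawn in [-1.9, -1.5], PZ in [-2.4, -2.1] and HZ in
    [-3.8, -3.2]; the bands keep a safety margin from both class thresholds.
    EZ regions are placed at random.  When a connectome is supplied, the PZ
    regions are the ones most strongly connected to the EZ set — the
    structural pathways along which a seizure can actually propagate, which
    is how propagation-zone candidates are defined clinically; otherwise
    they are random too.
    """
    if delta_eta <= 0:
        raise ValueError("delta_eta must be positive (band misconfiguration)")
    if n_ez + n_pz > n_regions:
        raise ValueError("n_ez + n_pz exceeds n_regions")
    rng = np.random.default_rng(seed)
    eta = rng.uniform(*HZ_BAND, size=n_regions)
    if connectome is None:
        special = rng.choice(n_regions, size=n_ez + n_pz, replace=False)
        ez_idx = special[:n_ez]
        pz_idx = special[n_ez:]
    else:
        ez_idx = rng.choice(n_regions, size=n_ez, replace=False)
        weight_to_ez = connectome[:, ez_idx].sum(axis=1)
        weight_to_ez[ez_idx] = -np.inf
        pz_idx = np.argsort(weight_to_ez)[::-1][:n_pz]
    eta[ez_idx] = rng.uniform(*EZ_BAND, size=n_ez)
    eta[pz_idx] = rng.uniform(*PZ_BAND, size=n_pz)
    return EpileptogenicityMap.from_eta(eta, eta_c, delta_eta)


def synth_geometry(n_regions: int, n_sensors: int, seed: int,
                   vertices_per_region: int = 3) -> SensorGeometry:
    """Random implantation geometry emulating a depth-electrode montage.

    Region vertex clouds live in a 100 mm head sphere.  Each contact is
    implanted close (4--12 mm) to one region's centre, cycling through a
    random permutation of regions, the way SEEG electrodes target candidate
    tissue; near-field dominance of the closest source gives the gain
    matrix well-differentiated columns while regions without a nearby
    contact remain only weakly observed.  Contacts keep >= 3 mm from any
    vertex (no degenerate zero-distance gain).
    """
    rng = np.random.default_rng(seed)

    def _in_ball(n, radius):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * rng.uniform(0.3, 1.0, size=(n, 1)) ** (1 / 3)
        return v * r

    centers = _in_ball(n_regions, 50.0)
    region_vertices = []
    all_vertices = []
    for c in centers:
        pos = c + rng.normal(scale=3.0, size=(vertices_per_region, 3))
        areas = rng.uniform(5.0, 15.0, size=vertices_per_region)
        region_vertices.append((pos, areas))
        all_vertices.append(pos)
    all_vertices = np.vstack(all_vertices)

    targets = rng.permutation(n_regions)
    sensors = np.empty((n_sensors, 3))
    for i in range(n_sensors):
        c = centers[targets[i % n_regions]]
        for _ in range(200):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            p = c + d * rng.uniform(5.0, 20.0)
            if np.min(np.linalg.norm(all_vertices - p, axis=1)) >= 3.0:
                sensors[i] = p
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place a sensor away from vertices")
    return SensorGeometry(sensor_positions=sensors,
                          region_vertices=region_vertices, scale_c=1.0)


def make_problem(problem_id: int, n_regions: int = 84, seed: int = 0,
                 n_ez: int = 2, n_pz: int = 3, n_sensors: int | None = None,
                 duration: float | None = None, K: float | None = None,
                 tau: float | None = None, noise_std: float | None = None,
                 stride: int = OBS_STRIDE, cost_mode: str = "raw",
                 eta_c: float = ETA_C, delta_eta: float = DELTA_ETA):
    """Build one of the six benchmark problems and its fixed observation.

    The triple (problem_id, n_regions, seed) fully determines the returned
    dataset; stochastic observations record the seed they were generated
    with so they never change afterwards.
    """
    if problem_id not in _PROBLEM_TABLE:
        raise ValueError(f"problem_id must be 1..6, got {problem_id}")
    level, regime, stochastic = _PROBLEM_TABLE[problem_id]
    s_conn, s_truth, s_geom, s_obs = _child_seeds(seed, problem_id, n_regions, 4)

    C = synth_connectome(n_regions, s_conn)
    truth = synth_truth_map(n_regions, n_ez=n_ez, n_pz=n_pz, seed=s_truth,
                            eta_c=eta_c, delta_eta=delta_eta, connectome=C)
    if K is None:
        K = K_WEAK if regime == "weak" else K_STRONG
    if tau is None:
        tau = TAU_STIFF if stochastic else TAU_DEFAULT
    if noise_std is None:
        noise_std = SIGMA_STOCHASTIC if stochastic else 0.0
    if duration is None:
        duration = DURATION_STOCH if stochastic else DURATION_DET

    model = NetworkModel(connectome=C, excitability=truth.eta_true.copy(),
                         coupling=float(K), timescale=float(tau),
                         noise_std=float(noise_std))

    if level == "sensor":
        if n_sensors is None:
            # keep N_s < N_n (rank-deficient gain), ~60 sensors per 84 regions
            n_sensors = max(2, int(round(n_regions * 60 / 84)))
        geometry = synth_geometry(n_regions, n_sensors, s_geom)
        gain = build_gain_matrix(geometry)
    else:
        gain = GainMatrix.identity(n_regions)

    if stochastic:
        traj = simulate_sde(model, duration, seed=s_obs)
    else:
        traj = simulate_ode(model, duration)
    sens = project_to_sensors(traj, gain, obs_noise_std=model.obs_noise_std,
                              seed=s_obs + 1)
    times = sens.times[::stride]
    series = sens.values[::stride]

    lb = np.concatenate([np.full(n_regions, ETA_BOUNDS[0]), [K_BOUNDS[0]]])
    ub = np.concatenate([np.full(n_regions, ETA_BOUNDS[1]), [K_BOUNDS[1]]])

    problem = ProblemSpec(
        problem_id=problem_id, observation_level=level,
        coupling_regime=regime, stochastic=stochastic, model=model,
        gain=gain, truth=truth, K_true=float(K), duration=float(duration),
        lower_bounds=lb, upper_bounds=ub, stride=stride, cost_mode=cost_mode)
    observed = ObservedDataset(level=level, times=times, series=series,
                               generator_seed=s_obs, problem_id=problem_id)
    return problem, observed


# ---------------------------------------------------------------------------
# RMSE cost
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _rmse_kernel(C, rowsum, eta, K, tau, I, dt, n_steps, stride,
                 x_init, z_init, G, obs, sigma, seed):
    """Integrate under theta and accumulate squared error against ``obs``
    at every ``stride``-th step, without storing the trajectory.

    Returns +inf if the integration blows up.  This is the optimizer's hot
    path (one call per cost evaluation), hence fastmath and hand-written
    matvecs; agreement with the exact trajectory kernel that generates the
    observations is at machine-epsilon level over the benchmark horizons
    (limit-cycle dynamics: rounding perturbations grow only linearly).
    """
    n = eta.shape[0]
    m = G.shape[0]
    x = x_init.copy()
    z = z_init.copy()
    if sigma > 0.0:
        np.random.seed(seed)
    inv_tau = 1.0 / tau
    sq = math.sqrt(dt)
    noisy = sigma > 0.0
    coupled = K != 0.0
    cx = np.zeros(n)
    xn = np.empty(n)
    zn = np.empty(n)
    ex = np.empty(n)
    acc = 0.0
    count = 0
    row = 0
    # step 0 is recorded
    for j in range(n):
        ex[j] = math.exp(x[j])
    for i in range(m):
        s = 0.0
        for j in range(n):
            s += G[i, j] * ex[j]
        d = s - obs[row, i]
        acc += d * d
    count += m
    row += 1
    for t in range(1, n_steps + 1):
        if coupled:
            for i in range(n):
                s = 0.0
                for j in range(n):
                    s += C[i, j] * x[j]
                cx[i] = s
        for i in range(n):
            xi = x[i]
            zi = z[i]
            dx = 1.0 - xi * xi * xi - 2.0 * xi * xi - zi + I
            coup = cx[i] - rowsum[i] * xi if coupled else 0.0
            dz = (4.0 * (xi - eta[i]) - zi - K * coup) * inv_tau
            xv = xi + dt * dx
            zv = zi + dt * dz
            if noisy:
                xv += sigma * sq * np.random.normal()
                zv += sigma * sq * np.random.normal()
            if abs(xv) > 1e6 or abs(zv) > 1e6 or xv != xv or zv != zv:
                return np.inf
            xn[i] = xv
            zn[i] = zv
        for i in range(n):
            x[i] = xn[i]
            z[i] = zn[i]
        if t % stride == 0 and row < obs.shape[0]:
            for j in range(n):
                ex[j] = math.exp(x[j])
            for i in range(m):
                s = 0.0
                for j in range(n):
                    s += G[i, j] * ex[j]
                d = s - obs[row, i]
                acc += d * d
            count += m
            row += 1
    return math.sqrt(acc / count)


def make_cost_function(problem: ProblemSpec, observed: ObservedDataset):
    """Fast closure ``f(theta, eval_seed=0) -> rmse`` for the optimizer.

    theta = (eta_1..eta_N, K), clipped to the problem bounds.  Deterministic
    problems ignore ``eval_seed``; stochastic ones draw fresh process noise
    from it, making the cost function itself stochastic.
    """
    model = problem.model
    C = np.ascontiguousarray(model.connectome)
    rowsum = C.sum(axis=1)
    G = np.ascontiguousarray(problem.gain.values)
    obs = np.ascontiguousarray(observed.series)
    n = problem.n_regions
    n_steps = int(math.floor(problem.duration / model.dt))
    x_init = np.full(n, model.x0z0[0])
    z_init = np.full(n, model.x0z0[1])
    sigma = float(model.noise_std)
    tau = float(model.timescale)
    I = float(model.current)
    dt = float(model.dt)
    stride = int(problem.stride)
    lb, ub = problem.lower_bounds, problem.upper_bounds
    if problem.cost_mode not in ("raw", "envelope"):
        raise ValueError(f"unknown cost_mode {problem.cost_mode!r}")
    if problem.cost_mode == "envelope":
        env_obs = seeg_envelope(
            SensorSeries(times=observed.times, values=obs),
            problem.envelope_window).values

        def cost(theta, eval_seed: int = 0) -> float:
            theta = np.clip(np.asarray(theta, float), lb, ub)
            sim = _simulate_series(problem, theta, eval_seed)
            if sim is None:
                return np.inf
            env_sim = seeg_envelope(
                SensorSeries(times=observed.times, values=sim),
                problem.envelope_window).values
            return float(np.sqrt(np.mean((env_sim - env_obs) ** 2)))

        return cost

    def cost(theta, eval_seed: int = 0) -> float:
        theta = np.clip(np.asarray(theta, float), lb, ub)
        return float(_rmse_kernel(
            C, rowsum, theta[:n], float(theta[n]), tau, I, dt, n_steps,
            stride, x_init, z_init, G, obs, sigma, int(eval_seed) & 0x7FFFFFFF))

    return cost


def _simulate_series(problem: ProblemSpec, theta, eval_seed: int):
    """Forward-simulate under theta and return the downsampled observation-
    level series (None if the integration diverges)."""
    from .dynamics import IntegrationDivergedError

    n = problem.n_regions
    model = NetworkModel(
        connectome=problem.model.connectome, excitability=np.asarray(theta[:n]),
        coupling=float(theta[n]), timescale=problem.model.timescale,
        current=problem.model.current, dt=problem.model.dt,
        x0z0=problem.model.x0z0, noise_std=problem.model.noise_std)
    try:
        if problem.stochastic:
            traj = simulate_sde(model, problem.duration, seed=eval_seed)
        else:
            traj = simulate_ode(model, problem.duration)
    except IntegrationDivergedError:
        return None
    sens = project_to_sensors(traj, problem.gain)
    return sens.values[::problem.stride]


def cost_rmse(theta, problem: ProblemSpec, observed: ObservedDataset,
              eval_seed: int = 0) -> float:
    """RMSE between the observation and a forward simulation under theta."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (problem.n_params,):
        raise ValueError(
            f"theta must have shape ({problem.n_params},), got {theta.shape}")
    lb, ub = problem.bounds
    if np.any(theta < lb) or np.any(theta > ub):
        warnings.warn("theta outside bounds; clamping", RuntimeWarning)
    return make_cost_function(problem, observed)(theta, eval_seed)
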