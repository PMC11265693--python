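"""2D reduced Epileptor network dynamics.

Each brain region carries a fast variable ``x`` (seizure discharges) and a
slow permittivity variable ``z``.  Regions are coupled diffusively through a
structural connectome ``C`` scaled by a global coupling constant ``K``:

    dx_i/dt = 1 - x_i^3 - 2 x_i^2 - z_i + I
    dz_i/dt = (1/tau) * (4 (x_i - eta_i) - z_i - K * sum_j C_ij (x_j - x_i))

``eta_i`` is the per-region excitability (Hopf bifurcation parameter): an
isolated node with ``eta`` above the critical value ``eta_c`` has no stable
fixed point and seizes autonomously.  Integration is forward Euler (or
Euler--Maruyama when process noise is present) with a fixed step ``dt`` in
dimensionless model time units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "NetworkModel",
    "Trajectory",
    "FixedPoint",
    "StabilityReport",
    "IntegrationDivergedError",
    "NoBifurcationError",
    "drift",
    "simulate_ode",
    "simulate_sde",
    "isolated_fixed_points",
    "critical_excitability",
]

#: guard against numerical blow-up: integration aborts past this magnitude
BLOWUP_LIMIT = 1e6


class IntegrationDivergedError(RuntimeError):
    """Raised when the Euler integration produces a non-finite/huge state."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"integration diverged at step {step}")


class NoBifurcationError(ValueError):
    """Raised when an excitability sweep never crosses a stability change."""


@dataclass
class NetworkModel:
    """Parameters of the coupled 2D Epileptor network.

    Parameters
    ----------
    connectome : (N, N) array
        Non-negative structural connectivity, row = source region.  The
        synthesizer normalizes it so the maximum entry is exactly 1.
    excitability : (N,) array
        Per-region excitability ``eta_i``.
    coupling : float
        Global coupling gain ``K`` (>= 0).
    timescale : float
        Slow-variable time constant ``tau`` (> 0); large values stretch the
        seizure envelope.
    current : float
        Constant input current ``I`` (default 3.1).
    dt : float
        Euler step in model time units (default 0.1).
    x0z0 : (float, float)
        Initial condition applied to every region (default (-2.5, 3.5)).
    noise_std : float
        Process-noise standard deviation ``sigma`` (0 => deterministic ODE).
    obs_noise_std : float
        Measurement-noise standard deviation ``sigma'`` used by the forward
        projection (kept here so a model fully specifies the state-space).
    noise_scale : (float, float)
        Optional per-equation scaling of the process noise applied to the
        x and z equations respectively (default equal).
    """

    connectome: np.ndarray
    excitability: np.ndarray
    coupling: float = 0.0
    timescale: float = 10.0
    current: float = 3.1
    dt: float = 0.1
    x0z0: tuple[float, float] = (-2.5, 3.5)
    noise_std: float = 0.0
    obs_noise_std: float = 0.0
    noise_scale: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.connectome = np.ascontiguousarray(self.connectome, dtype=np.float64)
        self.excitability = np.ascontiguousarray(self.excitability, dtype=np.float64)
        C, eta = self.connectome, self.excitability
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"connectome must be square, got shape {C.shape}")
        if eta.ndim != 1 or eta.shape[0] != C.shape[0]:
            raise ValueError(
                f"excitability length {eta.shape} does not match connectome {C.shape}"
            )
        if np.any(C < 0):
            raise ValueError("connectome entries must be non-negative")
        if self.coupling < 0:
            raise ValueError("coupling K must be non-negative")
        if self.timescale <= 0:
            raise ValueError("timescale tau must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_std < 0 or self.obs_noise_std < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.excitability.shape[0]


@dataclass
class Trajectory:
    """Uniformly sampled state trajectory of the network."""

    times: np.ndarray
    x: np.ndarray  # (T, N) fast variable
    z: np.ndarray  # (T, N) slow variable

    def __post_init__(self):
        if self.x.shape != self.z.shape:
            raise ValueError("x and z must share shape")
        if self.times.shape[0] != self.x.shape[0]:
            raise ValueError("times length must match trajectory length")

    @property
    def n_regions(self) -> int:
        return self.x.shape[1]


@dataclass
class FixedPoint:
    x: float
    z: float
    stable: bool
    trace: float
    det: float


@dataclass
class StabilityReport:
    """Fixed points of an isolated node and their linear stability."""

    fixed_points: list[FixedPoint] = field(default_factory=list)

    @property
    def has_stable(self) -> bool:
        return any(fp.stable for fp in self.fixed_points)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate_kernel(C, rowsum, eta, K, tau, I, dt, n_steps,
                      x_init, z_init, sigma_x, sigma_z, seed, use_noise):
    """Forward Euler / Euler--Maruyama integration storing every step.

    Returns (x_out, z_out, diverged_step); diverged_step is -1 on success.
    The coupling term is skipped entirely when K == 0 so that a decoupled
    network is arithmetically identical to independent single-node runs.
    """
    n = eta.shape[0]
    x_out = np.empty((n_steps + 1, n))
    z_out = np.empty((n_steps + 1, n))
    x = x_init.copy()
    z = z_init.copy()
    x_out[0] = x
    z_out[0] = z
    if use_noise:
        np.random.seed(seed)
    sq = math.sqrt(dt)
    coupled = K != 0.0
    cx = np.zeros(n)
    for t in range(1, n_steps + 1):
        if coupled:
            cx = C @ x
        for i in range(n):
            xi = x[i]
            zi = z[i]
            dx = 1.0 - xi * xi * xi - 2.0 * xi * xi - zi + I
            if coupled:
                coup = cx[i] - rowsum[i] * xi
            else:
                coup = 0.0
            dz = (4.0 * (xi - eta[i]) - zi - K * coup) / tau
            xn = xi + dt * dx
            zn = zi + dt * dz
            if use_noise:
                if sigma_x > 0.0:
                    xn += sigma_x * sq * np.random.normal()
                if sigma_z > 0.0:
                    zn += sigma_z * sq * np.random.normal()
            if not (math.isfinite(xn) and math.isfinite(zn)) or \
                    abs(xn) > BLOWUP_LIMIT or abs(zn) > BLOWUP_LIMIT:
                return x_out, z_out, t
            x_out[t, i] = xn
            z_out[t, i] = zn
        x = x_out[t]
        z = z_out[t]
    return x_out, z_out, -1


@njit(cache=True)
def _drift_kernel(x, z, C, rowsum, eta, K, tau, I):
    n = x.shape[0]
    dx = np.empty(n)
    dz = np.empty(n)
    coupled = K != 0.0
    cx = np.zeros(n)
    if coupled:
        cx = C @ x
    for i in range(n):
        xi = x[i]
        dx[i] = 1.0 - xi * xi * xi - 2.0 * xi * xi - z[i] + I
        coup = cx[i] - rowsum[i] * xi if coupled else 0.0
        dz[i] = (4.0 * (xi - eta[i]) - z[i] - K * coup) / tau
    return dx, dz


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def drift(x: np.ndarray, z: np.ndarray, model: NetworkModel):
    """Deterministic vector field (dx, dz) at state (x, z)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    z = np.ascontiguousarray(z, dtype=np.float64)
    n = model.n_regions
    if x.shape != (n,) or z.shape != (n,):
        raise ValueError(
            f"state vectors must have shape ({n},), got {x.shape} and {z.shape}"
        )
    rowsum = model.connectome.sum(axis=1)
    return _drift_kernel(x, z, model.connectome, rowsum, model.excitability,
                         float(model.coupling), float(model.timescale),
                         float(model.current))


def _run(model: NetworkModel, duration: float, seed: int, use_noise: bool) -> Trajectory:
    if duration < model.dt:
        raise ValueError("duration must be at least one time step")
    n_steps = int(math.floor(duration / model.dt))
    n = model.n_regions
    x_init = np.full(n, model.x0z0[0])
    z_init = np.full(n, model.x0z0[1])
    rowsum = model.connectome.sum(axis=1)
    sx = model.noise_std * model.noise_scale[0]
    sz = model.noise_std * model.noise_scale[1]
    x, z, bad = _integrate_kernel(
        model.connectome, rowsum, model.excitability,
        float(model.coupling), float(model.timescale), float(model.current),
        float(model.dt), n_steps, x_init, z_init,
        float(sx), float(sz), int(seed) & 0x7FFFFFFF, use_noise)
    if bad >= 0:
        raise IntegrationDivergedError(bad)
    times = np.arange(n_steps + 1) * model.dt
    return Trajectory(times=times, x=x, z=z)


def simulate_ode(model: NetworkModel, duration: float) -> Trajectory:
    """Deterministic forward-Euler trajectory from the model's initial state."""
    if model.noise_std != 0:
        raise ValueError("simulate_ode requires noise_std == 0; use simulate_sde")
    return _run(model, duration, seed=0, use_noise=False)


def simulate_sde(model: NetworkModel, duration: float, seed: int) -> Trajectory:
    """Euler--Maruyama trajectory; additive Gaussian noise on both equations.

    With ``noise_std == 0`` the result is bitwise identical to
    :func:`simulate_ode` (the noise branch is never taken).
    """
    return _run(model, duration, seed=seed, use_noise=True)


def isolated_fixed_points(eta: float, I: float = 3.1, tau: float = 10.0) -> StabilityReport:
    """Fixed points of an isolated node (K = 0) and their stability.

    A fixed point solves ``1 - x^3 - 2x^2 + I - 4(x - eta) = 0`` with
    ``z* = 4(x* - eta)``.  Stability comes from the eigenvalues of the
    2x2 Jacobian ``[[-3x^2 - 4x, -1], [4/tau, -1/tau]]``; a marginal point
    (|trace| < 1e-9, det > 0) is labeled unstable, breaking the tie toward
    seizure onset.
    """
    if not (math.isfinite(eta) and math.isfinite(I)):
        raise ValueError("eta and I must be finite")
    # x^3 + 2x^2 + 4x - (1 + I + 4 eta) = 0
    roots = np.roots([1.0, 2.0, 4.0, -(1.0 + I + 4.0 * eta)])
    report = StabilityReport()
    for r in roots:
        if abs(r.imag) > 1e-7:
            continue
        xs = float(r.real)
        # polish by Newton on the cubic to meet the 1e-9 residual contract
        for _ in range(8):
            f = xs**3 + 2.0 * xs**2 + 4.0 * xs - (1.0 + I + 4.0 * eta)
            fp = 3.0 * xs**2 + 4.0 * xs + 4.0
            step = f / fp
            xs -= step
            if abs(step) < 1e-14:
                break
        zs = 4.0 * (xs - eta)
        a = -3.0 * xs**2 - 4.0 * xs
        J = np.array([[a, -1.0], [4.0 / tau, -1.0 / tau]])
        tr = float(np.trace(J))
        det = float(np.linalg.det(J))
        eig_real_max = float(np.max(np.linalg.eigvals(J).real))
        stable = eig_real_max < 0 and not (abs(tr) < 1e-9)
        report.fixed_points.append(FixedPoint(x=xs, z=zs, stable=stable,
                                              trace=tr, det=det))
    report.fixed_points.sort(key=lambda fp: fp.x)
    return report


def critical_excitability(model_template: NetworkModel, eta_grid: np.ndarray) -> float:
    """Critical excitability ``eta_c`` of an isolated node.

    Scans ``eta_grid`` (ascending) for the loss of the stable fixed point and
    refines the bracket by bisection to 1e-3.  The template must have K = 0;
    its ``timescale`` and ``current`` are used for the stability analysis.
    """
    if model_template.coupling != 0:
        raise ValueError("critical_excitability requires an uncoupled model (K = 0)")
    eta_grid = np.asarray(eta_grid, dtype=float)
    if eta_grid.ndim != 1 or eta_grid.size < 2 or np.any(np.diff(eta_grid) <= 0):
        raise ValueError("eta_grid must be a sorted ascending vector")
    tau = model_template.timescale
    I = model_template.current

    def stable_at(eta):
        return isolated_fixed_points(eta, I=I, tau=tau).has_stable

    flags = [stable_at(e) for e in eta_grid]
    lo = hi = None
    for k in range(1, len(flags)):
        if flags[k - 1] and not flags[k]:
            lo, hi = eta_grid[k - 1], eta_grid[k]
            break
    if lo is None:
        raise NoBifurcationError(
            "eta_grid does not bracket a loss of stability; widen the grid")
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        if stable_at(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
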