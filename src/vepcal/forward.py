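"""SEEG forward problem: gain matrices and source-to-sensor projection.

A depth-electrode sensor picks up activity from every region, weighted by an
inverse-square distance law over the region's surface vertices:

    G_ij = sum_{k in V_j} c * A_k / |x_i^s - x_k^v|^2

and the measurable signal is an exponential transform of the fast variable,

    S_i(t) = sum_j G_ij exp(x_j(t))  (+ Gaussian measurement noise).

Orientation-dependent decay is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SensorGeometry",
    "GainMatrix",
    "SensorSeries",
    "DegenerateGeometryError",
    "build_gain_matrix",
    "project_to_sensors",
    "seeg_envelope",
]


class DegenerateGeometryError(ValueError):
    """A sensor coincides with a source vertex (zero distance)."""


@dataclass
class SensorGeometry:
    """Sensor positions plus per-region vertex sets.

    ``region_vertices[j]`` is a pair ``(positions, areas)`` with positions of
    shape (V_j, 3) in mm and positive areas in mm^2.  ``scale_c`` is the
    global gain scaling coefficient.
    """

    sensor_positions: np.ndarray
    region_vertices: list[tuple[np.ndarray, np.ndarray]]
    scale_c: float = 1.0

    def __post_init__(self):
        self.sensor_positions = np.atleast_2d(np.asarray(self.sensor_positions, float))
        if self.sensor_positions.shape[0] < 1 or self.sensor_positions.shape[1] != 3:
            raise ValueError("sensor_positions must be (N_s, 3) with N_s >= 1")
        if self.scale_c <= 0:
            raise ValueError("scale_c must be positive")
        clean = []
        for j, (pos, areas) in enumerate(self.region_vertices):
            pos = np.atleast_2d(np.asarray(pos, float))
            areas = np.atleast_1d(np.asarray(areas, float))
            if pos.shape[0] < 1:
                raise ValueError(f"region {j} has no vertices")
            if np.any(areas <= 0):
                raise ValueError(f"region {j} has non-positive vertex areas")
            if pos.shape[0] != areas.shape[0]:
                raise ValueError(f"region {j}: vertex/area count mismatch")
            clean.append((pos, areas))
        self.region_vertices = clean

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_vertices)


@dataclass
class GainMatrix:
    """Lead-field matrix mapping N_n region sources to N_s sensors."""

    values: np.ndarray
    rank_deficient: bool = False

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if np.any(self.values < 0):
            raise ValueError("gain entries must be non-negative")

    @classmethod
    def identity(cls, n: int) -> "GainMatrix":
        return cls(values=np.eye(n), rank_deficient=False)

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class SensorSeries:
    """Multichannel sensor time series on a uniform grid."""

    times: np.ndarray
    values: np.ndarray  # (T, N_s)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times length must match series length")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def build_gain_matrix(geometry: SensorGeometry) -> GainMatrix:
    """Inverse-square-law gain from sensor/vertex geometry.

    Flags the result rank-deficient when rank(G) < N_n, the identifiability
    obstacle characteristic of sparse SEEG implantations.
    """
    ns, nn = geometry.n_sensors, geometry.n_regions
    G = np.zeros((ns, nn))
    for j, (pos, areas) in enumerate(geometry.region_vertices):
        # (N_s, V_j) squared distances
        d2 = np.sum(
            (geometry.sensor_positions[:, None, :] - pos[None, :, :]) ** 2, axis=2
        )
        if np.any(d2 == 0):
            i, k = np.argwhere(d2 == 0)[0]
            raise DegenerateGeometryError(
                f"sensor {i} coincides with vertex {k} of region {j}")
        G[:, j] = geometry.scale_c * np.sum(areas[None, :] / d2, axis=1)
    rank = np.linalg.matrix_rank(G)
    return GainMatrix(values=G, rank_deficient=bool(rank < nn))


def project_to_sensors(traj, gain: GainMatrix, obs_noise_std: float = 0.0,
                       seed: int | None = None) -> SensorSeries:
    """Project a source trajectory to SEEG sensors: S = exp(x) @ G.T.

    Adds zero-mean Gaussian measurement noise of std ``obs_noise_std`` when
    positive (seeded); with zero noise the projection is deterministic.
    """
    if gain.n_regions != traj.x.shape[1]:
        raise ValueError(
            f"gain has {gain.n_regions} regions but trajectory has {traj.x.shape[1]}")
    S = np.exp(traj.x) @ gain.values.T
    if obs_noise_std > 0:
        rng = np.random.default_rng(seed)
        S = S + rng.normal(0.0, obs_noise_std, size=S.shape)
    return SensorSeries(times=np.asarray(traj.times).copy(), values=S)


def seeg_envelope(series: SensorSeries, window: int) -> SensorSeries:
    """Sliding-window RMS envelope of the mean-removed signal.

    Centered window of ``window`` samples, truncated at the edges; output on
    the same time grid.  Used for visualization and as an optional cost
    preprocessing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    T = series.values.shape[0]
    if window > T:
        raise ValueError(f"window {window} exceeds series length {T}")
    centered = series.values - series.values.mean(axis=0, keepdims=True)
    sq = pd.DataFrame(centered ** 2)
    env = np.sqrt(sq.rolling(window, center=True, min_periods=1).mean().to_numpy())
    return SensorSeries(times=series.times.copy(), values=env)
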