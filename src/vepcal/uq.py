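"""Ensemble uncertainty quantification from the optimizer's archive.

The optimizer logs every evaluated solution.  The UQ workflow keeps the
near-optimal subset (a relative cost threshold), draws a representative
subsample (farthest-point in bounds-normalized parameter space, anchored at
the best solution), normalizes the parameters to [0, 1] and summarizes each
parameter by empirical percentile bands around the median — the ensemble of
calibrations that explain the data about equally well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimizer import SolutionArchive

__all__ = [
    "EnsembleSummary",
    "filter_archive",
    "subsample_representative",
    "percentile_bands",
    "median_bandwidth",
]

DEFAULT_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass
class EnsembleSummary:
    """Percentile bands of one normalized parameter over the ensemble."""

    parameter_index: int
    percentiles: tuple
    band_values: np.ndarray
    n_members: int

    def __post_init__(self):
        self.band_values = np.asarray(self.band_values, float)
        if np.any(np.diff(self.band_values) < -1e-12):
            raise ValueError("band values must be non-decreasing")

    @property
    def median(self) -> float:
        k = int(np.argmin(np.abs(np.asarray(self.percentiles) - 50.0)))
        return float(self.band_values[k])

    def width(self, low: float = 5.0, high: float = 95.0) -> float:
        p = np.asarray(self.percentiles)
        return float(self.band_values[int(np.argmin(np.abs(p - high)))]
                     - self.band_values[int(np.argmin(np.abs(p - low)))])


def _subset(archive: SolutionArchive, idx) -> SolutionArchive:
    return SolutionArchive.from_arrays(
        archive.thetas[idx], archive.costs[idx], archive.worker_ids[idx],
        archive.eval_indices[idx], archive.eval_seeds[idx],
        quality_threshold=archive.quality_threshold)


def filter_archive(archive: SolutionArchive, rel_threshold: float = 10.0,
                   stochastic: bool = False) -> SolutionArchive:
    """Keep the near-optimal entries of the archive.

    Deterministic problems keep cost <= rel_threshold * best (absolute floor
    1e-12 when the best is exactly zero).  Stochastic costs carry noise, so
    the cut is additive instead: cost <= best + rel_threshold * IQR of the
    archived costs.
    """
    if len(archive) == 0:
        raise ValueError("archive is empty")
    if rel_threshold <= 1:
        raise ValueError("rel_threshold must exceed 1")
    costs = archive.costs
    best = costs.min()
    if stochastic:
        q25, q75 = np.percentile(costs, [25, 75])
        cut = best + rel_threshold * (q75 - q25)
    else:
        cut = rel_threshold * best if best > 0 else 1e-12
    idx = np.flatnonzero(costs <= cut)
    if idx.size == 0:  # always retain the best entry
        idx = np.array([int(np.argmin(costs))])
    return _subset(archive, idx)


def subsample_representative(archive: SolutionArchive, bounds,
                             target_n: int = 500,
                             rng=None) -> SolutionArchive:
    """Farthest-point subsample in bounds-normalized parameter space.

    Starts from the best-cost entry and greedily adds the entry farthest
    (max-min Euclidean distance) from the chosen set; ties broken by the
    rng.  Archives not larger than ``target_n`` are returned unchanged.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    n = len(archive)
    if n <= target_n:
        return archive
    rng = np.random.default_rng(rng)
    lb, ub = (np.asarray(b, float) for b in bounds)
    norm = (archive.thetas - lb) / (ub - lb)
    costs = archive.costs
    chosen = [int(np.argmin(costs))]
    dmin = np.linalg.norm(norm - norm[chosen[0]], axis=1)
    while len(chosen) < target_n:
        m = dmin.max()
        ties = np.flatnonzero(dmin >= m * (1 - 1e-12))
        k = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        chosen.append(k)
        dmin = np.minimum(dmin, np.linalg.norm(norm - norm[k], axis=1))
    return _subset(archive, np.asarray(chosen))


def percentile_bands(archive: SolutionArchive, bounds,
                     percentiles=DEFAULT_PERCENTILES) -> list[EnsembleSummary]:
    """Per-parameter percentile bands of the bounds-normalized ensemble."""
    if len(archive) == 0:
        raise ValueError("archive is empty")
    percentiles = tuple(float(p) for p in percentiles)
    if any(b < a for a, b in zip(percentiles, percentiles[1:])):
        raise ValueError("percentiles must be sorted ascending")
    lb, ub = (np.asarray(b, float) for b in bounds)
    if np.any(ub <= lb):
        raise ValueError("degenerate bounds (ub <= lb)")
    norm = (archive.thetas - lb) / (ub - lb)
    bands = np.percentile(norm, percentiles, axis=0)  # (P, dim)
    return [EnsembleSummary(parameter_index=i + 1, percentiles=percentiles,
                            band_values=bands[:, i], n_members=len(archive))
            for i in range(norm.shape[1])]


def median_bandwidth(summaries, low: float = 5.0, high: float = 95.0) -> float:
    """Median over parameters of the (low, high) percentile band width."""
    return float(np.median([s.width(low, high) for s in summaries]))
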