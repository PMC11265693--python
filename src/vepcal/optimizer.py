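"""Cooperative enhanced scatter search (eSS) with DHC local search.

Each worker runs an eSS instance: a small reference set (RefSet) of
high-quality, diverse solutions is combined pairwise inside expanded
hyper-rectangles, improvements trigger a "go-beyond" line intensification,
and a derivative-free Dynamic Hill Climbing (DHC) local search periodically
refines the best unrefined member.  Workers cooperate through a master that
propagates sufficiently large improvements to the other workers' RefSets and
keeps a scoreboard: workers that stay unproductive for too long have their
settings replaced by a jittered copy of the current best scorer's settings.

Cooperation runs in-process: workers are stepped round-robin and exchange
only (theta, cost) records through the master, so a single-worker
cooperative run is exactly an eSS run, and every reported best is the argmin
of the logged solution archive.
"""

from __future__ import annotations

import inspect
import logging
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

__all__ = [
    "WorkerConfig",
    "CooperationConfig",
    "SolutionArchive",
    "OptimizationResult",
    "initialize_refset",
    "combine_solutions",
    "go_beyond",
    "dhc_local_search",
    "run_ess",
    "run_cooperative",
]

logger = logging.getLogger("vepcal.optimizer")

#: minimum normalized pairwise distance kept between RefSet members
DUPLICATE_TOL = 1e-8


@dataclass
class WorkerConfig:
    """Tunables of a single eSS worker.

    ``refset_size`` defaults (when None) to 2*ceil(sqrt(dim)) rounded up to
    even, ``diversification_size`` to 10*dim, per standard scatter-search
    practice.  ``balance`` in [0, 1] weights intensification (quality
    members) vs diversification (diverse members) when the RefSet is built
    or regenerated.
    """

    refset_size: int | None = None
    diversification_size: int | None = None
    local_search_max_evals: int = 1000
    local_search_trigger: int = 10
    balance: float = 0.5
    seed: int = 0
    stagnation_iters: int = 8

    def resolved(self, dim: int) -> "WorkerConfig":
        rs = self.refset_size
        if rs is None:
            rs = 2 * math.ceil(math.sqrt(dim))
        if rs % 2:
            rs += 1
        rs = max(4, rs)
        dv = self.diversification_size
        if dv is None:
            dv = 10 * dim
        dv = max(dv, rs)
        cfg = replace(self, refset_size=rs, diversification_size=dv)
        if cfg.local_search_max_evals < 1 or cfg.local_search_trigger < 1:
            raise ValueError("local search counters must be positive")
        if not 0.0 <= cfg.balance <= 1.0:
            raise ValueError("balance must lie in [0, 1]")
        return cfg


@dataclass
class CooperationConfig:
    """Master-side settings of the cooperative (island) scheme."""

    n_workers: int = 4
    improvement_threshold: float = 0.1
    reconfigure_after_evals: int = 20000
    scoreboard_window: int = 10000
    max_evals_total: int = 200000
    max_walltime: float | None = None
    target_cost: float | None = None
    final_polish_frac: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if not 0.0 < self.improvement_threshold < 1.0:
            raise ValueError("improvement_threshold must lie in (0, 1)")
        if self.reconfigure_after_evals < 1 or self.scoreboard_window < 1:
            raise ValueError("cooperation counters must be positive")
        if not 0.0 <= self.final_polish_frac < 1.0:
            raise ValueError("final_polish_frac must lie in [0, 1)")


class SolutionArchive:
    """Every evaluated (theta, cost) record of a run, with provenance.

    Entries with non-finite cost are excluded.  ``quality_threshold`` is the
    relative cost threshold later applied by the UQ filtering step.
    """

    def __init__(self, quality_threshold: float = 10.0):
        self.quality_threshold = quality_threshold
        self._thetas: list[np.ndarray] = []
        self._costs: list[float] = []
        self._workers: list[int] = []
        self._eval_idx: list[int] = []
        self._seeds: list[int] = []

    def add(self, theta, cost, worker_id, eval_index, eval_seed=0):
        if math.isfinite(cost):
            self._thetas.append(np.array(theta, dtype=float))
            self._costs.append(float(cost))
            self._workers.append(int(worker_id))
            self._eval_idx.append(int(eval_index))
            self._seeds.append(int(eval_seed))

    def __len__(self) -> int:
        return len(self._costs)

    @property
    def thetas(self) -> np.ndarray:
        return np.array(self._thetas) if self._thetas else np.empty((0, 0))

    @property
    def costs(self) -> np.ndarray:
        return np.asarray(self._costs, dtype=float)

    @property
    def worker_ids(self) -> np.ndarray:
        return np.asarray(self._workers, dtype=int)

    @property
    def eval_indices(self) -> np.ndarray:
        return np.asarray(self._eval_idx, dtype=int)

    @property
    def eval_seeds(self) -> np.ndarray:
        return np.asarray(self._seeds, dtype=int)

    def best(self):
        i = int(np.argmin(self._costs))
        return self._thetas[i], self._costs[i]

    @classmethod
    def from_arrays(cls, thetas, costs, worker_ids=None, eval_indices=None,
                    eval_seeds=None, quality_threshold: float = 10.0):
        arc = cls(quality_threshold)
        thetas = np.atleast_2d(np.asarray(thetas, float))
        costs = np.asarray(costs, float)
        n = len(costs)
        worker_ids = np.zeros(n, int) if worker_ids is None else worker_ids
        eval_indices = np.arange(n) if eval_indices is None else eval_indices
        eval_seeds = np.zeros(n, int) if eval_seeds is None else eval_seeds
        for i in range(n):
            arc.add(thetas[i], costs[i], worker_ids[i], eval_indices[i],
                    eval_seeds[i])
        return arc

    def to_dataframe(self):
        import pandas as pd

        th = self.thetas
        cols = {f"theta_{i}": th[:, i] for i in range(th.shape[1])}
        cols["cost"] = self.costs
        cols["worker"] = self.worker_ids
        cols["eval_index"] = self.eval_indices
        cols["eval_seed"] = self.eval_seeds
        return pd.DataFrame(cols)


@dataclass
class OptimizationResult:
    best_theta: np.ndarray
    best_cost: float
    trace: list[tuple[int, float]]
    archive: SolutionArchive
    n_evals: int
    worker_stats: list[dict] = field(default_factory=list)


class _Budget:
    """Shared evaluation counter, global best bookkeeping and stop logic."""

    def __init__(self, max_evals, max_walltime=None, target_cost=None):
        self.max_evals = int(max_evals)
        self.max_walltime = max_walltime
        self.target_cost = target_cost
        self.t0 = time.monotonic()
        self.evals = 0
        self.best_cost = np.inf
        self.best_theta = None
        self.trace: list[tuple[int, float]] = []

    def exhausted(self) -> bool:
        if self.evals >= self.max_evals:
            return True
        if self.max_walltime is not None and \
                time.monotonic() - self.t0 >= self.max_walltime:
            return True
        if self.target_cost is not None and self.best_cost <= self.target_cost:
            return True
        return False

    def record(self, theta, cost):
        self.evals += 1
        if cost < self.best_cost:
            self.best_cost = cost
            self.best_theta = np.array(theta, dtype=float)
            self.trace.append((self.evals, float(cost)))


class _BudgetExhausted(Exception):
    pass


# ---------------------------------------------------------------------------
# eSS building blocks
# ---------------------------------------------------------------------------


def _wrap_cost(cost_fn):
    """Accept both f(theta) and f(theta, eval_seed) cost functions."""
    try:
        n_par = len(inspect.signature(cost_fn).parameters)
    except (TypeError, ValueError):
        n_par = 2
    if n_par >= 2:
        return cost_fn
    return lambda theta, eval_seed=0: cost_fn(theta)


def initialize_refset(bounds, config: WorkerConfig, rng, cost_fn=None,
                      evaluator=None):
    """Latin-hypercube diversification, then RefSet = quality + diversity.

    The best ``round(balance * size)`` candidates enter by cost; the rest
    are picked greedily to maximize the minimum normalized distance to the
    members already chosen.
    """
    lb, ub = (np.asarray(b, float) for b in bounds)
    dim = lb.size
    cfg = config.resolved(dim)
    if evaluator is None:
        f = _wrap_cost(cost_fn)

        def evaluator(th):
            return f(th, int(rng.integers(2 ** 31)))

    sampler = qmc.LatinHypercube(d=dim, seed=int(rng.integers(2 ** 31)))
    cand = lb + sampler.random(cfg.diversification_size) * (ub - lb)
    costs = np.array([evaluator(c) for c in cand])
    finite = np.isfinite(costs)
    if not finite.any():
        raise RuntimeError("initialization failed: all candidates non-finite")
    cand, costs = cand[finite], costs[finite]
    order = np.argsort(costs)
    size = min(cfg.refset_size, len(costs))
    n_quality = int(np.clip(round(cfg.balance * size), 1, size))
    chosen = list(order[:n_quality])
    # diversity fill: greedy max-min distance in bounds-normalized space
    norm = (cand - lb) / (ub - lb)
    rest = [i for i in order[n_quality:]]
    while len(chosen) < size and rest:
        sel = norm[chosen]
        dmin = np.array([np.min(np.linalg.norm(sel - norm[i], axis=1))
                         for i in rest])
        k = int(np.argmax(dmin))
        chosen.append(rest.pop(k))
    return [(cand[i].copy(), float(costs[i])) for i in chosen]


def combine_solutions(a, b, bounds, rng, expand: float = 1.0):
    """Child drawn uniformly from the hyper-rectangle spanned by a and b,
    expanded on each side by ``expand/2`` times the pair displacement, then
    clipped to bounds.  ``expand=0`` reduces to the plain [a, b] box."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    lb, ub = (np.asarray(x, float) for x in bounds)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    margin = 0.5 * expand * (hi - lo)
    child = rng.uniform(lo - margin, hi + margin)
    return np.clip(child, lb, ub)


def go_beyond(parent, child, cost_fn, bounds, max_steps: int = 20,
              eval_hook=None):
    """Intensify along the improving direction (child - parent).

    While the step keeps improving, advance further; after every pair of
    consecutive successes the advance factor's denominator is halved
    (doubling the stride), per the eSS convention.  Returns the best
    (theta, cost) found; never leaves the bounds.
    """
    f = _wrap_cost(cost_fn)
    lb, ub = (np.asarray(x, float) for x in bounds)
    p_theta, p_cost = np.asarray(parent[0], float), float(parent[1])
    c_theta, c_cost = np.asarray(child[0], float), float(child[1])
    if not c_cost < p_cost:
        raise ValueError("go_beyond requires child cost < parent cost")
    denom = 1.0
    successes = 0
    for _ in range(max_steps):
        step = (c_theta - p_theta) / denom
        cand = np.clip(c_theta + step, lb, ub)
        if np.allclose(cand, c_theta):
            break
        cand_cost = f(cand) if eval_hook is None else eval_hook(cand)
        if cand_cost < c_cost:
            p_theta, p_cost = c_theta, c_cost
            c_theta, c_cost = cand, float(cand_cost)
            successes += 1
            if successes == 2:
                denom /= 2.0
                successes = 0
        else:
            break
    return c_theta, c_cost


def dhc_local_search(start, cost_fn, bounds, max_evals: int, rng=None,
                     initial_step: float = 0.1, eval_hook=None):
    """Dynamic Hill Climbing: adaptive coordinate search with a composite
    pattern move.

    Maintains a signed step per coordinate (fractions of the box size);
    a successful probe doubles the step, a failed one reverses, then halves
    it.  After each improving sweep the composite displacement of the sweep
    is re-applied with doubling stride while it keeps improving, which cuts
    diagonally through ill-conditioned valleys that defeat purely
    coordinate-aligned moves.  Terminates when all steps shrink below 1e-9
    of the box or the evaluation budget is spent.  The returned cost never
    exceeds the start's.
    """
    f = _wrap_cost(cost_fn)
    lb, ub = (np.asarray(x, float) for x in bounds)
    span = ub - lb
    dim = lb.size
    theta = np.clip(np.asarray(start, float), lb, ub)
    evals = 0

    def ev(th):
        nonlocal evals
        evals += 1
        return f(th) if eval_hook is None else eval_hook(th)

    best_cost = ev(theta)
    steps = initial_step * span.copy()
    while evals < max_evals and np.any(np.abs(steps) >= 1e-9 * span):
        sweep_start = theta.copy()
        improved_any = False
        for i in range(dim):
            if evals >= max_evals:
                break
            if abs(steps[i]) < 1e-9 * span[i]:
                continue
            cand = theta.copy()
            cand[i] = np.clip(cand[i] + steps[i], lb[i], ub[i])
            c = ev(cand) if cand[i] != theta[i] else np.inf
            if c < best_cost:
                theta, best_cost = cand, c
                steps[i] *= 2.0
                steps[i] = math.copysign(min(abs(steps[i]), span[i]), steps[i])
                improved_any = True
            else:
                steps[i] = -0.5 * steps[i]
        # pattern move along the sweep's composite displacement
        if improved_any and evals < max_evals:
            delta = theta - sweep_start
            while evals < max_evals and np.any(delta != 0):
                cand = np.clip(theta + delta, lb, ub)
                if np.array_equal(cand, theta):
                    break
                c = ev(cand)
                if c < best_cost:
                    theta, best_cost = cand, c
                    delta *= 2.0
                else:
                    break
        if not improved_any and np.all(np.abs(steps) < 1e-9 * span):
            break
    return theta, float(best_cost)


# ---------------------------------------------------------------------------
# eSS worker
# ---------------------------------------------------------------------------


class ESSWorker:
    """One enhanced-scatter-search instance, steppable one iteration at a
    time so that a master can interleave several workers."""

    def __init__(self, worker_id, cost_fn, bounds, config: WorkerConfig,
                 budget: _Budget, archive: SolutionArchive):
        self.id = worker_id
        self.f = _wrap_cost(cost_fn)
        self.lb, self.ub = (np.asarray(b, float) for b in bounds)
        self.dim = self.lb.size
        self.config = config.resolved(self.dim)
        self.rng = np.random.default_rng(self.config.seed)
        self.budget = budget
        self.archive = archive
        self.refset: list[list] = []  # [theta, cost, ls_done]
        self.iterations = 0
        self.stagnation = 0
        self.regenerations_since_improvement = 0
        self.evals = 0
        self.best_cost = np.inf
        self.best_theta = None
        self.inbox: list[tuple[np.ndarray, float]] = []
        self.initialized = False

    # -- evaluation plumbing -------------------------------------------------
    def _eval(self, theta):
        if self.budget.exhausted():
            raise _BudgetExhausted()
        seed = int(self.rng.integers(2 ** 31))
        cost = float(self.f(theta, seed))
        self.evals += 1
        self.budget.record(theta, cost)
        self.archive.add(theta, cost, self.id, self.budget.evals, seed)
        if cost < self.best_cost:
            self.best_cost = cost
            self.best_theta = np.array(theta, float)
        return cost

    # -- RefSet management ---------------------------------------------------
    def _norm(self, theta):
        return (theta - self.lb) / (self.ub - self.lb)

    def _is_duplicate(self, theta, exclude=None):
        tn = self._norm(theta)
        for k, m in enumerate(self.refset):
            if exclude is not None and k == exclude:
                continue
            if np.linalg.norm(self._norm(m[0]) - tn) < DUPLICATE_TOL:
                return True
        return False

    def initialize(self):
        members = initialize_refset((self.lb, self.ub), self.config, self.rng,
                                    evaluator=self._eval)
        self.refset = [[t, c, False] for t, c in members]
        self.initialized = True

    def inject(self, theta, cost):
        """Receive a broadcast solution: replace the worst member if it is
        better and not a duplicate of an existing member."""
        if not self.initialized or self._is_duplicate(theta):
            return False
        worst = max(range(len(self.refset)), key=lambda k: self.refset[k][1])
        if cost < self.refset[worst][1]:
            self.refset[worst] = [np.array(theta, float), float(cost), True]
            if cost < self.best_cost:
                self.best_cost = float(cost)
                self.best_theta = np.array(theta, float)
            return True
        return False

    def _regenerate(self):
        """Stagnation recovery: keep the quality core, redraw the rest.

        A second stagnation without any improvement in between escalates to
        a full restart (fresh diversification, nothing kept) — polishing the
        same deceptive basin twice is a waste of the evaluation budget; the
        global best is safe in the archive and with the master.
        """
        if self.regenerations_since_improvement >= 1:
            self.initialize()
            # mate the fresh diversification with the incumbent: combinations
            # against the best-known solution probe its basin's surroundings
            if self.budget.best_theta is not None:
                self.inject(self.budget.best_theta, self.budget.best_cost)
            self.regenerations_since_improvement = 0
            self.stagnation = 0
            return
        self.refset.sort(key=lambda m: m[1])
        size = len(self.refset)
        keep = int(np.clip(round(self.config.balance * size), 1, size - 1))
        sampler = qmc.LatinHypercube(d=self.dim,
                                     seed=int(self.rng.integers(2 ** 31)))
        fresh = self.lb + sampler.random(size - keep) * (self.ub - self.lb)
        new = self.refset[:keep]
        for th in fresh:
            new.append([th, self._eval(th), False])
        self.refset = new
        self.regenerations_since_improvement += 1
        self.stagnation = 0

    # -- one eSS generation --------------------------------------------------
    def iteration(self):
        if not self.initialized:
            self.initialize()
            return
        prev_best = self.best_cost
        size = len(self.refset)
        replacements: dict[int, tuple[np.ndarray, float]] = {}
        for i in range(size):
            for j in range(i + 1, size):
                a_th, a_c = self.refset[i][0], self.refset[i][1]
                b_th, b_c = self.refset[j][0], self.refset[j][1]
                child = combine_solutions(a_th, b_th, (self.lb, self.ub),
                                          self.rng)
                c_cost = self._eval(child)
                # associate the child with the worse parent
                k, p_th, p_c = (j, b_th, b_c) if b_c >= a_c else (i, a_th, a_c)
                if c_cost < p_c:
                    child, c_cost = go_beyond(
                        (p_th, p_c), (child, c_cost), self.f,
                        (self.lb, self.ub), eval_hook=self._eval)
                    cur = replacements.get(k)
                    if cur is None or c_cost < cur[1]:
                        replacements[k] = (child, c_cost)
        for k, (th, c) in replacements.items():
            if c < self.refset[k][1] and not self._is_duplicate(th, exclude=k):
                self.refset[k] = [np.array(th, float), float(c), False]
        self.iterations += 1
        # periodic local search from the best unrefined member
        if self.iterations % self.config.local_search_trigger == 0:
            cand = [m for m in self.refset if not m[2]]
            if cand:
                m = min(cand, key=lambda m: m[1])
                th, c = dhc_local_search(
                    m[0], self.f, (self.lb, self.ub),
                    self.config.local_search_max_evals, self.rng,
                    eval_hook=self._eval)
                m[2] = True
                if c < m[1] and not self._is_duplicate(th):
                    m[0], m[1] = th, float(c)
        if self.best_cost < prev_best * (1 - 1e-12):
            self.stagnation = 0
            self.regenerations_since_improvement = 0
        else:
            self.stagnation += 1
            if self.stagnation >= self.config.stagnation_iters:
                self._regenerate()

    def stats(self) -> dict:
        return {"worker": self.id, "evals": self.evals,
                "best_cost": self.best_cost, "iterations": self.iterations,
                "config": {k: getattr(self.config, k) for k in
                           ("refset_size", "diversification_size",
                            "local_search_max_evals", "local_search_trigger",
                            "balance", "seed")}}


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _final_polish(budget: _Budget, worker: "ESSWorker") -> None:
    """Spend the reserved tail of the evaluation budget on one deep DHC run
    from the global best — exploration triages basins cheaply, and only the
    winner gets refined to full precision."""
    if budget.best_theta is None or budget.exhausted():
        return
    remaining = budget.max_evals - budget.evals
    if remaining < 2 * worker.dim:
        return
    try:
        dhc_local_search(budget.best_theta, worker.f,
                         (worker.lb, worker.ub), remaining,
                         initial_step=0.01, eval_hook=worker._eval)
    except _BudgetExhausted:
        pass


def _finish(budget: _Budget, archive: SolutionArchive, workers) -> OptimizationResult:
    if budget.best_theta is None:
        raise RuntimeError("no finite-cost evaluation was performed")
    return OptimizationResult(
        best_theta=budget.best_theta, best_cost=float(budget.best_cost),
        trace=budget.trace, archive=archive, n_evals=budget.evals,
        worker_stats=[w.stats() for w in workers])


def run_ess(cost_fn, bounds, config: WorkerConfig | None = None,
            max_evals: int = 50000, max_walltime: float | None = None,
            target_cost: float | None = None,
            final_polish_frac: float = 0.15) -> OptimizationResult:
    """Single-instance enhanced scatter search."""
    config = config or WorkerConfig()
    budget = _Budget(max_evals, max_walltime, target_cost)
    explore_cap = int(round(max_evals * (1.0 - final_polish_frac)))
    budget.max_evals = explore_cap
    archive = SolutionArchive()
    worker = ESSWorker(0, cost_fn, bounds, config, budget, archive)
    try:
        while not budget.exhausted():
            worker.iteration()
    except _BudgetExhausted:
        pass
    budget.max_evals = max_evals
    _final_polish(budget, worker)
    return _finish(budget, archive, [worker])


def run_cooperative(cost_fn, bounds, worker_configs=None,
                    coop: CooperationConfig | None = None) -> OptimizationResult:
    """Cooperative multi-worker eSS with master-mediated exchange.

    The master accepts a worker's best only when it improves the global best
    by more than ``improvement_threshold`` relative (the threshold halves
    after more than 20 rejections, mirroring the self-tuning spirit of the
    original scheme), broadcasts accepted solutions to the other workers,
    and reconfigures workers whose last accepted improvement lies more than
    ``reconfigure_after_evals`` evaluations in the past by copying the best
    scorer's settings with +-20% jitter.
    """
    coop = coop or CooperationConfig()
    if worker_configs is None:
        master_rng = np.random.default_rng(coop.seed)
        worker_configs = []
        for w in range(coop.n_workers):
            # heterogeneous islands: aggressive (small refset, frequent LS)
            # through conservative (large refset, rare LS)
            frac = w / max(1, coop.n_workers - 1) if coop.n_workers > 1 else 0.5
            worker_configs.append(WorkerConfig(
                balance=0.3 + 0.4 * frac,
                local_search_trigger=int(round(8 + 4 * frac)),
                seed=int(master_rng.integers(2 ** 31)),
            ))
    else:
        master_rng = np.random.default_rng(coop.seed)
    if len(worker_configs) != coop.n_workers:
        raise ValueError("worker_configs length must equal n_workers")

    budget = _Budget(coop.max_evals_total, coop.max_walltime, coop.target_cost)
    explore_cap = int(round(coop.max_evals_total
                            * (1.0 - coop.final_polish_frac)))
    budget.max_evals = explore_cap
    archive = SolutionArchive()
    workers = [ESSWorker(w, cost_fn, bounds, cfg, budget, archive)
               for w, cfg in enumerate(worker_configs)]
    alive = [True] * coop.n_workers
    global_best = np.inf
    threshold = coop.improvement_threshold
    rejected = 0
    # scoreboard: accepted improvements per worker within the recent window
    accepted_log: list[tuple[int, int]] = []  # (eval count, worker)
    last_accept_evals = [0] * coop.n_workers

    def scoreboard_counts():
        lo = budget.evals - coop.scoreboard_window
        counts = [0] * coop.n_workers
        for ev, w in accepted_log:
            if ev >= lo:
                counts[w] += 1
        return counts

    while not budget.exhausted() and any(alive):
        for w, worker in enumerate(workers):
            if not alive[w] or budget.exhausted():
                continue
            try:
                worker.iteration()
            except _BudgetExhausted:
                break
            except Exception:  # pragma: no cover - crash containment
                logger.exception("worker %d crashed; continuing without it", w)
                alive[w] = False
                continue
            if worker.best_cost < global_best:
                rel = ((global_best - worker.best_cost)
                       / max(abs(global_best), 1e-300))
                accept = (not math.isfinite(global_best)) or rel > threshold
                global_best = worker.best_cost
                if accept and coop.n_workers > 1:
                    accepted_log.append((budget.evals, w))
                    last_accept_evals[w] = budget.evals
                    for v, other in enumerate(workers):
                        if v != w and alive[v]:
                            other.inject(worker.best_theta, worker.best_cost)
                elif not accept:
                    rejected += 1
                    if rejected > 20:
                        threshold *= 0.5
                        rejected = 0
            # scoreboard-driven reconfiguration of inactive workers
            if coop.n_workers > 1 and \
                    budget.evals - last_accept_evals[w] > coop.reconfigure_after_evals:
                counts = scoreboard_counts()
                leader = int(np.argmax(counts))
                if leader != w and alive[leader]:
                    src = workers[leader].config
                    jit = lambda v: v * float(master_rng.uniform(0.8, 1.2))
                    workers[w].config = replace(
                        src,
                        local_search_max_evals=max(
                            2 * worker.dim, int(jit(src.local_search_max_evals))),
                        local_search_trigger=max(1, int(round(
                            jit(src.local_search_trigger)))),
                        balance=float(np.clip(jit(src.balance), 0.0, 1.0)),
                        seed=int(master_rng.integers(2 ** 31)),
                    ).resolved(worker.dim)
                    logger.info("reconfigured worker %d from leader %d", w, leader)
                last_accept_evals[w] = budget.evals
    if not any(alive):
        raise RuntimeError("all cooperative workers failed")
    budget.max_evals = coop.max_evals_total
    _final_polish(budget, workers[next(w for w in range(coop.n_workers)
                                       if alive[w])])
    return _finish(budget, archive, workers)
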