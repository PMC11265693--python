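# Methods

## Model

Each brain region `i` of an `N`-region network carries a 2D reduction of the
Epileptor neural mass, with a fast variable `x_i` (discharges) and a slow
permittivity variable `z_i`:

    dx_i/dt = 1 - x_i^3 - 2 x_i^2 - z_i + I
    dz_i/dt = (1/tau) * ( 4 (x_i - eta_i) - z_i - K * sum_j C_ij (x_j - x_i) )

with input current `I = 3.1`, time constant `tau` scaling the seizure
length, per-region excitability `eta_i`, a global coupling gain `K >= 0` and
the structural connectome `C` (non-negative, symmetric here, max entry
normalized to 1).  Time is dimensionless; the integrator is forward Euler
(Euler–Maruyama when process noise is on) with `dt = 0.1`, initial state
`(-2.5, 3.5)` in every region.

An isolated node (`K = 0`) has exactly one fixed point for every `eta`
(the map `eta(x) = (x^3 + 2x^2 + 4x - 1 - I)/4` is strictly monotone), and
the 2×2 Jacobian `[[-3x^2-4x, -1], [4/tau, -1/tau]]` always has positive
determinant, so stability is decided by the trace alone (a Hopf scenario).
The critical excitability solves `3x^2 + 4x + 1/tau = 0` at the fixed point:
`eta_c = -2.037` at `tau = 10`, tending to `-2.062` as `tau -> inf`; the
conventional quoted value −2.05 sits inside this weak `tau` dependence.
`critical_excitability` finds the threshold by a stability sweep plus
bisection to 1e-3 rather than the closed form, so it also works for any
variant of the node dynamics.

Regions are classed by excitability relative to `eta_c = -2.05` with margin
`delta_eta = 1.0`: EZ (`eta > eta_c`, seizes autonomously), PZ
(`eta_c - delta < eta <= eta_c`, recruitable), HZ (below).  Boundary values
go to the less pathological class.

## Observations

Sensor signals follow `S_i(t) = sum_j G_ij exp(x_j(t))`, with the gain
`G_ij = sum_{k in V_j} c A_k / d_ik^2` summing inverse-square contributions
of region `j`'s surface vertices.  Orientation dependence of the decay is
deliberately not modelled.  Source-level problems use `G = I`.
Measurement noise is Gaussian with std `sigma'` (zero in all benchmark
defaults); process noise enters both state equations with equal std
`sigma` (configurable per-equation scaling).

## Benchmark study conditions

Six problems cross coupling regime (weak `K = 0.1` / strong `K = 1.0`),
observation level (source / sensor with `N_s < N` so the gain is
rank-deficient), and dynamics (deterministic / stochastic with
`sigma = 0.1` and `tau = 90`, i.e. a ~9× longer seizure envelope).
The estimation target is `theta = (eta_1..eta_N, K)`, bounds
`eta in [-5, -1]`, `K in [0, 2]`, scored by the RMSE between the stored
observation and a fresh forward simulation under `theta` (raw signals by
default; a sliding-RMS envelope cost is available as `cost_mode =
"envelope"`).  Deterministic problems have a zero-cost global optimum by
construction; stochastic costs are strictly positive even at the truth.

Values the benchmark table does not print were chosen once, as follows:

* **Connectome** — symmetric log-normal weights (`sigma_log = 2.5`), zero
  diagonal, max entry exactly 1.  The heavy tail mirrors the
  orders-of-magnitude spread of tractography streamline counts; it is also
  what makes seizure propagation selective: with a narrow weight
  distribution, diffusive coupling anchors every region to its many quiet
  neighbours and no clinically plausible `K` recruits anything.
* **Truth map** — 2 EZ (eta ~ U[-1.9, -1.5]) placed at random, 3 PZ
  (U[-2.4, -2.1]) at the regions most strongly connected to the EZ set
  (propagation-zone candidates are defined by their structural pathways to
  the focus), remainder HZ (U[-3.8, -3.2]).  The bands keep >= 0.05 margin
  from both class thresholds.
* **Coupling** — `K = 0.1` produces no recruitment (all non-EZ regions stay
  within 0.5 of their fixed point); `K = 1.0` recruits at least one PZ into
  sustained oscillation while HZ regions stay quiet.  Both statements are
  asserted as tests on the shipped 12-region instance.
* **Record length** — 100 time units for the deterministic problems
  (~8 seizure cycles at `tau = 10`; the limit-cycle period at
  `eta = -1.6` is ≈ 12.4 units), 900 for the stiff stochastic ones,
  sampled every 10th Euler step.  Record length is a genuine design
  parameter of the cost: because all regions start from a common fixed
  initial state, the oscillation phase at time `t` is set by `eta`, and the
  width of the RMSE funnel around the true excitability of a seizing region
  shrinks roughly like 1/(number of cycles in the record).  A few-cycle
  window keeps the global optimum attractable while still identifying the
  period; hundred-cycle records make the deterministic cost needle-shaped
  around the truth and defeat any derivative-free search.
* **Implantation geometry** — region vertex clouds (3 vertices, areas
  U[5, 15] mm²) in a 100 mm head sphere; each of the `N_s` contacts is
  placed 5–20 mm from a distinct region's centre (cycling a random
  permutation), the way depth electrodes target candidate tissue.
  Near-field dominance gives the gain well-differentiated columns; an
  earlier far-field variant (contacts anywhere in the sphere) produced
  pairs of regions with almost parallel gain columns — an artificial
  degeneracy no estimator can break.  Regions without a nearby contact
  remain weakly observed, which is the intended identifiability challenge
  of the sensor-level problems.

What the generator does *not* emulate: real parcellation geometry and
fibre-count connectomes, electrode shafts with collinear contact strips,
bipolar referencing, volume conduction, measurement noise floors, and
patient-specific EZ hypotheses.  Passing benchmarks therefore demonstrate
the estimator's behaviour under the model's own assumptions, not clinical
performance.

## Optimizer

Each worker is an enhanced scatter search (eSS) instance:

* RefSet of `2*ceil(sqrt(dim))` members (even), built from a Latin
  hypercube diversification of `10*dim` points as a balance-weighted mix of
  best-by-cost and max-min-distance members.
* All RefSet pairs are combined by a uniform draw from the hyper-rectangle
  spanned by the pair expanded by half the displacement per side; children
  that improve the worse parent trigger the go-beyond line intensification
  (advance along the improving direction, doubling the stride after every
  two consecutive successes).
* Every `local_search_trigger` iterations the best not-yet-refined member
  is refined by Dynamic Hill Climbing (DHC): per-coordinate signed steps
  that double on success and reverse-halve on failure, plus a composite
  pattern move re-applying each improving sweep's total displacement with
  doubling stride (this is what lets the search walk along the
  ill-conditioned valleys created by rank-deficient gains); termination
  when all steps fall below 1e-9 of the box.
* Stagnation (`stagnation_iters` improvement-free iterations) regenerates
  the diversity half of the RefSet; a second consecutive stagnation
  escalates to a full restart whose fresh RefSet is seeded with the global
  incumbent, so combinations immediately probe the incumbent basin's
  surroundings with fresh diversity.

Workers run in-process, stepped round-robin; they exchange only
(theta, cost) records through a master.  The master broadcasts a worker's
best into the other workers' RefSets when it improves the global best by
more than `improvement_threshold` (10%, halved after every 20 rejected
improvements), keeps a scoreboard of accepted improvements, and replaces
the settings of workers that stay unproductive for `reconfigure_after_evals`
evaluations with a ±20% jittered copy of the best scorer's settings.
The last `final_polish_frac` (15%) of the evaluation budget is reserved for
a single deep DHC run from the global best: exploration triages basins with
lean local searches (1000 evaluations) and only the winner is refined to
full precision.  Stopping criteria: total evaluations, wall-clock time and
a target cost (useful for deterministic problems whose optimum is zero).

Stochastic costs are compared on single fresh-noise evaluations; every
archive entry records the evaluation seed used, so any cost can be
replayed.  With one worker the cooperative driver reduces exactly to plain
eSS.  Default worker settings (RefSet sizing, lean local-search budget,
stagnation threshold, balance spread across islands) were hand-tuned on the
shipped benchmark instances — the analogue, at desk scale, of the
hyperparameter-tuning stage of the original cooperative method; they are
plain configuration values, not magic constants.

## Uncertainty quantification

All evaluated solutions with finite cost form the archive.  The UQ workflow
keeps entries with `cost <= 10 x best` (deterministic; for stochastic costs
an additive cut `best + 10 x IQR` replaces the ratio, which is meaningless
against a noisy, strictly positive floor), takes a farthest-point subsample
of 500 in bounds-normalized space anchored at the best solution, and
reports per-parameter percentile bands (5/25/50/75/95) of the normalized
ensemble.  Threshold and subsample size trade band smoothness against
runtime and are plain configuration.

## Numerical choices

* Euler/Euler–Maruyama with `dt = 0.1`; halving `dt` changes trajectories
  O(dt) (asserted).  Integration aborts when |x| or |z| exceeds 1e6; the
  cost of a diverged simulation is +inf (the optimizer discards it).
* The calibration hot path is a fused numba kernel (integrate + project +
  accumulate RMSE, no trajectory storage) compiled with fastmath; the
  trajectory simulator that *generates* observations uses strict FP.  On
  limit-cycle dynamics rounding perturbations grow only linearly, and the
  cost at the generating parameters stays at machine epsilon (asserted
  <= 1e-10).
* A marginally stable fixed point (|trace| < 1e-9) is classed unstable —
  ties break toward seizure onset.
* `eta` exactly at a class threshold goes to the less pathological class.
* RefSet duplicate filtering at 1e-8 normalized distance.

## Known limitations

* Sensor-level recovery of *healthy-zone* excitabilities is set by weak
  far-field gain entries; their posterior spread is wide (this is visible
  in the UQ bands and is the expected rank-deficiency effect), while EZ/PZ
  excitabilities and `K` are recovered tightly.
* The stochastic problems (5–6) retain a strictly positive RMSE floor and
  occasional class confusions near thresholds; the raw-signal RMSE is a
  blunt instrument against noise-driven recruitment variability.
* With more than one worker the search path is configuration-dependent;
  results are reproducible for a fixed seed set but not invariant to
  worker count.
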