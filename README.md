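# vepcal

Calibration toolkit for virtual-epileptic-patient (VEP) brain network
models.  Whole-brain seizure dynamics are simulated with a 2D reduction of
the Epileptor neural mass placed at every region of a structural
connectome; invasive SEEG recordings are emulated by an inverse-square
lead-field; and the spatial map of epileptogenicity is recovered from the
recordings with a cooperative global optimizer.  It is aimed at researchers
benchmarking model-inversion methods for epilepsy surgery planning.

## The model and the estimation problem

Region `i` follows

    ẋ_i = 1 − x_i³ − 2x_i² − z_i + I
    ż_i = (1/τ) [ 4(x_i − η_i) − z_i − K Σ_j C_ij (x_j − x_i) ]

with `I = 3.1`, connectome `C` (max entry 1), global coupling `K`, and
per-region excitability `η_i` — the bifurcation parameter that decides
whether a region can seize.  An isolated node loses its stable fixed point
at `η_c ≈ −2.05`; regions are classed as epileptogenic zone
(EZ: `η > η_c`), propagation zone (PZ: `η_c − 1 < η ≤ η_c`) or healthy
(HZ: below).  SEEG sensors measure `S_i(t) = Σ_j G_ij exp(x_j(t))` through
a rank-deficient gain matrix `G`.

Calibration estimates `θ = (η_1..η_N, K) ∈ R^{N+1}` by minimizing the RMSE
between the observed series and a forward simulation under `θ`, with an
enhanced scatter search (eSS) hybridized with Dynamic Hill Climbing, run as
cooperating islands that exchange their best solutions through a master
with scoreboard-driven reconfiguration.  The near-optimal solution archive
yields per-parameter percentile bands (ensemble uncertainty
quantification).  Six benchmark problems cross weak/strong coupling,
source/sensor observation, and deterministic/stochastic dynamics; see
`docs/methods.md` for the full study conditions.

## Worked example

Generate the weak-coupling source-level benchmark at 12 regions, calibrate
it, and score the recovered map:

    $ vepcal generate --problem 1 --regions 12 --seed 7 -o demo/bundle
    wrote problem 1 bundle to demo/bundle

    $ vepcal fit --problem-dir demo/bundle --workers 2 --max-evals 50000 \
          --target-cost 1e-8 --seed 1 -o demo/fit
    best cost 9.61556e-09 after 8525 evaluations; results in demo/fit

    $ vepcal evaluate --result demo/fit/result.json \
          --problem-dir demo/bundle -o demo/confusion.json
    confusion matrix (rows true EZ/PZ/HZ, cols predicted):
         2    0    0
         0    3    0
         0    0    7
    accuracy: 100.0%

    $ vepcal uq --archive demo/fit/archive.tsv --problem-dir demo/bundle \
          -o demo/uq_bands.tsv
    wrote 13 parameter bands (500 ensemble members) to demo/uq_bands.tsv

The fit drives the RMSE to ~1e-8 (the deterministic optimum is zero by
construction), every region's class is recovered (2 EZ, 3 PZ, 7 HZ on the
diagonal), and `uq_bands.tsv` holds the 5/25/50/75/95 percentile bands of
each normalized parameter over the near-optimal ensemble — tight at source
level, visibly wider for the weakly observed regions of the sensor-level
problems.

The same things are available as a library:

```python
from vepcal import make_problem, make_cost_function, run_cooperative
from vepcal.optimizer import CooperationConfig

problem, observed = make_problem(2, n_regions=12, seed=7, n_sensors=8)
cost = make_cost_function(problem, observed)
result = run_cooperative(cost, problem.bounds,
                         coop=CooperationConfig(n_workers=2,
                                                max_evals_total=200_000,
                                                target_cost=1e-8, seed=1))
```

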