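# dynqs

Dynamic substrate-uptake growth modelling and real-time Bayesian state
estimation for fed-batch fermentations.

## The problem

Controlling a fed-batch culture of *E. coli* requires knowing, in real
time, quantities that cannot be sampled fast enough: the biomass *X*,
the residual substrate *S*, and the cell-specific kinetic parameters —
the maximum substrate uptake rate q<sub>S</sub><sup>max</sup> and the
biomass yield on carbon Y<sub>XC</sub>.  Off-gas signals (the CO₂
evolution rate, CER, and the O₂ uptake rate, OUR) are available every
few seconds and are stoichiometrically linked to growth, so they can
drive a model-based observer.

The classical Monod law makes the uptake rate an instantaneous function
of the substrate concentration,
q_S = q_S^max · (S/V)/(k_S + S/V), which ignores how long cells take to
*adapt* — the lag phase, and the damped response to substrate pulses.
An observer built on it systematically over-predicts CO₂ early in the
batch and compensates by discarding plausible parameter values.

`dynqs` instead promotes q_S to a state variable:

    dq_S/dt = λ · (1 − q_S/q_S^max) · (S/V)/(k_S + S/V)
              − q_S · q_S^max · (X/V) · k_S/(k_S + S/V)²

where λ [g g_DCW⁻¹ h⁻²] is the **substrate-uptake adaptability rate**, a
non-negative, non-decreasing, time-varying quantity modelled as a Gamma
process clocked by cell age φ = ∫(μ + MW_X·m_c)dτ.  A particle filter
propagates an ensemble of plants, each carrying its own state
(X, S, q_S, V) and parameters (q_S^max, Y_XC, λ), weights them by a
Gaussian likelihood on the CER channel, and resamples (systematic SIR)
whenever the effective sample size drops below 50% — each resampling
event also draws fresh Gamma increments Δλ ~ Γ(α·Δφ, β).

The package provides, as composable modules and a CLI:

* `models` — both ODE systems, the growth link μ(q_S), the CER/OUR
  output map, and the steady-state q_S expression;
* `simulate` — the synthetic fed-batch plant (batch on 8 g/L glycerol,
  exponential feed, sigmoidal λ activation, Dirac-like feed spikes,
  offline-assay noise);
* `lsq_prior` — weighted least-squares fitting (Nelder-Mead) and the
  Monte-Carlo mini-batch PSO procedure producing an empirical parameter
  prior p(θ);
* `particle_filter` — the Bayesian observer;
* `diagnostics` — Kullback-Leibler divergence between the empirical
  residual distribution and the designed likelihood, and the
  Monod-vs-dynamic model-comparison harness;
* `io_cli` — CSV schemas, YAML configuration, and the `dynqs` command.

## Worked example

```python
import numpy as np
from dynqs import simulate as sim, particle_filter as pf

# simulated plant: batch on 8 g/L glycerol, lambda activates around 8 h,
# feed from 11.5 h with four Gaussian pulses at t = 18, 22, 26, 30 h
traj = sim.simulate_plant(sim.reference_initial_state(),
                          sim.reference_parameters(),
                          sim.reference_feed(),
                          sim.reference_activation(), t_end=32.0)

# the observer sees only the CER record at dt = 0.05 h plus the feed law
obs = traj.observations(0.05)
res = pf.run_filter(obs, sim.reference_feed(),
                    sim.reference_initial_state(), seed=1)

end = res.mmse_at(11.5)
print(f"batch depleted near t = {traj.t[np.argmax(traj.S_conc < 0.01)]:.2f} h")
print(f"end-of-batch estimates: qS_max = {end['qS_max']:.3f}, "
      f"Y_XC = {end['Y_XC']:.3f}")
print(f"final lambda (MMSE) = {res.mmse['lam'].iloc[-1]:.2f},  "
      f"(MAP) = {res.final_lam_map_kde:.2f}")
print(f"resampling events: {len(res.resample_events)}")
print(f"mean CER residual over the run: {np.mean(res.residual_mean):.3f} cmmol/h")
```

prints

```
batch depleted near t = 10.81 h
end-of-batch estimates: qS_max = 1.131, Y_XC = 0.668
final lambda (MMSE) = 7.99,  (MAP) = 7.98
resampling events: 77
mean CER residual over the run: 0.286 cmmol/h
```

The plant was simulated with q_S^max = 1.2, Y_XC = 0.62 and an
asymptotic adaptability rate λ_act = 8.  For this single seed the
observer locates the yield/uptake pair near (but not exactly at) the
truth by the end of the batch — across ten seeds the medians land at
q_S^max ≈ 1.18 and Y_XC ≈ 0.64 — and, because the feed pulses keep
exciting the uptake dynamics, the λ estimate converges to the true
activation level.  The mean CER residual stays at a fraction of the
likelihood standard deviation (σ = √0.2 ≈ 0.45 cmmol/h).

The same pipeline from a shell:

```sh
dynqs simulate --seed 1 --outdir results
dynqs filter --observations results/observations.csv --seed 1 --outdir results
dynqs compare --observations results/observations.csv --n-seeds 3 --outdir results
```

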