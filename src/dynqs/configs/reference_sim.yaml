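# Reference in-silico fed-batch experiment: every numeric constant of the
# simulation study, used as the base profile with override semantics.
seed: 1
outdir: results

constants:
  MW_X: 0.0236      # g_DCW/cmmol
  MW_S: 0.0307      # g/cmmol
  m_c: 1.1          # cmmol/gDCW/h
  gamma_X: 4.25
  gamma_O2: -4.0
  gamma_S: 4.67
  S_in: 750.0       # g/L
  k_S: 0.004        # g/L

parameters:
  qS_max: 1.2       # g/gDCW/h (true simulation value)
  Y_XC: 0.62        # cmol/cmol

initial_state:
  X: 0.05           # g (in 1 L -> 0.05 g/L)
  S: 8.0            # g
  qS: 0.5           # g/gDCW/h
  V: 1.0            # L

feed:
  u0: 0.0014        # L/h
  mu_set: 0.12      # 1/h
  t_start: 11.5     # h
  spikes:
    centers: [18.0, 22.0, 26.0, 30.0]
    sigma: 0.01     # h
    factor: 2.0     # peak height = factor * base feed at center

activation:
  lambda_act: 8.0   # g/gDCW/h^2
  a: 0.8
  t_act: 8.0        # h

simulation:
  t_end: 32.0
  dt_out: 0.01
  rtol: 1.0e-8
  atol: 1.0e-10
  max_step: 0.005
  method: LSODA

offline_sampling:
  times: [2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0, 24.0, 28.0]
  noise: true

lsq:
  q_frac: 0.02
  bounds:
    qS_max: [0.2, 1.6]
    Y_XC: [0.3, 0.8]

pso:
  swarm_size: 100
  f_tol: 0.001
  max_iter: 20
  min_step: 0.001
  n_batches: 100

pf:
  n_particles: 1000
  dt: 0.05
  sigma2_cer: 0.2
  neff_fraction: 0.5
  alpha: 0.25
  beta: 1.7
  yxc_walk_var_rate: 1.0e-5
  qsmax_spread_threshold: 1.0e-4
  init_spread: 0.10
  transition: dynamic
  substeps: 5
  spike_substeps: 125

prior:
  kind: truncated_normal
  mean: [1.06, 0.63]
  sd: [0.15, 0.04]
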