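# Small demonstration pipeline config for `parage all`.
# Runs in a few minutes: 20,000 births, short chains for all ten outcomes.
# For production-scale inference raise iterations/burn_in to the defaults
# (200,000 thinned by 100 after 5,000 burn-in).
sim:
  n_births: 20000
  seed: 11
  outcomes:
    preterm:
      baseline: 0.08
      maternal: {kind: quadratic, trough: 30, curv_young: 0.00088, curv_old: 0.00218}
      paternal: {kind: quadratic, trough: 35, curv_young: 0.00067, curv_old: 0.00029}
      or_ds: 4.2
      or_cd: 6.0
    very_preterm: {baseline: 0.012, or_ds: 2.8, or_cd: 8.1}
    sga: {baseline: 0.10, or_ds: 2.3, or_cd: 5.2}
    low_apgar: {baseline: 0.005, or_ds: 4.7, or_cd: 31.4}
    nicu:
      baseline: 0.08
      maternal: {kind: quadratic, trough: 30, curv_young: 0.0005, curv_old: 0.00163}
      or_ds: 15.7
      or_cd: 15.9
    antibiotics: {baseline: 0.02, or_ds: 7.8, or_cd: 11.4}
    surfactant: {baseline: 0.005, or_ds: 6.0, or_cd: 16.4}
    prolonged_ventilation: {baseline: 0.007, or_ds: 12.7, or_cd: 22.9}
    seizures: {baseline: 0.0005, or_ds: 11.7, or_cd: 49.7}
    death: {baseline: 0.002, or_ds: 12.6, or_cd: 70.2}
mcmc:
  n_chains: 2
  burn_in: 500
  iterations: 3000
  thin: 10
  seed: 2020
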