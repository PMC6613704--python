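# Desk-scale synthetic run: excess-absence anomalies against an
# iris-shaped normal class. Every key mirrors RunConfig; omitted keys use
# the standard defaults (v_max=0.05, tau_A=5, f=0.1, FPR=0.1, ...).
synthetic:
  n_features: 4
  n_normal: 600
  n_anomalous: 100
  anomaly_mechanism: excess_absence
  seed: 0
N_pop: 4
W_tau: 2000
W_d: 2000
t_max: 300
tau_target: 150
folds: 3
seed: 0
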