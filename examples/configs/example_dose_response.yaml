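# Four-regime dose-response instance: linear, decreasing, increasing,
# saturating segments of log C3 vs log L1.
alpha: 1.0
beta: 5.0e+2
gamma: 1.2e-6
phi: 9.0e-2
b: 4.0e-2
kappa: 1.0e-4
nu1: 1.0e-2
nu2: 1.0
L1: 1.0
L2: 0.0
R: 3.0e+4
ST: 6.0e+5
N: 3
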