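# Instance with an interior optimum of C3 as a function of nu1
# (an optimal dissociation time for activation).
alpha: 1.0e-1
beta: 1.0e+1
gamma: 1.0e-4
phi: 1.0e-2
b: 1.0e-2
kappa: 1.0e-6
nu1: 1.0e-2
nu2: 1.0
L1: 1.0e+3
L2: 0.0
R: 1.0e+5
ST: 1.0e+7
N: 3
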