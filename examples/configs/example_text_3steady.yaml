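# Agonist-only instance with three positive steady states (N = 3).
# Low dissociation rate nu1 and abundant phosphatase ST make the
# feedback strong enough for bistability.
alpha: 1.0
beta: 1.0
gamma: 1.0
phi: 1.0
b: 0.0
kappa: 2.0e-4
nu1: 1.0e-4
nu2: 1.0
L1: 1.0
L2: 0.0
R: 1.0
ST: 10.0
N: 3
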