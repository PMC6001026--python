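# Calibrated default parameter sets for the four circuit variants.
# Produced by scripts/calibrate.py (seed 0); do not edit by hand.
#
# Published constants are pinned (MRSA: k_deg=0.7, b=0.7, R=0.6, A=1.4;
# MR: R=1, k_deg=1, b=1); the remaining constants (a, a1, S, n, b1, b2)
# are calibrated so that each variant reproduces its reference regime
# sequence (bistable -> asymmetric bistable -> monostable Y) at the
# reference morphogen levels, with the initial condition (0.5, 0.01)
# inside the X basin throughout the bistable range.

[mrsa]
a = 0.95
a1 = 0.0475
b = 0.7
A = 1.4
R = 0.6
k_deg = 0.7
S = 0.76
n = 4

[sa]
a = 1.0
a1 = 0.2
b1 = 0.6
b2 = 0.2
R = 0.6
k_deg = 0.7
S = 0.9
n = 4

[mr]
a = 1.0
a1 = 0.3
b = 1.0
A = 1.4
R = 1.0
k_deg = 1.0
S = 0.5
n = 4

[mrsa_cross]
a = 1.0
a1 = 0.25
b = 0.7
A = 1.1
R = 0.6
k_deg = 0.7
S = 0.95
n = 4
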