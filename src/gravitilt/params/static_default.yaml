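# Default static-model parameters.
# K, M, rho: hierarchical-regression estimates for static roll tilt.
# theta_utricle_deg: nose-up pitch of the utricular plane.
# idiotropic_magnitude / transduction_exponent: provisional idiotropic-vector
# model constants (the published values live in an external appendix).
model: modshear
K: 64.6
M: 0.26
rho: -0.29
theta_utricle_deg: 30.0
idiotropic_magnitude: 0.1
transduction_exponent: 1.0
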