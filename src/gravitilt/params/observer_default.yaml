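# Default observer configuration.
#
# Canal time constant and feedback gains follow the published observer-model
# lineage; the utricular weight is the package's own calibration of the
# out-of-plane otolith-error scale to the 20 deg roll / 2 G steady-state
# case (target 27.55 deg, the modified-shear prediction standing in for the
# raw datum).  Steady-state tilt predictions after that calibration are
# insensitive to the individual gain values; the gains set the transient
# dynamics.
tau_canal_s: 5.7
gains:
  k_w: 8.0
  k_f: 4.0
  k_fw: 8.0
  k_wf: 1.0
utricular_weight: 1.9786
theta_utricle_deg: 30.0
dt_s: 0.05
settle:
  time_s: 60.0
  tol_dps: 0.001
max_horizon_s: 1800.0
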