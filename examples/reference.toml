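# Reference configuration: a small burn with slow myofibroblast apoptosis.
# Absent keys take the package defaults (all other constants at their
# reference values; free rates at the midpoints of their reported ranges).

[geometry]
c_I = 3.57     # cm, initial wound radius
c_II = 0.10    # cm, wound edge ramp half-width
I_w = 0.10     # minimum initial fibroblast/collagen fill of the wound

[parameters]
delta_M = 2e-2    # /day, myofibroblast apoptosis rate
k_rho = 1.75e-8   # g/(cells day), collagen secretion rate

[solver]
t_end = 42.0
output_interval = 1.0
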