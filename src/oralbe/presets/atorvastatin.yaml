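# Atorvastatin compound file.
# clpo tagged L/h (apparent oral clearance ~600-950 L/h in the literature).
# clint_3a4 is the retrograde-calculated in vitro intrinsic clearance
# (uL/min/pmol CYP3A4) obtained from clpo assuming fa=1, fg=0.24; it is
# accepted as an input here, not re-derived (the system enzyme abundances
# behind the published figure are proprietary).
name: atorvastatin
ionization_class: monoprotic_acid
mw: 588.2
logp: 5.7
pka: [4.46]
fu: 0.051
bp_ratio: 0.61
vss: 4.78           # L/kg, parameter estimated
clpo: 949
clpo_unit: L/h
peff: 6.12e-4       # cm/s, parameter estimated
clint_3a4: 8.28     # uL/min/pmol
jmax_pgp: 151       # pmol/cm^2/min
km_pgp: 115         # uM
raf_pgp: 8.7        # parameter estimated against clinical data
retrograde_fa: 1.0
retrograde_fg: 0.24
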