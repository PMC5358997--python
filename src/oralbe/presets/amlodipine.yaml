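# Amlodipine compound file.
# clpo is tagged L/h: the literature oral clearance of amlodipine is ~25 L/h,
# so 24.8 is read as L/h (see docs/methods.md on unit interpretation).
# vss and peff are parameter-estimated values; the vss/peff pairing between
# the two drugs is ambiguous in the source narrative and the reading used
# here (vss 13.78 L/kg, peff 1.35e-4 cm/s for amlodipine) is the one
# consistent with the drugs' known disposition.
name: amlodipine
ionization_class: diprotic_base
mw: 408.88
logp: 3.43
pka: [9.4, 1.90]
fu: 0.07
bp_ratio: 1.0
vss: 13.78          # L/kg, parameter estimated
clpo: 24.8
clpo_unit: L/h
peff: 1.35e-4       # cm/s, parameter estimated
# No CYP3A4-specific in vitro clearance; systemic clearance is back-calculated
# from clpo assuming fa from its own absorption simulation and fg = 1
# (no gut-wall metabolism modeled for amlodipine).
retrograde_fa: 0.92
retrograde_fg: 1.0
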