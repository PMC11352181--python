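name = "Ibuprofen"
S0 = 1e-4
D = 0.61e-9
rho = 1.6
pKa = 5.3
molar_mass = 206.28
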