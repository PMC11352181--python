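name = "Linezolid"
S0 = 4.3e-3
D = 0.67e-9
rho = 1.12
pKa = 1.8
molar_mass = 337.35
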