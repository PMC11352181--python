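name = "Danazol"
S0 = 1.5e-6
D = 0.68e-9
rho = 1.21
pKa = 4.7
molar_mass = 337.46
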