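name = "Ketokenazole"
S0 = 1.225e-5
D = 0.66e-9
rho = 1.38
pKa = 6.5
molar_mass = 531.43
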