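name = "Fenofibrate"
S0 = 6.9252e-7
D = 0.66e-9
rho = 1.18
pKa = 4.7
molar_mass = 360.83
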