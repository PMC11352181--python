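name = "Ketoprofen"
S0 = 2e-4
D = 0.7e-9
rho = 1.6
pKa = 4.45
molar_mass = 254.28
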