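name = "Griseofulvin"
S0 = 4.25e-5
D = 0.7e-9
rho = 1.38
pKa = 17.7
molar_mass = 352.77
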