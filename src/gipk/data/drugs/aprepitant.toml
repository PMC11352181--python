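name = "Aprepitant"
S0 = 1.94e-2
D = 0.63e-9
rho = 1.51
pKa = 9.15
molar_mass = 534.43
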