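name = "Etoricoxib"
S0 = 0.6e-4
D = 0.59e-9
rho = 1.41
pKa = 4.96
molar_mass = 358.84
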