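# Elemental data table, version 1.
# Z and A: IUPAC 2021 standard atomic weights (g/mol).
# I_eV: gas-phase mean excitation energies after ICRU Report 37.
# By default the loader rescales all I_eV by a single multiplicative factor so that
# Bragg additivity on the packaged water composition reproduces I(water) = 78.73 eV
# (condensed-phase anchoring; see docs/methods.md).
symbol,Z,A_g_mol,I_eV
H,1,1.008,19.2
C,6,12.011,78.0
N,7,14.007,82.0
O,8,15.999,95.0
F,9,18.998,115.0
Na,11,22.990,149.0
Mg,12,24.305,156.0
Al,13,26.982,166.0
Si,14,28.085,173.0
P,15,30.974,173.0
S,16,32.060,180.0
Cl,17,35.450,174.0
Ar,18,39.948,188.0
K,19,39.098,190.0
Ca,20,40.078,191.0
Ti,22,47.867,233.0
Fe,26,55.845,286.0
Zn,30,65.380,330.0
Zr,40,91.224,393.0
Ba,56,137.327,491.0
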