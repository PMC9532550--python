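# Reference single-ion scenario: 10 mm drift tube at 50 V/mm, 5 µm grid,
# 0.1 mm gate slab.  The mobility is fixed by the 1.79 ms drift time,
# K = L/(E_d·t_d); D is an independent input.  Strict SI units.
L_drift_m: 0.01
E_Vpm: 5.0e+4
dx_m: 5.0e-6
L_ion_m: 1.0e-4
S_m2: 1.0
C0: 1.0
species:
  - label: reference
    K: 1.1173e-4
    D: 2.8e-6
    q: 1.602176634e-19
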