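"""Unit conversion constants.

All geometry at the public interfaces is in mm, pressures in Pa or mmHg,
flows in ml/s and resistances in Pa s/ml.  The solver works internally in
strict SI (m, Pa, m^3/s, Pa s/m^3); these constants are the only place the
conversion factors appear.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

MM_TO_M = 1e-3
M_TO_MM = 1e3

ML_TO_M3 = 1e-6
M3_TO_ML = 1e6

# resistance: Pa s / ml  <->  Pa s / m^3
PA_S_PER_ML_TO_SI = 1.0 / ML_TO_M3
PA_S_PER_M3_TO_ML = ML_TO_M3

MM2_TO_M2 = 1e-6
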