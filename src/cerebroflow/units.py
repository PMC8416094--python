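"""Unit conversion constants.

All internal computation is SI (Pa, m^3/s, s).  Reports and configuration use
clinical units (mmHg, ml/s), converted with the constants below.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

MLPS_TO_M3PS = 1e-6
M3PS_TO_MLPS = 1e6


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p * PA_TO_MMHG


def mlps_to_m3ps(q):
    return q * MLPS_TO_M3PS


def m3ps_to_mlps(q):
    return q * M3PS_TO_MLPS
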