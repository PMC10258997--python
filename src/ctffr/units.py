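"""Unit conversions.

All internal computation is SI (m, m^3/s, Pa, Pa*s/m^3).  Clinical units
(mmHg, L/min, mm, grams) appear only at I/O boundaries.
"""

MMHG_TO_PA = 133.322
L_PER_MIN_TO_M3_PER_S = 1.0e-3 / 60.0


def mmhg_to_pa(p_mmhg):
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa):
    return p_pa / MMHG_TO_PA


def lmin_to_m3s(q_lmin):
    return q_lmin * L_PER_MIN_TO_M3_PER_S


def m3s_to_lmin(q_m3s):
    return q_m3s / L_PER_MIN_TO_M3_PER_S
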