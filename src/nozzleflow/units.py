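"""Unit conversions between table conventions (mm, kPa, uL/s) and internal SI.

All library internals are strict SI: metres, pascals, m^3/s, Pa*s^n.  Each
conversion pair multiplies and divides by the same exactly-representable
power of ten, so round trips are exact to the last bit for virtually all
inputs (IEEE-754 guarantees correct rounding of each step; the composed
round trip is identity except possibly in the last ulp).
"""

_MM = 1e3       # mm per m
_KPA = 1e3      # Pa per kPa
_UL = 1e9       # uL/s per m^3/s


def mm_to_m(x: float) -> float:
    return x / _MM


def m_to_mm(x: float) -> float:
    return x * _MM


def kpa_to_pa(x: float) -> float:
    return x * _KPA


def pa_to_kpa(x: float) -> float:
    return x / _KPA


def ul_s_to_m3_s(x: float) -> float:
    return x / _UL


def m3_s_to_ul_s(x: float) -> float:
    return x * _UL
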