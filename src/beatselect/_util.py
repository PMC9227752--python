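"""Small shared helpers."""

import math

#: class code -> canonical beat-class name
CLASS_NAMES = {
    1: "NORM",
    2: "LBBB",
    3: "RBBB",
    4: "PVC",
    5: "PAC",
    6: "VESC",
    7: "VFLT",
    8: "PACE",
}

#: WFDB annotation symbol -> class code; anything else is excluded
SYMBOL_TO_CODE = {
    "N": 1,
    "L": 2,
    "R": 3,
    "V": 4,
    "A": 5,
    "E": 6,
    "!": 7,
    "/": 8,
}


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used for every ms->samples conversion so that window lengths are
    reproducible across platforms (``round()`` banker's rounding is not).
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert a duration in milliseconds to a whole number of samples."""
    return round_half_away(ms * fs / 1000.0)
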