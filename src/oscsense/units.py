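"""SI quantity parsing for circuit configs.

Internally everything is strict SI (volts, ohms, farads, seconds).  Config
files may use engineering-suffixed strings such as ``"8.2k"``, ``"100p"``
or ``"10n"``; this module converts them to floats at load time.
"""

from __future__ import annotations

_SUFFIXES = {
    "f": 1e-15,
    "p": 1e-12,
    "n": 1e-9,
    "u": 1e-6,
    "µ": 1e-6,
    "m": 1e-3,
    "k": 1e3,
    "M": 1e6,
    "G": 1e9,
}


def parse_si(value: float | int | str) -> float:
    """Convert a number or engineering-suffixed string to a float.

    >>> parse_si("8.2k")
    8200.0
    >>> parse_si("100p")
    1e-10
    >>> parse_si(3.3)
    3.3
    """
    if isinstance(value, (int, float)):
        return float(value)
    s = value.strip()
    if not s:
        raise ValueError("empty quantity string")
    if s[-1] in _SUFFIXES:
        return float(s[:-1]) * _SUFFIXES[s[-1]]
    return float(s)


def format_si(value: float, unit: str = "") -> str:
    """Render a value with the nearest engineering prefix (for logs)."""
    if value == 0:
        return f"0 {unit}".strip()
    import math

    exp3 = int(math.floor(math.log10(abs(value)) / 3)) * 3
    exp3 = min(max(exp3, -15), 9)
    prefixes = {-15: "f", -12: "p", -9: "n", -6: "u", -3: "m", 0: "", 3: "k", 6: "M", 9: "G"}
    return f"{value / 10**exp3:.4g} {prefixes[exp3]}{unit}".strip()
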