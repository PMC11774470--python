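"""Small unit helpers.

All public APIs in this package take SI units (metres, seconds, Pa, mol).
These helpers make call sites that start from device drawings (μm) or
bench protocols (μL/min) explicit about the conversion.
"""

from __future__ import annotations

UM = 1e-6  # metre per micrometre
PMOL = 1e-12  # mole per picomole


def um(value: float) -> float:
    """Micrometres → metres."""
    return value * 1e-6


def ul_per_min(value: float) -> float:
    """Microlitres per minute → m³/s."""
    return value * 1e-9 / 60.0


def pmol_per_s(value: float) -> float:
    """pmol/s → mol/s."""
    return value * 1e-12
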