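"""Reference toxicant parameters for the chip-based 48 h immobilization assay.

On-chip 48 h median effect concentrations for the four validation
toxicants, with the concentration ranges used to bracket them in a
7-point log-spaced design (n = 15 animals per concentration).  The Hill
slope of the generative immobilization model is 2 for all toxicants.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ToxicantPreset", "REFERENCE_TOXICANTS", "DEFAULT_HILL_SLOPE"]

DEFAULT_HILL_SLOPE = 2.0


@dataclass(frozen=True)
class ToxicantPreset:
    name: str
    ec50: float
    units: str
    conc_min: float
    conc_max: float
    hill_slope: float = DEFAULT_HILL_SLOPE


REFERENCE_TOXICANTS: dict[str, ToxicantPreset] = {
    "copper": ToxicantPreset("copper", 0.15, "mg/L", 0.01, 1.0),
    "dichromate": ToxicantPreset("dichromate", 0.53, "mg/L", 0.05, 5.0),
    "caffeine": ToxicantPreset("caffeine", 210.8, "mg/L", 20.0, 1200.0),
    "ethanol": ToxicantPreset("ethanol", 1.7, "% v/v", 0.075, 4.0),
}
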