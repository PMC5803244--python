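"""Positron-emitter decay components."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import NUCLIDE_DATA

__all__ = ["DecayComponent", "get_component", "default_components"]


@dataclass(frozen=True)
class DecayComponent:
    """One beta+ emitter: identity, decay clock and positron spectrum endpoint."""

    isotope: str
    half_life_s: float
    positron_endpoint_mev: float
    branching_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.half_life_s <= 0:
            raise ValueError("half-life must be positive")
        if not (0.0 < self.branching_ratio <= 1.0):
            raise ValueError("branching ratio must be in (0, 1]")
        if self.positron_endpoint_mev <= 0:
            raise ValueError("endpoint energy must be positive")

    @property
    def decay_constant(self) -> float:
        """lambda = ln 2 / T_1/2, exactly."""
        return math.log(2.0) / self.half_life_s


def get_component(isotope: str) -> DecayComponent:
    if isotope not in NUCLIDE_DATA:
        raise KeyError(f"unknown isotope {isotope!r}; known: {sorted(NUCLIDE_DATA)}")
    d = NUCLIDE_DATA[isotope]
    return DecayComponent(isotope=isotope, **d)


def default_components(include_14o: bool = False) -> list[DecayComponent]:
    """The three oxygen-derived emitters that survive past 120 s; 14O decays
    away before the analysis window opens and is off by default."""
    labels = ["15O", "13N", "11C"] + (["14O"] if include_14o else [])
    return [get_component(s) for s in labels]
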