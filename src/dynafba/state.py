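"""Fermentation state and temperature profiles.

Canonical extracellular species ids used by the simulator's kinetic layer
(models loaded from files must use these ids for the species they track):
``glc``/``fru`` (sugars, g/L), ``etoh`` (ethanol, g/L), ``glyc`` (glycerol),
``ac`` (acetate), ``nh4``/``aa`` (nitrogen compounds, mg N/L), ``co2``
(cumulative evolved CO2, g/L of medium).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import NegativeConcentrationError, UnorderedProfileError

GLUCOSE = "glc"
FRUCTOSE = "fru"
ETHANOL = "etoh"
SUGARS = (GLUCOSE, FRUCTOSE)


@dataclass
class FermentationState:
    """Snapshot of the bioreactor: time, temperature, biomass and medium.

    ``M_EX`` maps species id to concentration (sugars and products in g/L,
    nitrogen compounds in mg N/L).  ``yan0`` is the *initial* assimilable
    nitrogen of the culture — a culture-level property used by the sluggish
    maintenance term, deliberately not the instantaneous YAN.
    """

    t: float  # h
    T: float  # degC
    X_V: float  # gDW/L viable biomass
    M_EX: dict[str, float] = field(default_factory=dict)
    f_consumed: float = 0.0  # fraction of initial sugar consumed
    yan0: float | None = None

    def __post_init__(self):
        for sp, conc in self.M_EX.items():
            if conc < 0:
                raise NegativeConcentrationError(f"{sp}: concentration {conc} < 0")
        if not 0.0 <= self.f_consumed <= 1.0 + 1e-12:
            raise NegativeConcentrationError(f"f_consumed {self.f_consumed} outside [0,1]")

    def conc(self, species: str) -> float:
        return self.M_EX.get(species, 0.0)

    @property
    def total_sugar(self) -> float:
        return sum(self.conc(s) for s in SUGARS)

    def yan(self, nitrogen_species: list[str]) -> float:
        """Current yeast assimilable nitrogen (mg N/L)."""
        return sum(self.conc(s) for s in nitrogen_species)

    def copy(self, **changes) -> "FermentationState":
        new = replace(self, M_EX=dict(self.M_EX))
        for k, v in changes.items():
            setattr(new, k, v)
        return new


def temperature_at(profile, t: float) -> float:
    """Temperature (degC) at time ``t`` from a constant or piecewise profile.

    ``profile`` is a number (isothermal) or a sequence of ``(t_h, degC)``
    pairs; piecewise-linear interpolation with constant extrapolation beyond
    the endpoints.
    """
    if np.isscalar(profile):
        return float(profile)
    pts = [(float(a), float(b)) for a, b in profile]
    times = [a for a, _ in pts]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise UnorderedProfileError(f"profile times not strictly increasing: {times}")
    temps = [b for _, b in pts]
    return float(np.interp(t, times, temps))
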