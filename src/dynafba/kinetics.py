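"""Dynamic kinetic constraints: sugar and nitrogen uptake, ATP maintenance,
and the time-medium-specific biomass equation.

These functions map the current :class:`~dynafba.state.FermentationState` to
flux bounds for the LP.  The functional forms are closed-form saturation and
hinge expressions whose dependencies follow the experimentally observed
physiology of wine fermentations:

* hexose transport — Michaelis-Menten with competitive inhibition between
  glucose and fructose, non-competitive inhibition by ethanol, and Arrhenius
  temperature scaling of vmax;
* nitrogen transport — a single saturable total-YAN uptake capacity shared
  among nitrogen compounds in proportion to their share of current YAN
  (competition for a limited transporter pool);
* maintenance ATP — a base cost plus hinge terms above an ethanol and a
  temperature threshold, plus a constant surcharge for nitrogen-deficient
  (sluggish) cultures;
* carbohydrate storage — a smooth monotone accumulation with sugar
  consumption, which reshapes the biomass equation over time.

All default parameter values are packaged (``data/defaults.yaml``) and
overridable from the simulation config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import (
    InvalidFractionError,
    NegativeConcentrationError,
    ZeroNitrogenContentError,
)
from .model import INF, Reaction
from .state import ETHANOL, FRUCTOSE, GLUCOSE, FermentationState

R_GAS = 8.314  # J/mol/K


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class SugarKinetics:
    vmax_ref_glc: float = 4.2  # mmol/gDW/h at T_ref
    vmax_ref_fru: float = 4.0
    Kg: float = 1.0  # g/L, glucose half-saturation
    Kf: float = 2.0  # g/L, fructose half-saturation (lower affinity)
    Kig_f: float = 20.0  # g/L, fructose inhibition of glucose uptake
    Kif_g: float = 10.0  # g/L, glucose inhibition of fructose uptake
    Ki_eth: float = 150.0  # g/L, non-competitive ethanol inhibition
    Ea: float = 60000.0  # J/mol, activation energy of transport
    T_ref: float = 28.0  # degC


@dataclass
class NitrogenKinetics:
    vmax_N: float = 35.0  # mg N/gDW/h, total YAN uptake capacity
    K_N: float = 30.0  # mg N/L


@dataclass
class MaintenanceKinetics:
    m0: float = 1.2  # mmol ATP/gDW/h, base maintenance
    a_eth: float = 0.01  # mmol ATP/gDW/h per g/L ethanol above threshold
    E_thr: float = 31.6  # g/L (~4% v/v)
    a_T: float = 0.12  # mmol ATP/gDW/h per degC above threshold
    T_thr: float = 30.0  # degC
    a_sluggish: float = 1.0  # mmol ATP/gDW/h surcharge
    N_sluggish: float = 140.0  # mg N/L initial-YAN trigger
    legacy_value: float = 1.0  # mmol ATP/gDW/h, constant legacy maintenance


@dataclass
class CarbohydrateKinetics:
    c_min: float = 0.25  # g/gDW at f_consumed = 0
    c_max: float = 0.45  # g/gDW at f_consumed = 1
    k_c: float = 2.0  # shape exponent

    def __post_init__(self):
        if not 0 < self.c_min < self.c_max < 1:
            raise InvalidFractionError("require 0 < c_min < c_max < 1")


@dataclass
class KineticParameters:
    sugar: SugarKinetics = field(default_factory=SugarKinetics)
    nitrogen: NitrogenKinetics = field(default_factory=NitrogenKinetics)
    maintenance: MaintenanceKinetics = field(default_factory=MaintenanceKinetics)
    carbohydrate: CarbohydrateKinetics = field(default_factory=CarbohydrateKinetics)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(
            sugar=SugarKinetics(**d.get("sugar", {})),
            nitrogen=NitrogenKinetics(**d.get("nitrogen", {})),
            maintenance=MaintenanceKinetics(**d.get("maintenance", {})),
            carbohydrate=CarbohydrateKinetics(**d.get("carbohydrate", {})),
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass(frozen=True)
class NitrogenCompound:
    """An assimilable nitrogen source and its nitrogen content."""

    species: str  # extracellular species id (tracked in mg N/L)
    mg_n_per_mmol: float  # e.g. 14.0 for ammonia (one N per molecule)

    def __post_init__(self):
        if self.mg_n_per_mmol <= 0:
            raise ZeroNitrogenContentError(
                f"compound {self.species}: mg N per mmol must be > 0"
            )


# ---------------------------------------------------------------------------
# Uptake kinetics
# ---------------------------------------------------------------------------


def arrhenius_factor(T: float, Ea: float, T_ref: float) -> float:
    """vmax(T)/vmax(T_ref) = exp(-Ea/R * (1/T_K - 1/T_ref_K))."""
    return math.exp(-Ea / R_GAS * (1.0 / (T + 273.15) - 1.0 / (T_ref + 273.15)))


def sugar_uptake_bounds(
    state: FermentationState, p: KineticParameters
) -> tuple[float, float]:
    """Maximum specific glucose and fructose uptake rates (mmol/gDW/h).

    ub_glc = vmax_glc(T) * G / (Kg*(1 + F/Kig_f) + G) * Ki_eth/(Ki_eth + E)
    and symmetrically for fructose.  Returns 0 for an absent sugar.
    """
    G, F, E = state.conc(GLUCOSE), state.conc(FRUCTOSE), state.conc(ETHANOL)
    for name, c in (("glucose", G), ("fructose", F), ("ethanol", E)):
        if c < 0:
            raise NegativeConcentrationError(f"{name} concentration {c} < 0")
    if not 0.0 <= state.T <= 50.0:
        raise NegativeConcentrationError(f"temperature {state.T} outside 0-50 degC")
    s = p.sugar
    temp = arrhenius_factor(state.T, s.Ea, s.T_ref)
    eth_inh = s.Ki_eth / (s.Ki_eth + E)
    ub_glc = 0.0
    if G > 0:
        ub_glc = s.vmax_ref_glc * temp * G / (s.Kg * (1 + F / s.Kig_f) + G) * eth_inh
    ub_fru = 0.0
    if F > 0:
        ub_fru = s.vmax_ref_fru * temp * F / (s.Kf * (1 + G / s.Kif_g) + F) * eth_inh
    return ub_glc, ub_fru


def nitrogen_uptake_bounds(
    state: FermentationState,
    p: KineticParameters,
    compounds: list[NitrogenCompound],
) -> dict[str, float]:
    """Per-compound maximum uptake rates (mmol/gDW/h).

    The total nitrogen flux v_N = vmax_N * YAN/(K_N + YAN) (mg N/gDW/h) is
    shared among compounds in proportion to their fraction of current YAN,
    then converted to molar flux by each compound's nitrogen content.  The
    allocation conserves total nitrogen flux exactly.
    """
    for c in compounds:
        if c.mg_n_per_mmol <= 0:
            raise ZeroNitrogenContentError(f"compound {c.species} declares no nitrogen")
    yan = sum(state.conc(c.species) for c in compounds)
    if yan <= 0:
        return {c.species: 0.0 for c in compounds}
    n = p.nitrogen
    v_N = n.vmax_N * yan / (n.K_N + yan)  # mg N/gDW/h
    return {
        c.species: v_N * (state.conc(c.species) / yan) / c.mg_n_per_mmol
        for c in compounds
    }


def maintenance_lower_bound(
    state: FermentationState, p: KineticParameters, legacy: bool = False
) -> float:
    """Lower bound on the maintenance ATP flux (mmol ATP/gDW/h).

    m_ATP = m0 + a_eth*max(0, E - E_thr) + a_T*max(0, T - T_thr)
          + a_sluggish*[YAN0 < N_sluggish]

    The sluggish surcharge keys on the culture's *initial* YAN so maintenance
    does not jump when nitrogen is consumed in a normally-fed fermentation.
    ``legacy=True`` returns the constant value used by earlier genome-scale
    models (1 mmol/gDW/h) for ablation comparisons.
    """
    m = p.maintenance
    if legacy:
        return m.legacy_value
    E = state.conc(ETHANOL)
    cost = m.m0 + m.a_eth * max(0.0, E - m.E_thr) + m.a_T * max(0.0, state.T - m.T_thr)
    if state.yan0 is not None and state.yan0 < m.N_sluggish:
        cost += m.a_sluggish
    return cost


# ---------------------------------------------------------------------------
# Biomass composition
# ---------------------------------------------------------------------------


def carbohydrate_fraction(f: float, p: KineticParameters) -> float:
    """Storage-carbohydrate mass fraction (g/gDW) at sugar-consumption fraction f.

    c(f) = c_min + (c_max - c_min) * f**k_c — smooth, monotone non-decreasing,
    bounded by [c_min, c_max].
    """
    if not 0.0 <= f <= 1.0:
        raise InvalidFractionError(f"fraction consumed {f} outside [0,1]")
    c = p.carbohydrate
    return c.c_min + (c.c_max - c.c_min) * f**c.k_c


@dataclass
class BiomassComposition:
    """Macromolecular mass fractions (g/gDW) plus the ATP cost of polymerization.

    Fractions must sum to 1 within 1e-6.  ``atp_cost`` is the growth-associated
    ATP requirement (mmol ATP per gDW of biomass formed).
    """

    protein: float
    carbohydrate: float
    lipid: float
    rna: float
    dna: float
    atp_cost: float = 30.0

    def __post_init__(self):
        total = self.protein + self.carbohydrate + self.lipid + self.rna + self.dna
        if abs(total - 1.0) > 1e-6:
            raise InvalidFractionError(f"mass fractions sum to {total}, not 1")

    def fractions(self) -> dict[str, float]:
        return {
            "protein": self.protein,
            "carbohydrate": self.carbohydrate,
            "lipid": self.lipid,
            "rna": self.rna,
            "dna": self.dna,
        }


@dataclass(frozen=True)
class Precursor:
    """A biomass precursor metabolite and its molar mass (g/mol)."""

    metabolite_id: str
    mw: float


@dataclass
class PrecursorSet:
    """Model-specific mapping from composition fractions to precursor drains.

    ``precursors`` maps fraction names (protein, carbohydrate, lipid, rna,
    dna) to the metabolite drained for that fraction; two fractions may share
    a precursor (e.g. a toy model pooling RNA and DNA into one nucleotide
    unit).  ``carve_outs`` lets a fixed mass (g/gDW) of a fraction be diverted
    to a distinct precursor (e.g. a sterol requirement inside the lipid
    fraction).  ``atp``/``adp``/``pi``/``h2o`` are the currency metabolite ids
    used for the polymerization cost.
    """

    precursors: dict[str, Precursor]
    atp: str = "atp"
    adp: str = "adp"
    pi: str = "pi"
    h2o: str = "h2o"
    carve_outs: dict[str, tuple[Precursor, float]] = field(default_factory=dict)


def biomass_equation(
    f_consumed: float,
    composition: BiomassComposition,
    p: KineticParameters,
    precursors: PrecursorSet,
    legacy: bool = False,
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Build the biomass pseudo-reaction for the current fermentation stage.

    Unless ``legacy`` is set, the carbohydrate fraction is replaced by
    :func:`carbohydrate_fraction` at the current sugar-consumption fraction and
    the remaining fractions are rescaled proportionally so the composition
    still sums to 1 (the time-medium-specific biomass equation).  With
    ``legacy=True`` the composition is used as given, time-invariantly.

    Precursor coefficients are fraction/MW in mmol per gDW; the reaction's flux
    is therefore the specific growth rate in 1/h.
    """
    if p.carbohydrate.c_max >= 1.0:
        raise InvalidFractionError("c_max must be < 1 for a valid composition")
    base = composition.fractions()
    if legacy:
        fracs = dict(base)
    else:
        carb = carbohydrate_fraction(f_consumed, p)
        rest0 = 1.0 - base["carbohydrate"]
        scale = (1.0 - carb) / rest0
        fracs = {k: v * scale for k, v in base.items() if k != "carbohydrate"}
        fracs["carbohydrate"] = carb
    stoich: dict[str, float] = {}
    for name, frac in fracs.items():
        pre = precursors.precursors[name]
        if name in precursors.carve_outs:
            extra_pre, extra_mass = precursors.carve_outs[name]
            if extra_mass >= frac:
                raise InvalidFractionError(
                    f"carve-out {extra_mass} g/gDW exceeds {name} fraction {frac}"
                )
            stoich[extra_pre.metabolite_id] = (
                stoich.get(extra_pre.metabolite_id, 0.0) - extra_mass * 1000.0 / extra_pre.mw
            )
            frac = frac - extra_mass
        stoich[pre.metabolite_id] = stoich.get(pre.metabolite_id, 0.0) - frac * 1000.0 / pre.mw
    gam = composition.atp_cost
    stoich[precursors.atp] = stoich.get(precursors.atp, 0.0) - gam
    stoich[precursors.h2o] = stoich.get(precursors.h2o, 0.0) - gam
    stoich[precursors.adp] = stoich.get(precursors.adp, 0.0) + gam
    stoich[precursors.pi] = stoich.get(precursors.pi, 0.0) + gam
    return Reaction(
        id=reaction_id,
        name="biomass synthesis",
        stoichiometry=stoich,
        lb=0.0,
        ub=INF,
        tags=frozenset({"biomass"}),
    )
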