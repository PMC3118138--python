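"""Toy anaerobic yeast network and synthetic experimental datasets.

The toy network is a ~40-reaction, elementally balanced caricature of wine-yeast
fermentative metabolism, built so that every constraint the simulator applies
has a visible, auditable consequence:

* fermentative core — glucose -> 2 ethanol + 2 CO2 with 2 ATP and a closed
  NADH loop (glycolysis +2 NADH, alcohol dehydrogenase -2 NADH);
* biomass synthesis produces *excess* NADH (amino-acid and nucleotide synthesis
  from sugar and ammonia are oxidative), so anaerobic growth REQUIRES the
  glycerol branch as a redox valve — the coupling on which all glycerol
  predictions rest;
* a TCA cycle present as two branches: the succinate-dehydrogenase and
  succinyl-CoA-ligase steps are tagged ``tca_oxidative_break`` and pinned to
  zero under anaerobiosis (the split cycle); un-pinning them opens a
  reductive route to secreted succinate that sinks 2 NADH per succinate;
* quinone-tagged reactions that reoxidize NADH/FADH2 as pure electron sinks
  (no oxygen precursor), off under the anaerobic set;
* oxygen uptake and respiration, off under the anaerobic set;
* sterol: required by biomass in trace amount, synthesizable only with
  oxygen, so anaerobic growth needs the sterol-uptake relaxation;
* trace acetoin/butanediol sinks and a maintenance ATP hydrolysis reaction.

Metabolite formulas use integer-friendly molar masses so carbon closure can be
audited by hand.  The quinone sinks (NADH -> NAD+ + H) are elementally balanced
but deliberately not redox-balanced: they model electron disposal into an
acceptor pool outside the network boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DisconnectedNetworkError, EmptyTrajectoryError
from .kinetics import BiomassComposition, Precursor, PrecursorSet
from .model import INF, MetabolicModel, Metabolite, Reaction


@dataclass
class ToyNetworkSpec:
    """Subsystem switches and yield parameters for the toy network."""

    glycerol_branch: bool = True
    ethanol_branch: bool = True
    acetate: bool = True
    tca_branches: bool = True
    quinones: bool = True
    respiration: bool = True
    sterol: bool = True
    acetoin_butanediol: bool = True
    maintenance: bool = True
    biomass: bool = True
    atp_per_glucose: float = 2.0  # glycolytic substrate-level ATP yield
    nadh_per_glucose: float = 2.0  # glycolytic NADH yield
    trace_flux_cap: float = 0.05  # mmol/gDW/h, cap on trace by-product routes
    succinate_cap: float = 0.002  # mmol/gDW/h, cap on succinate secretion
    maintenance_nadh_yield: float = 0.12  # mol NADH released per mol maintenance ATP


#: Base biomass composition of the toy cell (g/gDW); the carbohydrate
#: fraction is replaced dynamically by the storage-accumulation expression.
TOY_COMPOSITION = BiomassComposition(
    protein=0.40, carbohydrate=0.35, lipid=0.08, rna=0.12, dna=0.05, atp_cost=60.0
)

#: Fixed sterol requirement carved out of the lipid fraction (g/gDW).
STEROL_MASS_FRACTION = 0.005

TOY_PRECURSORS = PrecursorSet(
    precursors={
        "protein": Precursor("protU", 57.0),
        "carbohydrate": Precursor("carbU", 162.0),
        "lipid": Precursor("lipU", 84.0),
        "rna": Precursor("nucU", 242.0),
        "dna": Precursor("nucU", 242.0),  # pooled nucleotide unit
    },
    carve_outs={"lipid": (Precursor("sterol_c", 98.0), STEROL_MASS_FRACTION)},
)


def _metabolites() -> list[Metabolite]:
    ex = [
        # id, name, formula, mw(g/mol)
        ("glc", "glucose", "C6H12O6", 180.0),
        ("fru", "fructose", "C6H12O6", 180.0),
        ("nh4", "ammonia", "NH3", 17.0),
        ("aa", "amino acid pool", "C2H5NO2", 75.0),
        ("etoh", "ethanol", "C2H6O", 46.0),
        ("glyc", "glycerol", "C3H8O3", 92.0),
        ("ac", "acetate", "C2H4O2", 60.0),
        ("succ", "succinate", "C4H6O4", 118.0),
        ("co2", "carbon dioxide", "CO2", 44.0),
        ("actn", "acetoin", "C4H8O2", 88.0),
        ("btd", "2,3-butanediol", "C4H10O2", 90.0),
        ("sterol_e", "sterol (medium)", "C6H10O", 98.0),
        ("h2o", "water", "H2O", 18.0),
        ("h", "proton", "H", 1.0),
        ("o2", "oxygen", "O2", 32.0),
    ]
    cyt = [
        ("pyr", "pyruvate", "C3H4O3"),
        ("acald", "acetaldehyde", "C2H4O"),
        ("oaa", "oxaloacetate", "C4H4O5"),
        ("akg", "2-oxoglutarate", "C5H6O5"),
        ("mal", "malate", "C4H6O5"),
        ("fum", "fumarate", "C4H4O4"),
        ("sterol_c", "sterol (cell)", "C6H10O"),
        ("atp", "ATP", "C10H16N5O13P3"),
        ("adp", "ADP", "C10H15N5O10P2"),
        ("pi", "phosphate", "H3PO4"),
        ("nad", "NAD+", "C21H27N7O14P2"),
        ("nadh", "NADH", "C21H28N7O14P2"),
        ("fad", "FAD", "C27H33N9O15P2"),
        ("fadh2", "FADH2", "C27H35N9O15P2"),
        ("carbU", "carbohydrate unit", "C6H10O5"),
        ("protU", "protein unit", "C2H3NO"),
        ("lipU", "lipid unit", "C5H8O"),
        ("nucU", "nucleotide unit", "C8H10N4O5"),
    ]
    mets = [
        Metabolite(id=i, name=n, compartment="e", formula=f, mw=mw, is_extracellular=True)
        for i, n, f, mw in ex
    ]
    mets += [Metabolite(id=i, name=n, compartment="c", formula=f) for i, n, f in cyt]
    return mets


def _rxn(rid, name, eq, lb=None, ub=None, genes=None, tags=()):
    from .model import parse_equation

    stoich, reversible = parse_equation(eq)
    lo = lb if lb is not None else (-INF if reversible else 0.0)
    hi = ub if ub is not None else INF
    return Reaction(
        id=rid, name=name, stoichiometry=stoich, lb=lo, ub=hi, genes=genes,
        tags=frozenset(tags),
    )


def make_toy_network(spec: ToyNetworkSpec | None = None) -> MetabolicModel:
    """Build the toy model; raises DisconnectedNetworkError if the enabled
    subsystems cannot support growth even under fully relaxed aerobic bounds.
    """
    spec = spec or ToyNetworkSpec()
    rxns: list[Reaction] = []

    # exchange reactions (uptake negative, secretion positive)
    def ex(species, rid, lb, ub, tags=()):
        rxns.append(
            Reaction(
                id=rid, name=f"{species} exchange", stoichiometry={species: -1.0},
                lb=lb, ub=ub, tags=frozenset(set(tags) | {"exchange"}),
            )
        )

    ex("glc", "EX_glc", -INF, 0.0, {"hexose_uptake"})
    ex("fru", "EX_fru", -INF, 0.0, {"hexose_uptake"})
    ex("nh4", "EX_nh4", -INF, 0.0, {"nitrogen_uptake"})
    ex("aa", "EX_aa", -INF, 0.0, {"nitrogen_uptake"})
    ex("etoh", "EX_etoh", 0.0, INF)
    if spec.glycerol_branch:
        ex("glyc", "EX_glyc", 0.0, INF)
    if spec.acetate:
        # secretion capped at a trace overflow; uptake allowed so engineered
        # acetate-consuming strains can be simulated
        ex("ac", "EX_ac", -INF, spec.trace_flux_cap)
    if spec.tca_branches:
        ex("succ", "EX_succ", 0.0, spec.succinate_cap)
    ex("co2", "EX_co2", 0.0, INF)
    if spec.acetoin_butanediol:
        ex("actn", "EX_actn", 0.0, INF)
        ex("btd", "EX_btd", 0.0, INF)
    if spec.sterol:
        ex("sterol_e", "EX_sterol", -INF, 0.0)
    ex("h2o", "EX_h2o", -INF, INF)
    ex("h", "EX_h", -INF, INF)
    if spec.respiration:
        ex("o2", "EX_o2", -INF, INF, {"oxygen_uptake"})

    # fermentative core
    g = spec.atp_per_glucose
    rxns.append(
        _rxn(
            "GLYCO", "glycolysis (lumped)",
            f"glc + {g:g} adp + {g:g} pi + {spec.nadh_per_glucose:g} nad -> "
            f"2 pyr + {g:g} atp + {spec.nadh_per_glucose:g} nadh + "
            f"{spec.nadh_per_glucose:g} h + {g:g} h2o",
        )
    )
    rxns.append(_rxn("FRUISO", "fructose isomerization", "fru -> glc"))
    if spec.ethanol_branch:
        rxns.append(_rxn("PDC", "pyruvate decarboxylase", "pyr -> acald + co2"))
        rxns.append(_rxn("ADH", "alcohol dehydrogenase", "acald + nadh + h -> etoh + nad"))
    if spec.acetate:
        rxns.append(_rxn("ALD", "acetaldehyde dehydrogenase", "acald + nad + h2o -> ac + nadh + h"))
    if spec.glycerol_branch:
        rxns.append(
            _rxn(
                "GPD", "glycerol branch (lumped)",
                "glc + 2 atp + 2 nadh + 2 h + 2 h2o -> 2 glyc + 2 adp + 2 pi + 2 nad",
                genes="GPD1 or GPD2",
            )
        )
    if spec.maintenance:
        # maintenance as an oxidative-turnover lump: besides hydrolysing ATP,
        # upkeep (protein/membrane turnover) oxidizes a little sugar and
        # releases reducing equivalents that must be re-oxidized elsewhere
        f = spec.maintenance_nadh_yield
        rxns.append(
            _rxn("ATPM", "maintenance (ATP hydrolysis + turnover oxidation)",
                 f"atp + {1 + f / 2:g} h2o + {f / 12:g} glc + {f:g} nad -> "
                 f"adp + pi + {f / 2:g} co2 + {f:g} nadh + {f:g} h",
                 tags=("maintenance_atp",))
        )
        # futile ATP hydrolysis absorbing surplus ATP without byproducts
        rxns.append(_rxn("ATPSLIP", "uncoupled ATP hydrolysis", "atp + h2o -> adp + pi"))

    # biomass precursor synthesis
    rxns.append(_rxn("CARBS", "storage carbohydrate synthesis", "glc + atp -> carbU + adp + pi"))
    rxns.append(_rxn("PROTS", "protein synthesis", "aa + 2 atp + h2o -> protU + 2 adp + 2 pi"))
    rxns.append(
        _rxn("AAS", "amino acid synthesis",
             "0.5 glc + nh4 + h2o + 2 nad -> aa + co2 + 2 nadh + 4 h")
    )
    rxns.append(
        _rxn("LIPS", "lipid synthesis",
             "glc + nadh + h + 2 atp -> lipU + co2 + nad + h2o + 2 adp + 2 pi")
    )
    rxns.append(
        _rxn("NUCS", "nucleotide synthesis",
             "1.5 glc + 4 nh4 + 8 nad + 6 atp + 4 h2o -> nucU + co2 + 8 nadh + 8 h + 6 adp + 6 pi")
    )

    if spec.acetoin_butanediol:
        rxns.append(
            _rxn("ACTNS", "acetoin synthase", "2 pyr -> actn + 2 co2", ub=spec.trace_flux_cap)
        )
        rxns.append(_rxn("BDH", "butanediol dehydrogenase", "actn + nadh + h -> btd + nad"))

    if spec.sterol:
        rxns.append(
            _rxn("STEROLS", "sterol synthesis (O2-dependent)",
                 "glc + 5 nadh + 5 h + 0.5 o2 -> sterol_c + 5 nad + 6 h2o")
        )
        rxns.append(
            _rxn("STEROLt", "sterol uptake", "sterol_e -> sterol_c", ub=0.0,
                 tags=("sterol_uptake",))
        )

    if spec.tca_branches:
        rxns.append(_rxn("PYC", "pyruvate carboxylase", "pyr + co2 + atp + h2o -> oaa + adp + pi"))
        rxns.append(
            _rxn("TCAOX1", "oxidative branch to 2-oxoglutarate",
                 "pyr + oaa + 2 nad + h2o <-> akg + 2 co2 + 2 nadh + 2 h")
        )
        rxns.append(
            _rxn("SCL", "2-oxoglutarate <-> succinate (succinyl-CoA ligase lump)",
                 "akg + nad + adp + pi <-> succ + co2 + nadh + h + atp",
                 genes="LSC1 and LSC2", tags=("tca_oxidative_break",))
        )
        rxns.append(
            _rxn("SDH", "succinate dehydrogenase", "succ + fad <-> fum + fadh2",
                 genes="SDH1 and SDH2", tags=("tca_oxidative_break",))
        )
        rxns.append(_rxn("FUMR", "fumarase", "mal <-> fum + h2o"))
        rxns.append(_rxn("MDH", "malate dehydrogenase", "oaa + nadh + h <-> mal + nad"))
        rxns.append(
            _rxn("FRD", "fumarate reductase (NADH-linked, reductive branch)",
                 "fum + nadh + h -> succ + nad")
        )

    if spec.quinones:
        rxns.append(
            _rxn("QNADH", "quinone-mediated NADH reoxidation", "nadh -> nad + h",
                 tags=("quinone",))
        )
        rxns.append(
            _rxn("QFADH", "quinone-mediated FADH2 reoxidation", "fadh2 -> fad + 2 h",
                 tags=("quinone",))
        )

    if spec.respiration:
        rxns.append(
            _rxn("RESPN", "NADH oxidase + oxidative phosphorylation",
                 "nadh + h + 0.5 o2 + 1.5 adp + 1.5 pi -> nad + 2.5 h2o + 1.5 atp")
        )
        rxns.append(
            _rxn("RESPF", "FADH2 oxidase + oxidative phosphorylation",
                 "fadh2 + 0.5 o2 + adp + pi -> fad + 2 h2o + atp")
        )

    if spec.biomass:
        rxns.append(toy_biomass_reaction(0.0))

    model = MetabolicModel(_metabolites(), rxns)
    _check_connected(model, spec)
    return model


def toy_biomass_reaction(f_consumed: float, legacy: bool = False) -> Reaction:
    """The toy biomass equation at sugar-consumption fraction ``f_consumed``."""
    from .kinetics import KineticParameters, biomass_equation

    return biomass_equation(
        f_consumed, TOY_COMPOSITION, KineticParameters(), TOY_PRECURSORS, legacy=legacy
    )


def _check_connected(model: MetabolicModel, spec: ToyNetworkSpec) -> None:
    if not spec.biomass:
        return
    from .fba import Objective, solve_fba

    dist = solve_fba(model, None, Objective("max", "BIOMASS"))
    if not dist.optimal or dist.objective_value < 1e-9:
        raise DisconnectedNetworkError(
            "enabled subsystems do not admit growth under relaxed aerobic bounds"
        )


def biomass_carbon_fraction(f_consumed: float, legacy: bool = False) -> float:
    """g carbon per gDW of toy biomass at the given consumption fraction."""
    carbon_per_unit = {  # g C per g of precursor
        "carbU": 72.0 / 162.0,
        "protU": 24.0 / 57.0,
        "lipU": 60.0 / 84.0,
        "nucU": 96.0 / 242.0,
        "sterol_c": 72.0 / 98.0,
    }
    mw = {"carbU": 162.0, "protU": 57.0, "lipU": 84.0, "nucU": 242.0, "sterol_c": 98.0}
    rxn = toy_biomass_reaction(f_consumed, legacy=legacy)
    total = 0.0
    for mid, coef in rxn.stoichiometry.items():
        if mid in carbon_per_unit and coef < 0:
            total += (-coef) * mw[mid] / 1000.0 * carbon_per_unit[mid]
    return total


def default_config(**overrides) -> "SimulationConfig":
    """A ready-to-run simulation config for the toy network.

    The benchmark condition is an isothermal 28 degC fermentation of a
    233 g/L sugar, 300 mg N/L must — a standard laboratory wine fermentation.
    """
    from .simulate import SimulationConfig

    cfg = SimulationConfig(
        composition=TOY_COMPOSITION,
        precursors=TOY_PRECURSORS,
        carbon_fraction_fn=biomass_carbon_fraction,
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


def default_initial_state(
    sugar: float = 233.0,
    yan: float = 300.0,
    temperature: float = 28.0,
    biomass: float = 0.1,
) -> "FermentationState":
    """The benchmark initial state: equal glucose/fructose must, 40/60
    ammonia/amino-acid nitrogen, trace sterol supplement."""
    from .state import FermentationState

    return FermentationState(
        t=0.0,
        T=temperature,
        X_V=biomass,
        M_EX={
            "glc": sugar / 2.0,
            "fru": sugar / 2.0,
            "nh4": 0.4 * yan,
            "aa": 0.6 * yan,
            "etoh": 0.0,
            "glyc": 0.0,
            "ac": 0.0,
            "succ": 0.0,
            "co2": 0.0,
            "actn": 0.0,
            "btd": 0.0,
            "sterol_e": 0.05,
        },
    )


def make_synthetic_experiment(
    traj, cv: float, n_points: int, seed: int, species: list[str] | None = None
) -> pd.DataFrame:
    """Sample a trajectory into a noisy tidy 'experimental' dataset.

    Emulates triplicate measurements with a given coefficient of variation:
    multiplicative Gaussian noise, clamped at zero, deterministic per seed.
    Returns a tidy frame (time_h, species, value, unit).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_points < 3:
        raise ValueError("need at least 3 sample points")
    df = traj.to_dataframe()
    if df.empty:
        raise EmptyTrajectoryError("trajectory has no states")
    rng = np.random.default_rng(seed)
    times = np.linspace(df["time_h"].iloc[0], df["time_h"].iloc[-1], n_points)
    skip = {"time_h", "temperature_C"}
    cols = [c for c in df.columns if c not in skip]
    if species is not None:
        cols = [c for c in cols if c in species]
    rows = []
    for col in cols:
        clean = np.interp(times, df["time_h"], df[col])
        noisy = np.maximum(0.0, clean * (1.0 + cv * rng.standard_normal(n_points)))
        unit = "mg N/L" if col in ("nh4", "aa") else ("gDW/L" if col == "biomass_gDW_L" else "g/L")
        rows += [
            {"time_h": t, "species": col, "value": v, "unit": unit}
            for t, v in zip(times, noisy)
        ]
    return pd.DataFrame(rows)
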