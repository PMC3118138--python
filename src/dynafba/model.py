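"""Stoichiometric model representation and constraint patching.

A :class:`MetabolicModel` is the static substrate of the simulator: metabolites,
reactions with flux bounds, exchange reactions crossing the system boundary, and
optional boolean gene associations.  Constraint *patches* — per-reaction bound
overrides labelled ``fixed`` (anaerobic set), ``dynamic`` (kinetic bounds
recomputed every step) or ``genetic`` (knockouts and expression changes) — are
kept separate from the model so the same network can be re-used across
scenarios.

Sign convention (used everywhere in the package): exchange fluxes are negative
for uptake and positive for secretion.  A kinetic "maximum uptake rate" u for a
species therefore becomes a *lower* bound of -u on its exchange reaction.

Bounds are stored as floats; "unbounded" is represented by ``INF`` (1000
mmol/gDW/h), a solver-safe stand-in for infinity that exceeds any physiological
flux by an order of magnitude.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    BiomassDeletionError,
    DuplicateIdError,
    InvalidBoundsError,
    ModelParseError,
    ModelValidationError,
    UnknownMetaboliteError,
    UnknownTargetError,
)

#: Numeric stand-in for an unbounded flux (mmol/gDW/h).
INF = 1000.0

#: Reaction tags with package-level meaning (constraint targeting is tag-driven
#: so the logic is independent of any particular reconstruction's gene ids).
KNOWN_TAGS = frozenset(
    {
        "oxygen_uptake",
        "tca_oxidative_break",
        "quinone",
        "sterol_uptake",
        "maintenance_atp",
        "biomass",
        "exchange",
        "hexose_uptake",
        "nitrogen_uptake",
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ModelParseError(f"cannot parse formula {formula!r}")
        pos = m.end()
        n = float(m.group(2)) if m.group(2) else 1.0
        counts[m.group(1)] = counts.get(m.group(1), 0.0) + n
    if pos != len(formula):
        raise ModelParseError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    """A molecular species.

    ``mw`` (g/mmol... stored as g/mol; divide by 1000 for g/mmol) is required
    for extracellular species because the integrator converts exchange fluxes
    (mmol/gDW/h) into medium concentrations (g/L).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    mw: float | None = None
    is_extracellular: bool = False

    def __post_init__(self):
        if self.mw is not None and self.mw <= 0:
            raise ModelValidationError(f"metabolite {self.id}: mw must be > 0")

    @property
    def elements(self) -> dict[str, float]:
        return parse_formula(self.formula) if self.formula else {}


@dataclass(frozen=True)
class Reaction:
    """A (pseudo-)reaction: stoichiometry, flux bounds, gene rule, tags."""

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lb: float = 0.0
    ub: float = INF
    genes: str | None = None
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lb > self.ub:
            raise ModelValidationError(f"reaction {self.id}: lb > ub")
        object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub


@dataclass(frozen=True)
class GeneticModification:
    """A deletion, insertion, overexpression or downregulation.

    ``target`` is a gene id (resolved through boolean gene rules) or a reaction
    id (resolved directly).  Expression changes multiply the bound magnitudes by
    ``factor``; the default overexpression factor of 10 is used when a study
    reports an overexpression without a level.
    """

    target: str
    kind: str  # deletion | insertion | overexpression | downregulation
    factor: float | None = None
    added_reaction: Reaction | None = None

    def __post_init__(self):
        kinds = {"deletion", "insertion", "overexpression", "downregulation"}
        if self.kind not in kinds:
            raise ModelValidationError(f"unknown modification kind {self.kind!r}")
        if self.kind == "overexpression":
            f = 10.0 if self.factor is None else self.factor
            if f <= 1:
                raise ModelValidationError("overexpression requires factor > 1")
            object.__setattr__(self, "factor", f)
        if self.kind == "downregulation":
            if self.factor is None or not (0 < self.factor < 1):
                raise ModelValidationError("downregulation requires 0 < factor < 1")
        if self.kind == "insertion" and self.added_reaction is None:
            raise ModelValidationError("insertion requires added_reaction")


@dataclass
class ConstraintPatch:
    """Per-reaction (lb, ub) overrides with a provenance label.

    Labels: ``fixed`` (constant through the fermentation), ``dynamic``
    (recomputed every interval) or ``genetic`` (applied for the whole run and
    never relaxed by dynamic patches).
    """

    label: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def set(self, rxn_id: str, lb: float, ub: float) -> None:
        if lb > ub:
            raise InvalidBoundsError(f"{self.label} patch on {rxn_id}: lb {lb} > ub {ub}")
        self.bounds[rxn_id] = (float(lb), float(ub))

    def __len__(self) -> int:
        return len(self.bounds)

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.bounds


class MetabolicModel:
    """A validated stoichiometric model.

    Exchange reactions (single-metabolite boundary reactions) are auto-detected
    at construction and recorded in ``exchange_map`` (species id -> reaction id,
    a bijection over extracellular species).
    """

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction]):
        ids = [m.id for m in metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise DuplicateIdError(f"duplicate reaction ids: {dup}")
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._validate()
        self.exchange_map = self._detect_exchanges()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise UnknownMetaboliteError(
                        f"reaction {r.id} references unknown metabolite {mid!r}"
                    )
        for tag in ("maintenance_atp", "biomass"):
            tagged = [r.id for r in self.reactions if tag in r.tags]
            if len(tagged) > 1:
                raise ModelValidationError(f"multiple reactions tagged {tag}: {tagged}")

    def _detect_exchanges(self) -> dict[str, str]:
        exchange_map: dict[str, str] = {}
        for r in self.reactions:
            if r.is_exchange and "biomass" not in r.tags:
                (mid,) = r.stoichiometry
                if mid in exchange_map:
                    raise ModelValidationError(
                        f"species {mid} has two exchange reactions: "
                        f"{exchange_map[mid]}, {r.id}"
                    )
                exchange_map[mid] = r.id
        return exchange_map

    # -- lookups --------------------------------------------------------------

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reaction_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    def tagged(self, tag: str) -> list[Reaction]:
        return [r for r in self.reactions if tag in r.tags]

    def tagged_one(self, tag: str) -> Reaction | None:
        rs = self.tagged(tag)
        return rs[0] if rs else None

    @property
    def biomass_reaction(self) -> Reaction | None:
        return self.tagged_one("biomass")

    @property
    def maintenance_reaction(self) -> Reaction | None:
        return self.tagged_one("maintenance_atp")

    # -- numerics -------------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions); S @ v = 0 is the steady state."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                S[self._met_index[mid], j] = coef
        return S

    def bounds_arrays(self, patches: list[ConstraintPatch] | None = None):
        """Compose model bounds with patches.

        Patches apply in order, later overriding earlier, except that
        ``genetic`` overrides are re-asserted last so a dynamic patch can never
        relax a knockout.  May return lb > ub for some reaction (the LP then
        reports infeasibility; composition itself does not raise).
        """
        lb = np.array([r.lb for r in self.reactions])
        ub = np.array([r.ub for r in self.reactions])
        genetic: dict[str, tuple[float, float]] = {}
        for patch in patches or []:
            for rid, (lo, hi) in patch.bounds.items():
                j = self._rxn_index[rid]
                lb[j], ub[j] = lo, hi
                if patch.label == "genetic":
                    genetic[rid] = (lo, hi)
        for rid, (lo, hi) in genetic.items():
            j = self._rxn_index[rid]
            lb[j], ub[j] = lo, hi
        return lb, ub

    def with_reaction(self, reaction: Reaction) -> "MetabolicModel":
        """A new model with one reaction appended (re-validated)."""
        return MetabolicModel(self.metabolites, self.reactions + [reaction])

    def replace_reaction(self, reaction: Reaction) -> "MetabolicModel":
        """A new model with the same-id reaction swapped out."""
        j = self._rxn_index[reaction.id]
        reactions = list(self.reactions)
        reactions[j] = reaction
        return MetabolicModel(self.metabolites, reactions)

    # -- audits ---------------------------------------------------------------

    def element_imbalances(self, elements=("C", "H", "O", "N")) -> dict[str, dict[str, float]]:
        """Elemental conservation audit.

        Returns, for every non-exchange, non-biomass reaction, the net element
        production (should be 0 for a balanced reaction).  Reactions touching a
        metabolite with no declared formula are skipped.
        """
        out: dict[str, dict[str, float]] = {}
        for r in self.reactions:
            if r.is_exchange or "biomass" in r.tags:
                continue
            mets = [self.metabolite(mid) for mid in r.stoichiometry]
            if any(m.formula is None for m in mets):
                continue
            net = {e: 0.0 for e in elements}
            for mid, coef in r.stoichiometry.items():
                for e, n in self.metabolite(mid).elements.items():
                    if e in net:
                        net[e] += coef * n
            out[r.id] = net
        return out


# ---------------------------------------------------------------------------
# Gene rules
# ---------------------------------------------------------------------------

_GENE_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+")


def evaluate_gene_rule(rule: str, deleted: set[str]) -> bool:
    """Evaluate a boolean AND/OR gene-association rule under a deletion set."""
    expr_parts: list[str] = []
    for tok in _GENE_TOKEN.findall(rule):
        if tok in ("(", ")", "and", "or"):
            expr_parts.append(tok)
        else:
            expr_parts.append("False" if tok in deleted else "True")
    expr = " ".join(expr_parts)
    try:
        return bool(eval(expr, {"__builtins__": {}}, {}))  # literals only
    except SyntaxError as exc:
        raise ModelParseError(f"cannot parse gene rule {rule!r}") from exc


def genes_in_rule(rule: str) -> set[str]:
    return {t for t in _GENE_TOKEN.findall(rule) if t not in ("(", ")", "and", "or")}


# ---------------------------------------------------------------------------
# Constraint application
# ---------------------------------------------------------------------------

#: Species-id fragments identifying the inorganic exchanges whose supply is
#: treated as non-limiting under anaerobiosis.
INORGANIC_SPECIES = ("phosphate", "sulphate", "sulfate")


def apply_anaerobic_constraints(model: MetabolicModel) -> ConstraintPatch:
    """The fixed anaerobic constraint set, as a ``fixed`` patch.

    * oxygen uptake pinned to zero (lb = ub = 0);
    * the TCA cycle split into oxidative and reductive branches by zeroing the
      succinate-dehydrogenase / succinyl-CoA-ligase reactions
      (tag ``tca_oxidative_break``);
    * quinone-mediated FADH2/NADH reoxidation turned off (tag ``quinone``);
    * sterol uptake made non-limiting (ub = +INF on ``sterol_uptake``), since
      yeast cannot synthesize sterols without oxygen;
    * phosphate and sulphate exchanges fully relaxed (supply non-limiting).

    Idempotent: a pure function of the model's tags.
    """
    patch = ConstraintPatch(label="fixed")
    o2 = model.tagged("oxygen_uptake")
    if not o2:
        warnings.warn("no reaction tagged oxygen_uptake; model may be pre-anaerobic")
    for r in o2 + model.tagged("tca_oxidative_break") + model.tagged("quinone"):
        if r.lb > 0:
            raise InvalidBoundsError(
                f"cannot zero reaction {r.id}: pre-existing lb {r.lb} > 0"
            )
        patch.set(r.id, 0.0, 0.0)
    for r in model.tagged("sterol_uptake"):
        patch.set(r.id, r.lb, INF)
    for mid, rid in model.exchange_map.items():
        if any(frag in mid.lower() for frag in INORGANIC_SPECIES):
            patch.set(rid, -INF, INF)
    return patch


def _resolve_target(model: MetabolicModel, target: str) -> list[Reaction]:
    """Reactions knocked out by deleting ``target`` (reaction id or gene)."""
    if model.has_reaction(target):
        return [model.reaction(target)]
    hits = [
        r
        for r in model.reactions
        if r.genes and not evaluate_gene_rule(r.genes, {target})
    ]
    if not hits:
        known_genes = sorted({g for r in model.reactions if r.genes for g in genes_in_rule(r.genes)})
        raise UnknownTargetError(
            f"target {target!r} matches no reaction id and disables no gene rule; "
            f"known genes: {known_genes}"
        )
    return hits


def _reactions_mentioning(model: MetabolicModel, target: str) -> list[Reaction]:
    if model.has_reaction(target):
        return [model.reaction(target)]
    hits = [r for r in model.reactions if r.genes and target in genes_in_rule(r.genes)]
    if not hits:
        raise UnknownTargetError(f"target {target!r} matches no reaction or gene")
    return hits


def apply_genetic_modifications(
    model: MetabolicModel, mods: list[GeneticModification]
) -> tuple[ConstraintPatch, MetabolicModel]:
    """Translate genetic modifications into a ``genetic`` patch.

    Deletions pin all mapped reactions to zero for the whole fermentation.
    Over/under-expression scales bound magnitudes by ``factor``.  Insertions
    extend the model with the added reaction (returned model differs from the
    input in that case; stoichiometric consistency is re-validated).
    """
    patch = ConstraintPatch(label="genetic")
    out = model
    # collect gene-level deletions first so multi-gene rules ("G1 or G2")
    # require all isozymes deleted before the reaction is disabled
    deleted_genes = {
        m.target for m in mods if m.kind == "deletion" and not model.has_reaction(m.target)
    }
    for m in mods:
        if m.kind == "deletion":
            if model.has_reaction(m.target):
                hits = [model.reaction(m.target)]
            else:
                if m.target not in {
                    g for r in model.reactions if r.genes for g in genes_in_rule(r.genes)
                }:
                    _resolve_target(model, m.target)  # raises UnknownTargetError
                hits = [
                    r
                    for r in model.reactions
                    if r.genes and not evaluate_gene_rule(r.genes, deleted_genes)
                ]
            for r in hits:
                if "biomass" in r.tags:
                    raise BiomassDeletionError(
                        f"modification {m.target!r} would delete the biomass reaction"
                    )
                patch.set(r.id, 0.0, 0.0)
        elif m.kind in ("overexpression", "downregulation"):
            f = m.factor
            for r in _reactions_mentioning(model, m.target):
                lb = r.lb * f if r.lb < 0 else r.lb
                patch.set(r.id, lb, r.ub * f)
        elif m.kind == "insertion":
            out = out.with_reaction(m.added_reaction)
    return patch, out


# ---------------------------------------------------------------------------
# I/O — TSV dialect and SBML
# ---------------------------------------------------------------------------

_MET_COLUMNS = ["metabolite_id", "name", "compartment", "formula", "mw", "extracellular"]
_RXN_COLUMNS = ["reaction_id", "name", "equation", "lb", "ub", "genes", "tags"]


def _parse_side(side: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for term in side.split("+"):
        term = term.strip()
        if not term:
            continue
        parts = term.split()
        if len(parts) == 1:
            coef, mid = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError as exc:
                raise ModelParseError(f"bad coefficient in term {term!r}") from exc
            mid = parts[1]
        else:
            raise ModelParseError(f"cannot parse equation term {term!r}")
        stoich[mid] = stoich.get(mid, 0.0) + coef
    return stoich


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"a A + b B -> c C"`` (``<->`` marks reversible)."""
    if "<->" in equation:
        left, right = equation.split("<->")
        reversible = True
    elif "->" in equation:
        left, right = equation.split("->")
        reversible = False
    else:
        raise ModelParseError(f"equation {equation!r} has no arrow")
    stoich = {mid: -c for mid, c in _parse_side(left).items()}
    for mid, c in _parse_side(right).items():
        stoich[mid] = stoich.get(mid, 0.0) + c
    return {m: c for m, c in stoich.items() if c != 0.0}, reversible


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def fmt(coef: float, mid: str) -> str:
        return mid if coef == 1.0 else f"{coef:.17g} {mid}"

    left = " + ".join(fmt(-c, m) for m, c in stoich.items() if c < 0)
    right = " + ".join(fmt(c, m) for m, c in stoich.items() if c > 0)
    arrow = "<->" if reversible else "->"
    return f"{left} {arrow} {right}"


def load_model(path, fmt: str | None = None) -> MetabolicModel:
    """Load a model from the TSV dialect or (via cobra) from SBML.

    The format is sniffed from the extension when not given: ``.xml``/``.sbml``
    is SBML, anything else the TSV dialect.
    """
    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "tsv"
    if fmt == "sbml":
        return _load_sbml(path)
    if fmt == "tsv":
        return _load_tsv(path)
    raise ModelParseError(f"unknown model format {fmt!r}")


def _load_tsv(path: str) -> MetabolicModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    section = None
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    for ln in lines:
        if not ln.strip() or ln.startswith("#"):
            if ln.strip().lower() == "## metabolites":
                section = None
            continue
        cells = ln.split("\t")
        if cells[0] == "metabolite_id":
            section = "met"
            continue
        if cells[0] == "reaction_id":
            section = "rxn"
            continue
        if section == "met":
            cells += [""] * (len(_MET_COLUMNS) - len(cells))
            mid, name, comp, formula, mw, extra = cells[: len(_MET_COLUMNS)]
            metabolites.append(
                Metabolite(
                    id=mid,
                    name=name,
                    compartment=comp or "c",
                    formula=formula or None,
                    mw=float(mw) if mw else None,
                    is_extracellular=extra.strip().lower() in ("1", "true", "yes"),
                )
            )
        elif section == "rxn":
            cells += [""] * (len(_RXN_COLUMNS) - len(cells))
            rid, name, equation, lb, ub, genes, tags = cells[: len(_RXN_COLUMNS)]
            try:
                stoich, reversible = parse_equation(equation)
            except ModelParseError as exc:
                raise ModelParseError(f"reaction {rid}: {exc}") from exc
            lo = float(lb) if lb else (-INF if reversible else 0.0)
            hi = float(ub) if ub else INF
            reactions.append(
                Reaction(
                    id=rid,
                    name=name,
                    stoichiometry=stoich,
                    lb=lo,
                    ub=hi,
                    genes=genes or None,
                    tags=frozenset(t for t in tags.split(",") if t.strip()),
                )
            )
        else:
            raise ModelParseError(f"line outside a section: {ln!r}")
    if not reactions:
        raise ModelParseError(f"{path}: no reactions parsed")
    return MetabolicModel(metabolites, reactions)


def write_model(model: MetabolicModel, path) -> None:
    """Write a model in the TSV dialect (round-trips through load_model)."""
    with open(str(path), "w") as fh:
        fh.write("\t".join(_MET_COLUMNS) + "\n")
        for m in model.metabolites:
            fh.write(
                "\t".join(
                    [
                        m.id,
                        m.name,
                        m.compartment,
                        m.formula or "",
                        f"{m.mw:g}" if m.mw is not None else "",
                        "1" if m.is_extracellular else "",
                    ]
                )
                + "\n"
            )
        fh.write("\n")
        fh.write("\t".join(_RXN_COLUMNS) + "\n")
        for r in model.reactions:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.name,
                        format_equation(r.stoichiometry, r.reversible),
                        f"{r.lb:.17g}",
                        f"{r.ub:.17g}",
                        r.genes or "",
                        ",".join(sorted(r.tags)),
                    ]
                )
                + "\n"
            )


def _load_sbml(path: str) -> MetabolicModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ModelParseError("SBML support requires the cobra package") from exc
    cm = cobra.io.read_sbml_model(path)
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            formula=m.formula or None,
            mw=None,
            is_extracellular=(m.compartment or "").startswith("e"),
        )
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lb=max(r.lower_bound, -INF),
            ub=min(r.upper_bound, INF),
            genes=r.gene_reaction_rule or None,
        )
        for r in cm.reactions
    ]
    return MetabolicModel(metabolites, reactions)


def load_modifications(path) -> list[GeneticModification]:
    """Read a JSON genetic-modification spec.

    Format: ``[{"target": "GPD1", "kind": "deletion"}, ...]``; insertions carry
    an ``added_reaction`` object with ``id``, ``equation``, and optional
    ``lb``/``ub``.
    """
    import json

    with open(str(path)) as fh:
        entries = json.load(fh)
    mods = []
    for e in entries:
        added = None
        if "added_reaction" in e:
            ar = e["added_reaction"]
            stoich, reversible = parse_equation(ar["equation"])
            added = Reaction(
                id=ar["id"],
                name=ar.get("name", ""),
                stoichiometry=stoich,
                lb=ar.get("lb", -INF if reversible else 0.0),
                ub=ar.get("ub", INF),
            )
        mods.append(
            GeneticModification(
                target=e.get("target", ""),
                kind=e["kind"],
                factor=e.get("factor"),
                added_reaction=added,
            )
        )
    return mods
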