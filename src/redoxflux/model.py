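"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a list of :class:`Metabolite` and
:class:`Reaction` objects together with a biomass objective.  The
stoichiometric matrix ``S`` (rows = metabolites, columns = reactions) is
derived from the reaction stoichiometries on demand.  Flux units are
mmol gDW^-1 h^-1 throughout; the growth rate carried by the biomass
objective has units h^-1.

Sign convention: uptake through an exchange reaction is a *negative*
flux, so "uptake of q" is expressed as ``lower_bound = -q``.  This
matches the dominant convention of published SBML models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ValidationReport",
    "parse_formula",
    "molecular_weight",
    "ModelError",
]

DEFAULT_BOUND = 1000.0

#: Standard atomic weights (g/mol), sufficient for biochemical formulas.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cu": 63.546, "Mn": 54.938, "Co": 58.933,
    "Mo": 95.95, "Ni": 58.693, "Cl": 35.45, "Se": 78.971, "W": 183.84,
    "La": 138.905, "Ce": 140.116,
}

#: Formula tokens that mark an undefined moiety; such metabolites are
#: excluded from balance checking and reported as warnings.
PLACEHOLDER_ELEMENTS = {"R", "X", "*"}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?|\*)(\d*)")


class ModelError(ValueError):
    """Raised for structurally invalid models or inputs."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string into an element -> count map.

    Raises :class:`ModelError` if the string contains characters that are
    not element symbols followed by optional counts.
    """
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ModelError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return counts


def molecular_weight(formula: str) -> float:
    """Molecular weight in g/mol computed from an elemental formula.

    Placeholder elements (R groups, X) make the weight undefined and
    raise :class:`ModelError`.
    """
    counts = parse_formula(formula)
    if not counts:
        raise ModelError("empty formula has no molecular weight")
    weight = 0.0
    for elem, n in counts.items():
        if elem in PLACEHOLDER_ELEMENTS:
            raise ModelError(f"formula {formula!r} has placeholder element {elem!r}")
        try:
            weight += ATOMIC_WEIGHTS[elem] * n
        except KeyError:
            raise ModelError(f"unknown element {elem!r} in formula {formula!r}") from None
    return weight


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str = ""
    charge: int = 0

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula)

    @property
    def molecular_weight(self) -> float:
        return molecular_weight(self.formula)

    @property
    def has_placeholder(self) -> bool:
        return any(e in PLACEHOLDER_ELEMENTS for e in self.elements)


@dataclass
class Reaction:
    """One reaction; negative stoichiometric coefficients are consumed."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        """Exchange/demand reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class ValidationReport:
    """Outcome of structural/mass-balance validation.

    ``unbalanced_reactions`` lists (reaction id, element, imbalance)
    triples with nonzero imbalance only.  ``orphan_reaction_count``
    counts reactions without a gene association.
    """

    unbalanced_reactions: list[tuple[str, str, float]] = field(default_factory=list)
    orphan_reaction_count: int = 0
    exchange_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def is_balanced(self) -> bool:
        return not self.unbalanced_reactions


class MetabolicModel:
    """A genome-scale(-style) metabolic model.

    Parameters
    ----------
    metabolites, reactions:
        Model components; ids must be unique within each list.
    objective_id:
        Reaction id of the (biomass) objective.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        objective_id: str,
        id: str = "model",
        extras: dict | None = None,
    ) -> None:
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.objective_id = objective_id
        self.extras = dict(extras or {})  # passthrough bag for unknown JSON fields
        self._check_structure()

    # -- structural integrity ------------------------------------------------
    def _check_structure(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ModelError(f"reaction {r.id} references unknown metabolites {sorted(missing)}")
        if self.objective_id not in set(rxn_ids):
            raise ModelError(f"objective reaction {self.objective_id!r} not in model")

    # -- lookups -------------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    # -- matrices ------------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with rows ordered as ``metabolites`` and columns as
        ``reactions``."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met_id, coeff in r.stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        mets = [Metabolite(m.id, m.name, m.compartment, m.formula, m.charge) for m in self.metabolites]
        rxns = [
            Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                     r.gene_rule, r.subsystem, r.name)
            for r in self.reactions
        ]
        return MetabolicModel(mets, rxns, self.objective_id, id=self.id, extras=dict(self.extras))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"MetabolicModel({self.id!r}, {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions)")


def validate_mass_balance(
    model: MetabolicModel,
    exclude: set[str] | None = None,
    tol: float = 1e-9,
) -> ValidationReport:
    """Check elemental balance of every internal (non-exchange) reaction.

    Per-element imbalance is the signed sum of coefficient x element count
    over the reaction's metabolites; only nonzero imbalances are reported.
    Reactions touching a metabolite with a missing or placeholder formula
    are skipped and listed in ``warnings``.  The objective reaction (a
    biomass drain, inherently unbalanced) and any ids in ``exclude`` are
    skipped.

    Returns a :class:`ValidationReport` which also carries the orphan
    (no gene rule) reaction count and the exchange reaction ids.
    """
    exclude = set(exclude or ())
    exclude.add(model.objective_id)
    report = ValidationReport(
        orphan_reaction_count=sum(1 for r in model.reactions if not r.gene_rule.strip()),
        exchange_ids=model.exchange_ids,
    )
    met_elements: dict[str, dict[str, int] | None] = {}
    for m in model.metabolites:
        try:
            elems = m.elements
        except ModelError:
            met_elements[m.id] = None
            continue
        if not elems or any(e in PLACEHOLDER_ELEMENTS for e in elems):
            met_elements[m.id] = None
        else:
            met_elements[m.id] = elems

    for r in model.reactions:
        if r.is_exchange or r.id in exclude:
            continue
        bad = [mid for mid in r.stoichiometry if met_elements[mid] is None]
        if bad:
            report.warnings.append(
                f"reaction {r.id}: skipped, missing/placeholder formula for {sorted(bad)}"
            )
            continue
        balance: dict[str, float] = {}
        for mid, coeff in r.stoichiometry.items():
            for elem, n in met_elements[mid].items():
                balance[elem] = balance.get(elem, 0.0) + coeff * n
        for elem in sorted(balance):
            if abs(balance[elem]) > tol:
                report.unbalanced_reactions.append((r.id, elem, balance[elem]))
    return report
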