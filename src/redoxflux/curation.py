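"""Model-hygiene procedures for constraint-based reconstructions.

Covers the curation steps a genome-scale model goes through before
simulation: thermodynamic directionality assignment from standard Gibbs
energies, detection of erroneous energy-generating cycles (EGCs),
normalization of the biomass reaction to 1 g/mmol, installation of
growth/non-growth ATP maintenance, fitting the growth-associated
maintenance (GAM) to an experimental O2 yield, and yield bookkeeping.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

from .fba import FbaProblem, FluxSolution, SolverSettings
from .model import MetabolicModel, ModelError, Reaction, molecular_weight

__all__ = [
    "GibbsRecord",
    "EGCReport",
    "MaintenanceSpec",
    "BiomassSpec",
    "YieldSet",
    "assign_directionality",
    "detect_energy_generating_cycles",
    "normalize_biomass",
    "set_maintenance",
    "fit_gam_to_yield",
    "compute_yields",
    "read_gibbs_tsv",
    "DEFAULT_ENERGY_METABOLITES",
]


@dataclass(frozen=True)
class GibbsRecord:
    """Standard reaction Gibbs energy (kJ/mol) with its uncertainty."""

    reaction_id: str
    dg0: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ModelError(f"Gibbs record {self.reaction_id}: negative sd")


@dataclass
class EGCReport:
    """One detected energy-generating cycle: the energy metabolite whose
    dissipation reaction carries flux with all exchanges closed, and the
    internal reactions active in the (parsimonious) dissipating solution."""

    energy_metabolite: str
    dissipation_flux: float
    cycle_reactions: list[str] = field(default_factory=list)


@dataclass
class MaintenanceSpec:
    """ATP maintenance: GAM is mmol ATP per gDW biomass (enters the
    biomass reaction, the h^-1 arrives via the growth rate); NGAM is the
    lower bound (mmol gDW^-1 h^-1) of the ATP-hydrolysis reaction.
    ``po_ratio`` records the respiratory-chain assumption used when the
    GAM was fitted."""

    gam: float = 10.86
    ngam: float = 3.5
    po_ratio: float = 2.5

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ModelError("maintenance values must be nonnegative")

    def replace(self, **kw) -> "MaintenanceSpec":
        return MaintenanceSpec(
            gam=kw.get("gam", self.gam),
            ngam=kw.get("ngam", self.ngam),
            po_ratio=kw.get("po_ratio", self.po_ratio),
        )


@dataclass
class BiomassSpec:
    """Target of biomass normalization: total precursor weight of
    ``target_weight`` g/mmol (1000 g/mol) and the C-mol formula weight
    used in yield conversions."""

    target_weight: float = 1.0  # g per mmol biomass
    cmol_weight: float = 24.6   # g per C-mol
    tolerance: float = 1e-3     # relative tolerance on the weight sum


@dataclass
class YieldSet:
    """Stoichiometric yields for one solution: O2 and CO2 per substrate
    (mol/mol) and biomass carbon yield (C-mol/mol)."""

    mu: float
    q_substrate: float
    y_o2: float
    y_co2: float
    y_x: float


#: Currency metabolites excluded from the biomass weight sum and moved by
#: the GAM term.  Ids are matched on their compartment-stripped stem.
GAM_CURRENCY = {"atp", "adp", "pi", "h2o", "h", "ppi"}

#: Dissipation-reaction recipes for the energy-metabolite screen, keyed by
#: a descriptive name.  Each maps metabolite-id stems to coefficients;
#: metabolites absent from the model cause the entry to be skipped with a
#: warning.  The default list follows the common curation convention for
#: eleven energy carriers, adapted to a menaquinone-based chain, plus the
#: periplasmic proton gradient.
DISSIPATION_RECIPES: dict[str, dict[str, float]] = {
    "atp": {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1},
    "ctp": {"ctp": -1, "h2o": -1, "cdp": 1, "pi": 1, "h": 1},
    "gtp": {"gtp": -1, "h2o": -1, "gdp": 1, "pi": 1, "h": 1},
    "utp": {"utp": -1, "h2o": -1, "udp": 1, "pi": 1, "h": 1},
    "itp": {"itp": -1, "h2o": -1, "idp": 1, "pi": 1, "h": 1},
    "nadh": {"nadh": -1, "nad": 1, "h": 1},
    "nadph": {"nadph": -1, "nadp": 1, "h": 1},
    "fadh2": {"fadh2": -1, "fad": 1, "h": 2},
    "fmnh2": {"fmnh2": -1, "fmn": 1, "h": 2},
    "menaquinol": {"mql": -1, "mqn": 1, "h": 2},
    "accoa": {"accoa": -1, "h2o": -1, "ac": 1, "coa": 1, "h": 1},
    "proton_gradient": {},  # special-cased: h_p -> h_c
}
DEFAULT_ENERGY_METABOLITES = list(DISSIPATION_RECIPES)


def read_gibbs_tsv(path: str | Path) -> list[GibbsRecord]:
    """Read Gibbs records from TSV columns reaction_id, dg0_kj_mol,
    sd_kj_mol (header optional)."""
    records = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "reaction_id":
                continue
            records.append(GibbsRecord(row[0], float(row[1]), float(row[2])))
    return records


def assign_directionality(
    model: MetabolicModel,
    gibbs: list[GibbsRecord],
    dg_threshold: float = 1.0,
    sd_fraction: float = 0.03,
) -> tuple[MetabolicModel, list[str]]:
    """Constrain reaction directionality from standard Gibbs energies.

    A reaction is made forward-irreversible (lb := 0) when its dG0 is
    below ``-dg_threshold`` kJ/mol and the standard deviation is below
    ``sd_fraction`` of |dG0|; symmetrically backward-irreversible
    (ub := 0) for strongly positive dG0.  All other records leave the
    bounds untouched.  Unknown reaction ids are skipped with a warning.

    Returns the updated model copy and the warning list.  The outcome is
    order-independent because each record touches only its own reaction.
    """
    out = model.copy()
    warnings: list[str] = []
    for rec in gibbs:
        if not out.has_reaction(rec.reaction_id):
            warnings.append(f"Gibbs record for unknown reaction {rec.reaction_id!r} skipped")
            continue
        if abs(rec.dg0) <= dg_threshold or rec.sd >= sd_fraction * abs(rec.dg0):
            continue
        rxn = out.reaction(rec.reaction_id)
        if rec.dg0 < 0:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        else:
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
    return out, warnings


def _stem_index(model: MetabolicModel) -> dict[str, dict[str, str]]:
    """Map compartment -> metabolite-id stem -> full id.

    The stem of ``atp_c`` is ``atp``; ids without a compartment suffix
    are their own stem.
    """
    by_comp: dict[str, dict[str, str]] = {}
    for m in model.metabolites:
        stem = m.id
        if "_" in m.id and m.id.rsplit("_", 1)[1] == m.compartment:
            stem = m.id.rsplit("_", 1)[0]
        by_comp.setdefault(m.compartment, {})[stem] = m.id
    return by_comp


def _resolve_currency(model: MetabolicModel, compartment: str = "c") -> dict[str, str]:
    return _stem_index(model).get(compartment, {})


def detect_energy_generating_cycles(
    model: MetabolicModel,
    energy_metabolites: list[str] | None = None,
    tol: float = 1e-6,
    compartment: str = "c",
) -> tuple[list[EGCReport], list[str]]:
    """Screen for erroneous energy-generating cycles.

    For each energy metabolite a dissipation reaction (e.g. ATP + H2O ->
    ADP + Pi + H+) is added, every exchange bound is closed to zero,
    forced fluxes are relaxed (positive lower bounds and negative upper
    bounds set to 0), and the dissipation flux is maximized.  A positive
    optimum means the network can generate the energy carrier from
    nothing — an EGC.  Cycle members are the internal reactions active in
    the parsimonious dissipating solution.

    Returns (reports, warnings); an empty report list means EGC-free.
    """
    names = energy_metabolites or DEFAULT_ENERGY_METABOLITES
    stems = _resolve_currency(model, compartment)
    reports: list[EGCReport] = []
    warnings: list[str] = []

    closed = model.copy()
    for r in closed.reactions:
        if r.is_exchange:
            r.lower_bound = r.upper_bound = 0.0
        else:
            if r.lower_bound > 0:
                r.lower_bound = 0.0
            if r.upper_bound < 0:
                r.upper_bound = 0.0

    for name in names:
        if name == "proton_gradient":
            per = _stem_index(model).get("p", {})
            if "h" not in per or "h" not in stems:
                warnings.append("proton-gradient dissipation skipped: no periplasmic proton")
                continue
            stoich = {per["h"]: -1.0, stems["h"]: 1.0}
        else:
            recipe = DISSIPATION_RECIPES.get(name)
            if recipe is None:
                warnings.append(f"no dissipation recipe for {name!r}; skipped")
                continue
            missing = [s for s in recipe if s not in stems]
            if missing:
                warnings.append(f"{name}: metabolites {missing} absent; skipped")
                continue
            stoich = {stems[s]: float(c) for s, c in recipe.items()}

        probe = closed.copy()
        dem_id = f"EGC_DM_{name}"
        probe.reactions.append(Reaction(dem_id, stoich, 0.0, 1000.0, name="dissipation probe"))
        probe = MetabolicModel(probe.metabolites, probe.reactions, dem_id, id=probe.id)
        sol = FbaProblem(probe).solve(parsimonious=True)
        if sol.status == "unbounded" or (sol.optimal and sol.objective_value > tol):
            flux = math.inf if sol.status == "unbounded" else sol.objective_value
            members = []
            if sol.optimal:
                members = sorted(
                    rid for rid, v in sol.fluxes.items()
                    if abs(v) > tol and rid != dem_id
                )
            reports.append(EGCReport(name, flux, members))
    return reports, warnings


def normalize_biomass(model: MetabolicModel, spec: BiomassSpec | None = None) -> MetabolicModel:
    """Rescale biomass precursor coefficients by one common factor so the
    precursor weight sum equals ``spec.target_weight`` g/mmol (1000 g/mol).

    Currency metabolites of the GAM term (ATP/ADP/Pi/H2O/H+) are excluded
    from both the weight sum and the rescaling, so maintenance installed
    with :func:`set_maintenance` is preserved.  A precursor without a
    usable formula is an error listing the offender.
    """
    spec = spec or BiomassSpec()
    out = model.copy()
    biomass = out.reaction(out.objective_id)
    currency_ids = {
        mid for mid in biomass.stoichiometry
        if _strip_compartment(out, mid) in GAM_CURRENCY
    }
    weight = 0.0
    missing: list[str] = []
    for mid, coeff in biomass.stoichiometry.items():
        if mid in currency_ids:
            continue
        try:
            mw = out.metabolite(mid).molecular_weight
        except ModelError:
            missing.append(mid)
            continue
        weight += abs(coeff) * mw
    if missing:
        raise ModelError(f"biomass precursors without usable formula: {sorted(missing)}")
    if weight <= 0:
        raise ModelError("biomass reaction has no weighable precursors")
    factor = spec.target_weight * 1000.0 / weight
    for mid in list(biomass.stoichiometry):
        if mid not in currency_ids:
            # 12 significant digits: far inside the 0.1% weight tolerance
            # and short enough to survive SBML serialization exactly
            biomass.stoichiometry[mid] = float(f"{biomass.stoichiometry[mid] * factor:.12g}")
    return out


def _strip_compartment(model: MetabolicModel, met_id: str) -> str:
    m = model.metabolite(met_id)
    if "_" in met_id and met_id.rsplit("_", 1)[1] == m.compartment:
        return met_id.rsplit("_", 1)[0]
    return met_id


def biomass_weight(model: MetabolicModel) -> float:
    """Weight (g/mol) of the biomass precursors, GAM currency excluded."""
    biomass = model.reaction(model.objective_id)
    total = 0.0
    for mid, coeff in biomass.stoichiometry.items():
        if _strip_compartment(model, mid) in GAM_CURRENCY:
            continue
        total += abs(coeff) * model.metabolite(mid).molecular_weight
    return total


def set_maintenance(
    model: MetabolicModel,
    spec: MaintenanceSpec,
    atpm_id: str = "ATPM",
    compartment: str = "c",
) -> MetabolicModel:
    """Install GAM and NGAM on a model copy.

    GAM: the biomass reaction consumes ``spec.gam`` additional mmol ATP
    (+H2O) per gDW and releases matching ADP/Pi/H+.  NGAM: the ATP
    hydrolysis maintenance reaction (created if absent) gets lower bound
    ``spec.ngam``.  Idempotent — reapplying replaces the previous GAM
    contribution (tracked in ``model.extras``) instead of adding to it.
    """
    out = model.copy()
    stems = _resolve_currency(out, compartment)
    needed = ["atp", "adp", "pi", "h2o"]
    missing = [s for s in needed if s not in stems]
    if missing:
        raise ModelError(f"currency metabolites missing for maintenance: {missing}")
    atp, adp, pi, h2o = (stems[s] for s in needed)
    h = stems.get("h")

    biomass = out.reaction(out.objective_id)
    previous = float(out.extras.get("gam", 0.0))
    delta = spec.gam - previous
    for mid, sign in ((atp, -1.0), (h2o, -1.0), (adp, 1.0), (pi, 1.0)):
        biomass.stoichiometry[mid] = biomass.stoichiometry.get(mid, 0.0) + sign * delta
        if abs(biomass.stoichiometry[mid]) < 1e-12:
            del biomass.stoichiometry[mid]
    if h is not None:
        biomass.stoichiometry[h] = biomass.stoichiometry.get(h, 0.0) + delta
        if abs(biomass.stoichiometry.get(h, 0.0)) < 1e-12:
            biomass.stoichiometry.pop(h, None)
    out.extras["gam"] = spec.gam

    if out.has_reaction(atpm_id):
        atpm = out.reaction(atpm_id)
    else:
        stoich = {atp: -1.0, h2o: -1.0, adp: 1.0, pi: 1.0}
        if h is not None:
            stoich[h] = 1.0
        atpm = Reaction(atpm_id, stoich, 0.0, 1000.0, name="ATP maintenance",
                        subsystem="Maintenance")
        out.reactions.append(atpm)
    atpm.lower_bound = spec.ngam
    if atpm.upper_bound < spec.ngam:
        atpm.upper_bound = 1000.0
    return out


def compute_yields(solution: FluxSolution, condition, cmol_weight: float = 24.6) -> YieldSet:
    """Yields from one optimal solution under ``condition``.

    ``condition`` supplies the exchange ids (substrate, O2, CO2).  By the
    Table-style convention: Y_O2 = |v_O2|/qS and Y_CO2 = |v_CO2|/qS in
    mol/mol, and Y_X = (mu * 1000 / cmol_weight) / qS in C-mol/mol using
    the stated biomass C-mol formula weight.
    """
    if not solution.optimal:
        raise ModelError(f"cannot compute yields from a {solution.status} solution")
    q = abs(solution.fluxes.get(condition.substrate_exchange, 0.0))
    if q < 1e-12:
        raise ModelError("zero substrate uptake: yields undefined")
    mu = solution.objective_value
    return YieldSet(
        mu=mu,
        q_substrate=q,
        y_o2=abs(solution.fluxes.get(condition.o2_exchange, 0.0)) / q,
        y_co2=abs(solution.fluxes.get(condition.co2_exchange, 0.0)) / q,
        y_x=(mu * 1000.0 / cmol_weight) / q,
    )


def fit_gam_to_yield(
    model: MetabolicModel,
    condition,
    target_y_o2: float,
    bracket: tuple[float, float] = (0.0, 100.0),
    tol: float = 0.01,
    settings: SolverSettings | None = None,
) -> float:
    """Fit the GAM so the simulated O2 yield matches ``target_y_o2``.

    Bisection on the GAM over ``bracket``; Y_O2(GAM) is verified to be
    monotone (non-decreasing) across the bracket before the search.  A
    target outside the attainable range raises an error reporting
    [min, max].
    """
    from .fba import solve_fba  # local import to keep module load order flat

    settings = settings or SolverSettings(parsimonious=True)
    base_ngam = condition.maintenance.ngam if condition.maintenance else 0.0

    def y_o2_at(gam: float) -> float:
        spec = MaintenanceSpec(gam=gam, ngam=base_ngam)
        m = set_maintenance(model, spec)
        cond = condition.without_maintenance()
        sol = solve_fba(m, cond, settings)
        if not sol.optimal:
            raise ModelError(f"infeasible at GAM={gam}: cannot fit")
        return compute_yields(sol, condition).y_o2

    lo, hi = bracket
    y_lo, y_mid, y_hi = y_o2_at(lo), y_o2_at(0.5 * (lo + hi)), y_o2_at(hi)
    if not (y_lo <= y_mid + 1e-9 and y_mid <= y_hi + 1e-9):
        raise ModelError("Y_O2 is not monotone in GAM over the bracket; bisection invalid")
    if not (y_lo - 1e-9 <= target_y_o2 <= y_hi + 1e-9):
        raise ModelError(
            f"target Y_O2 {target_y_o2} outside attainable range [{y_lo:.4f}, {y_hi:.4f}]"
        )
    # yield slack keeps the search stable on flat segments of Y_O2(GAM):
    # the smallest GAM reaching the target (within slack) is returned
    y_slack = 1e-6
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if y_o2_at(mid) < target_y_o2 - y_slack:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
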