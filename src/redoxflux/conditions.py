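"""Growth conditions and the simulation experiments built on them.

A :class:`Condition` is a named, declarative description of one growth
scenario: substrate uptake bounds, flux-split ratio constraints,
reversibility overrides and maintenance settings.  Applying a condition
to a model yields a bounded model copy plus the ratio constraints to be
installed as LP rows.

On top of conditions this module implements the simulation experiments:
maintenance sensitivity scans, the formaldehyde-split scan, the H2
phase plane with complex-I directionality switch and minimum-uptake
threshold detection, the carbon-normalized substrate panel, and the
O2/CO2-vs-CH4 uptake-response regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .curation import MaintenanceSpec, YieldSet, compute_yields, set_maintenance
from .fba import RatioConstraint, SolverSettings, solve_fba
from .model import MetabolicModel, ModelError

__all__ = [
    "Condition",
    "ScanResult",
    "PhasePlaneResult",
    "ResponseFit",
    "FitResult",
    "build_condition",
    "load_condition",
    "save_condition",
    "scan_maintenance",
    "scan_formaldehyde_split",
    "phase_plane_h2",
    "find_switch_fraction",
    "find_min_h2_uptake",
    "uptake_response_fit",
    "simulate_substrate_panel",
    "SUBSTRATE_CARBONS",
]

#: Substrate name -> (exchange-id stem, carbon count per molecule).
SUBSTRATE_CARBONS: dict[str, tuple[str, int]] = {
    "CH4": ("EX_ch4_e", 1),
    "H2+CO2": ("EX_h2_e", 0),
    "propane": ("EX_prpn_e", 3),
    "isopropanol": ("EX_ipoh_e", 3),
    "acetone": ("EX_actn_e", 3),
}

#: Default flux-split reactions (mini-model naming, matching the field's
#: id conventions so the published model needs no remapping for the
#: shared ids).
FALDH_FOCAL = "FALDHpp"
FALDH_DENOMINATOR = ("FALDHpp", "THFOX")
HYD_FOCAL = "HYD4pp"
HYD_DENOMINATOR = ("HYD4pp", "NAD_H2")
COMPLEX_I = "NADH16pp"


@dataclass
class Condition:
    """One simulated growth scenario.

    ``uptake_bounds`` maps exchange ids to maximum uptake rates
    (nonnegative; applied internally as ``lower_bound = -q``).
    ``reversible_overrides`` maps reaction ids to explicit (lb, ub)
    pairs, e.g. making complex I reversible under autotrophy.
    """

    name: str
    uptake_bounds: dict[str, float] = field(default_factory=dict)
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)
    reversible_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    maintenance: MaintenanceSpec | None = None
    substrate_exchange: str = ""
    o2_exchange: str = "EX_o2_e"
    co2_exchange: str = "EX_co2_e"

    def __post_init__(self) -> None:
        for ex, q in self.uptake_bounds.items():
            if q < 0:
                raise ModelError(f"uptake bound for {ex} must be nonnegative, got {q}")

    def apply(self, model: MetabolicModel) -> tuple[MetabolicModel, list[RatioConstraint]]:
        """Return a bounded model copy and the ratio constraints to install."""
        out = model.copy() if self.maintenance is None else set_maintenance(model, self.maintenance)
        for rid, (lb, ub) in self.reversible_overrides.items():
            rxn = out.reaction(rid)
            rxn.lower_bound, rxn.upper_bound = lb, ub
        for ex, q in self.uptake_bounds.items():
            rxn = out.reaction(ex)
            rxn.lower_bound = -q
        return out, list(self.ratio_constraints)

    def without_maintenance(self) -> "Condition":
        return replace(self, maintenance=None)

    def with_ratio(self, rc: RatioConstraint) -> "Condition":
        """Replace any constraint sharing ``rc``'s focal reaction."""
        kept = [c for c in self.ratio_constraints if c.focal_reaction != rc.focal_reaction]
        return replace(self, ratio_constraints=kept + [rc])


def build_condition(
    substrate: str,
    carbon_uptake: float = 3.5,
    maintenance: MaintenanceSpec | None = None,
    faldh_fraction: float = 0.2,
    hyd_fraction: float = 0.76,
    h2_uptake: float | None = None,
) -> Condition:
    """Build the default condition for one substrate.

    Carbon substrates get uptake ``carbon_uptake / carbon_count`` so all
    conditions share an equivalent carbon uptake (default 3.5 C-mmol
    gDW^-1 h^-1); O2 and NH4 remain freely available.  CH4 attaches the
    formaldehyde-split constraint (``faldh_fraction`` of total
    formaldehyde oxidation through the cytochrome-coupled branch).
    Autotrophy ("H2+CO2") sets the H2 bound directly in mmol (default
    13.2), opens CO2 uptake, attaches the periplasmic-hydrogenase split
    and makes complex I reversible.
    """
    if substrate not in SUBSTRATE_CARBONS:
        raise ModelError(f"unknown substrate {substrate!r}; choose from {sorted(SUBSTRATE_CARBONS)}")
    maintenance = maintenance if maintenance is not None else MaintenanceSpec()
    exchange, carbons = SUBSTRATE_CARBONS[substrate]

    if substrate == "H2+CO2":
        q_h2 = 13.2 if h2_uptake is None else h2_uptake
        return Condition(
            name=f"H2+CO2 (qH2={q_h2:g})",
            uptake_bounds={exchange: q_h2, "EX_co2_e": 1000.0},
            ratio_constraints=[RatioConstraint(HYD_FOCAL, HYD_DENOMINATOR, hyd_fraction)],
            reversible_overrides={COMPLEX_I: (-1000.0, 1000.0)},
            maintenance=maintenance,
            substrate_exchange=exchange,
        )

    uptake = carbon_uptake / carbons
    ratios = []
    if substrate == "CH4":
        ratios.append(RatioConstraint(FALDH_FOCAL, FALDH_DENOMINATOR, faldh_fraction))
    return Condition(
        name=f"{substrate} (qC={carbon_uptake:g})",
        uptake_bounds={exchange: uptake},
        ratio_constraints=ratios,
        maintenance=maintenance,
        substrate_exchange=exchange,
    )


# ---------------------------------------------------------------------------
# Condition YAML/JSON files

def save_condition(condition: Condition, path) -> None:
    doc = {
        "name": condition.name,
        "uptake_bounds": dict(condition.uptake_bounds),
        "ratio_constraints": [
            {"focal": rc.focal_reaction, "denominator": list(rc.denominator_reactions),
             "fraction": rc.fraction}
            for rc in condition.ratio_constraints
        ],
        "reversible_overrides": {k: list(v) for k, v in condition.reversible_overrides.items()},
        "substrate_exchange": condition.substrate_exchange,
        "o2_exchange": condition.o2_exchange,
        "co2_exchange": condition.co2_exchange,
    }
    if condition.maintenance is not None:
        doc["gam"] = condition.maintenance.gam
        doc["ngam"] = condition.maintenance.ngam
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_condition(path) -> Condition:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    maintenance = None
    if "gam" in doc or "ngam" in doc:
        maintenance = MaintenanceSpec(gam=float(doc.get("gam", 0.0)),
                                      ngam=float(doc.get("ngam", 0.0)))
    return Condition(
        name=doc.get("name", "condition"),
        uptake_bounds={k: float(v) for k, v in (doc.get("uptake_bounds") or {}).items()},
        ratio_constraints=[
            RatioConstraint(rc["focal"], tuple(rc["denominator"]), float(rc["fraction"]))
            for rc in doc.get("ratio_constraints") or []
        ],
        reversible_overrides={k: (float(v[0]), float(v[1]))
                              for k, v in (doc.get("reversible_overrides") or {}).items()},
        maintenance=maintenance,
        substrate_exchange=doc.get("substrate_exchange", ""),
        o2_exchange=doc.get("o2_exchange", "EX_o2_e"),
        co2_exchange=doc.get("co2_exchange", "EX_co2_e"),
    )


# ---------------------------------------------------------------------------
# Scans

@dataclass
class ScanResult:
    parameter: str
    grid: list[float]
    mu: list[float | None]  # None = infeasible
    segment_slopes: list[tuple[tuple[float, float], float]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.parameter: self.grid,
                             "mu": [np.nan if m is None else m for m in self.mu]})


def _segment_slopes(grid, mu, breakpoints=None):
    """Slopes d mu / d parameter over feasible spans.

    Without breakpoints: slope between consecutive feasible grid points.
    With breakpoints: least-squares slope within each interval.
    """
    pts = [(g, m) for g, m in zip(grid, mu) if m is not None]
    slopes: list[tuple[tuple[float, float], float]] = []
    if breakpoints:
        edges = [min(g for g, _ in pts), *sorted(breakpoints), max(g for g, _ in pts)]
        for x0, x1 in zip(edges[:-1], edges[1:]):
            seg = [(g, m) for g, m in pts if x0 <= g <= x1]
            if len(seg) >= 2:
                xs = np.array([g for g, _ in seg])
                ys = np.array([m for _, m in seg])
                slope = float(np.polyfit(xs, ys, 1)[0])
                slopes.append(((x0, x1), slope))
    else:
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            slopes.append(((x0, x1), (y1 - y0) / (x1 - x0)))
    return slopes


def scan_maintenance(
    model: MetabolicModel,
    condition: Condition,
    which: str,
    grid: list[float],
    breakpoints: list[float] | None = None,
    settings: SolverSettings | None = None,
) -> ScanResult:
    """Growth-rate sensitivity to GAM or NGAM over ``grid``."""
    if which not in ("gam", "ngam"):
        raise ModelError("which must be 'gam' or 'ngam'")
    if sorted(grid) != list(grid):
        raise ModelError("grid must be increasing")
    base = condition.maintenance or MaintenanceSpec(gam=0.0, ngam=0.0)
    mus: list[float | None] = []
    for value in grid:
        cond = replace(condition, maintenance=base.replace(**{which: value}))
        sol = solve_fba(model, cond, settings)
        mus.append(sol.objective_value if sol.optimal else None)
    return ScanResult(which, list(grid), mus, _segment_slopes(grid, mus, breakpoints))


def scan_formaldehyde_split(
    model: MetabolicModel,
    condition: Condition,
    alpha_grid: list[float],
    focal: str = FALDH_FOCAL,
    denominator: tuple[str, ...] = FALDH_DENOMINATOR,
    settings: SolverSettings | None = None,
) -> ScanResult:
    """Growth rate as a function of the fraction of total formaldehyde
    oxidation routed through the cytochrome-coupled branch."""
    if not denominator:
        raise ModelError("empty denominator set for formaldehyde split")
    mus: list[float | None] = []
    for alpha in alpha_grid:
        cond = condition.with_ratio(RatioConstraint(focal, tuple(denominator), alpha))
        sol = solve_fba(model, cond, settings)
        mus.append(sol.objective_value if sol.optimal else None)
    return ScanResult("faldh_fraction", list(alpha_grid), mus, _segment_slopes(alpha_grid, mus))


# ---------------------------------------------------------------------------
# H2 phase plane

@dataclass
class PhasePlaneResult:
    h2_grid: np.ndarray
    f_grid: np.ndarray
    mu: np.ndarray               # shape (len(h2_grid), len(f_grid)); NaN = infeasible
    complex_i_flux: np.ndarray   # positive = NADH-oxidizing (forward)
    atp_synthase_flux: np.ndarray


def _autotrophic_solution(model, h2, f, maintenance, settings, builder=None) -> tuple:
    if builder is None:
        cond = build_condition("H2+CO2", h2_uptake=h2, hyd_fraction=f, maintenance=maintenance)
    else:
        cond = builder(h2, f)
    sol = solve_fba(model, cond, settings)
    return cond, sol


def phase_plane_h2(
    model: MetabolicModel,
    h2_grid,
    f_grid,
    maintenance: MaintenanceSpec | None = None,
    complex_i: str = COMPLEX_I,
    atp_synthase: str = "ATPS4rpp",
    settings: SolverSettings | None = None,
    condition_builder=None,
) -> PhasePlaneResult:
    """Phase plane over H2 uptake and the periplasmic-hydrogenase
    fraction f; fluxes come from parsimonious solutions."""
    settings = settings or SolverSettings(parsimonious=True)
    h2_grid = np.asarray(h2_grid, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    shape = (len(h2_grid), len(f_grid))
    mu = np.full(shape, np.nan)
    ci = np.full(shape, np.nan)
    atps = np.full(shape, np.nan)
    for i, h2 in enumerate(h2_grid):
        for j, f in enumerate(f_grid):
            _, sol = _autotrophic_solution(model, h2, f, maintenance, settings,
                                           condition_builder)
            if sol.optimal:
                mu[i, j] = sol.objective_value
                ci[i, j] = sol.fluxes.get(complex_i, np.nan)
                atps[i, j] = sol.fluxes.get(atp_synthase, np.nan)
    return PhasePlaneResult(h2_grid, f_grid, mu, ci, atps)


def find_switch_fraction(
    model: MetabolicModel,
    h2_uptake: float = 13.2,
    maintenance: MaintenanceSpec | None = None,
    complex_i: str = COMPLEX_I,
    resolution: float = 1e-3,
    settings: SolverSettings | None = None,
    condition_builder=None,
) -> float | None:
    """Fraction f* at which complex I changes direction (zero crossing of
    its parsimonious flux) at fixed H2 uptake.

    Monotonicity of the complex-I flux in f is verified on a coarse grid
    first; returns ``None`` when the flux has no sign change on [0, 1].
    ``condition_builder(h2, f)`` can override how the autotrophic
    condition is constructed (e.g. for a different model namespace).
    """
    settings = settings or SolverSettings(parsimonious=True)

    def ci_flux(f: float) -> float | None:
        _, sol = _autotrophic_solution(model, h2_uptake, f, maintenance, settings,
                                       condition_builder)
        return sol.fluxes.get(complex_i) if sol.optimal else None

    coarse = np.linspace(0.0, 1.0, 11)
    vals = [ci_flux(f) for f in coarse]
    feas = [(f, v) for f, v in zip(coarse, vals) if v is not None]
    if len(feas) < 2:
        return None
    seq = [v for _, v in feas]
    if not all(a >= b - 1e-6 for a, b in zip(seq[:-1], seq[1:])):
        raise ModelError("complex-I flux is not monotone in f; switch search invalid")
    bracket = None
    for (f0, v0), (f1, v1) in zip(feas[:-1], feas[1:]):
        if v0 > 0 >= v1 or v0 >= 0 > v1:
            bracket = (f0, f1)
            break
    if bracket is None:
        return None
    lo, hi = bracket
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        v = ci_flux(mid)
        if v is None or v <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def find_min_h2_uptake(
    model: MetabolicModel,
    f: float = 1.0,
    maintenance: MaintenanceSpec | None = None,
    resolution: float = 1e-3,
    upper: float = 50.0,
    mu_min: float = 1e-6,
    settings: SolverSettings | None = None,
    condition_builder=None,
) -> float:
    """Smallest H2 uptake with feasible positive growth (mu > 1e-6 h^-1)
    at hydrogenase fraction ``f``, by bisection.

    Defaults to f = 1 — all H2 oxidized periplasmically, so every NADH
    must come from reverse electron flow through complex I.
    """
    settings = settings or SolverSettings()

    def grows(h2: float) -> bool:
        _, sol = _autotrophic_solution(model, h2, f, maintenance, settings,
                                       condition_builder)
        return sol.optimal and sol.objective_value > mu_min

    if not grows(upper):
        raise ModelError(f"no growth even at H2 uptake {upper}; cannot bracket threshold")
    lo, hi = 0.0, upper
    if grows(lo):
        return 0.0
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if grows(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Uptake-response regression and the substrate panel

@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    log_likelihood: float


@dataclass
class ResponseFit:
    o2: FitResult
    co2: FitResult
    ch4_grid: list[float]
    o2_uptake: list[float]
    co2_production: list[float]


def _ols(x: np.ndarray, y: np.ndarray) -> FitResult:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return FitResult(slope=float(res.params[1]), intercept=float(res.params[0]),
                     r_squared=float(res.rsquared), log_likelihood=float(res.llf))


def uptake_response_fit(
    model: MetabolicModel,
    ch4_grid=None,
    maintenance: MaintenanceSpec | None = None,
    faldh_fraction: float = 0.2,
    settings: SolverSettings | None = None,
) -> ResponseFit:
    """OLS fits of parsimonious O2 uptake and CO2 production against CH4
    uptake over ``ch4_grid`` (default 20 points on [1, 6])."""
    settings = settings or SolverSettings(parsimonious=True)
    grid = np.linspace(1.0, 6.0, 20) if ch4_grid is None else np.asarray(ch4_grid, float)
    ch4, o2, co2 = [], [], []
    for q in grid:
        cond = build_condition("CH4", carbon_uptake=float(q), maintenance=maintenance,
                               faldh_fraction=faldh_fraction)
        sol = solve_fba(model, cond, settings)
        if not sol.optimal:
            continue
        ch4.append(float(q))
        o2.append(abs(sol.fluxes[cond.o2_exchange]))
        co2.append(max(sol.fluxes[cond.co2_exchange], 0.0))
    if len(ch4) < 3:
        raise ModelError(f"only {len(ch4)} feasible grid points; need >= 3 for OLS")
    x = np.array(ch4)
    return ResponseFit(
        o2=_ols(x, np.array(o2)),
        co2=_ols(x, np.array(co2)),
        ch4_grid=ch4, o2_uptake=o2, co2_production=co2,
    )


def simulate_substrate_panel(
    model: MetabolicModel,
    substrates=("CH4", "propane", "isopropanol", "acetone"),
    carbon_uptake: float = 3.5,
    maintenance: MaintenanceSpec | None = None,
    cmol_weight: float = 24.6,
    cyo_id: str = "CYO1_KT",
    atps_id: str = "ATPS4rpp",
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Growth and yields per substrate at equal carbon uptake.

    Returns a frame indexed by substrate with mu, qS, yields, and the
    cytochrome-oxidase / ATP-synthase fluxes from the parsimonious
    solution (basis of the pairwise oxidase comparisons).  Infeasible
    substrates are recorded with status != "optimal", not raised.
    """
    settings = settings or SolverSettings(parsimonious=True)
    rows = []
    for substrate in substrates:
        cond = build_condition(substrate, carbon_uptake=carbon_uptake, maintenance=maintenance)
        sol = solve_fba(model, cond, settings)
        row = {"substrate": substrate, "status": sol.status,
               "mu": np.nan, "q_substrate": np.nan, "y_o2": np.nan,
               "y_co2": np.nan, "y_x": np.nan, "cyo_flux": np.nan, "atps_flux": np.nan}
        if sol.optimal:
            row.update(mu=sol.objective_value,
                       q_substrate=abs(sol.fluxes.get(cond.substrate_exchange, np.nan)),
                       cyo_flux=sol.fluxes.get(cyo_id, np.nan),
                       atps_flux=sol.fluxes.get(atps_id, np.nan))
            try:
                ys: YieldSet = compute_yields(sol, cond, cmol_weight)
                row.update(y_o2=ys.y_o2, y_co2=ys.y_co2, y_x=ys.y_x)
            except ModelError:
                pass  # zero uptake: yields stay NaN
        rows.append(row)
    return pd.DataFrame(rows).set_index("substrate")
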