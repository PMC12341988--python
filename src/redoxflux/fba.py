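"""Linear-programming core: FBA, ratio constraints, pFBA, and FVA.

Flux balance analysis is posed directly as the LP

    maximize   c' v
    subject to S v = 0,  lb <= v <= ub,

optionally augmented with *ratio constraints* — extra equality rows of
the form ``v_focal = fraction * sum(v_denominator)`` that pin the split
of a metabolite pool between competing routes (e.g. what fraction of
formaldehyde oxidation runs through the cytochrome-coupled branch).
Ratio constraints are genuine LP rows, not bound manipulations, so they
compose correctly with flux variability analysis and flux sampling.

Because FBA optima are typically degenerate, all per-reaction fluxes
reported by the higher-level scan/panel code come from the parsimonious
second stage: among all optima, minimize the total absolute flux
(positive/negative split reformulation).  This gives a deterministic,
documented tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError

__all__ = [
    "RatioConstraint",
    "SolverSettings",
    "FluxSolution",
    "FbaProblem",
    "solve_fba",
    "flux_variability",
]


@dataclass(frozen=True)
class RatioConstraint:
    """Linear flux-split constraint ``v_focal = fraction * sum(v_denom)``.

    The denominator set must contain the focal reaction and every
    denominator flux must be nonnegative in the scenario (irreversible
    forward), so that ``fraction`` reads as a share in [0, 1].
    """

    focal_reaction: str
    denominator_reactions: tuple[str, ...]
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ModelError(f"ratio fraction {self.fraction} outside [0, 1]")
        if self.focal_reaction not in self.denominator_reactions:
            raise ModelError(
                f"denominator of ratio constraint must include focal reaction "
                f"{self.focal_reaction!r}"
            )

    def row(self, index: dict[str, int], n: int) -> np.ndarray:
        """Dense coefficient row encoding the constraint over ``n`` fluxes."""
        row = np.zeros(n)
        for rid in self.denominator_reactions:
            if rid not in index:
                raise ModelError(f"ratio constraint references unknown reaction {rid!r}")
            row[index[rid]] -= self.fraction
        row[index[self.focal_reaction]] += 1.0
        return row


@dataclass
class SolverSettings:
    tolerance: float = 1e-9
    parsimonious: bool = False

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ModelError("solver tolerance must be positive")


@dataclass
class FluxSolution:
    """Result of one FBA solve.

    ``objective_value`` is the growth rate (h^-1) when the objective is
    biomass.  ``fluxes`` is empty unless ``status == "optimal"``.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: float = float("nan")
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class FbaProblem:
    """An FBA LP under construction: S v = 0 rows plus ratio rows."""

    def __init__(self, model: MetabolicModel, settings: SolverSettings | None = None):
        self.model = model
        self.settings = settings or SolverSettings()
        self.reaction_ids = model.reaction_ids
        self.index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self._S = sparse.csr_matrix(model.stoichiometric_matrix())
        self._extra_rows: list[np.ndarray] = []
        self.lb, self.ub = model.bounds_arrays()
        self.c = np.zeros(len(self.reaction_ids))
        self.c[self.index[model.objective_id]] = 1.0

    # -- construction --------------------------------------------------------
    def add_ratio_constraint(self, rc: RatioConstraint) -> "FbaProblem":
        self._extra_rows.append(rc.row(self.index, len(self.reaction_ids)))
        return self

    def set_bounds(self, reaction_id: str, lb: float, ub: float) -> None:
        j = self.index[reaction_id]
        if lb > ub:
            raise ModelError(f"bounds for {reaction_id}: lb {lb} > ub {ub}")
        self.lb[j], self.ub[j] = lb, ub

    @property
    def equality_matrix(self) -> sparse.csr_matrix:
        if not self._extra_rows:
            return self._S
        return sparse.vstack([self._S, sparse.csr_matrix(np.array(self._extra_rows))], format="csr")

    def _options(self) -> dict:
        tol = max(self.settings.tolerance, 1e-11)  # HiGHS floor
        return {
            "presolve": True,
            "primal_feasibility_tolerance": tol,
            "dual_feasibility_tolerance": tol,
        }

    # -- solving -------------------------------------------------------------
    def _linprog(self, c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
        return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                       bounds=bounds, method="highs", options=self._options())

    def solve(self, objective: np.ndarray | None = None, sense: str = "max",
              parsimonious: bool | None = None) -> FluxSolution:
        """Solve the LP; optionally refine to the parsimonious optimum."""
        c = self.c if objective is None else objective
        sign = -1.0 if sense == "max" else 1.0
        A_eq = self.equality_matrix
        b_eq = np.zeros(A_eq.shape[0])
        bounds = list(zip(self.lb, self.ub))
        res = self._linprog(sign * c, A_eq, b_eq, bounds)
        status = _STATUS.get(res.status, "failed")
        if status != "optimal":
            return FluxSolution(status=status)
        opt = float(c @ res.x)
        v = res.x
        if parsimonious if parsimonious is not None else self.settings.parsimonious:
            v = self._parsimonious(c, opt, A_eq)
        fluxes = {rid: float(v[j]) for rid, j in self.index.items()}
        return FluxSolution(status="optimal", objective_value=opt, fluxes=fluxes)

    def _parsimonious(self, c: np.ndarray, opt: float, A_eq) -> np.ndarray:
        """Minimize sum |v_i| at the fixed optimum via the t >= |v| split."""
        n = len(self.reaction_ids)
        A_fix = sparse.vstack([A_eq, sparse.csr_matrix(c)], format="csr")
        A_fix = sparse.hstack([A_fix, sparse.csr_matrix((A_fix.shape[0], n))], format="csr")
        b_fix = np.zeros(A_fix.shape[0])
        b_fix[-1] = opt
        eye = sparse.eye(n, format="csr")
        A_ub = sparse.vstack([
            sparse.hstack([eye, -eye]),    # v - t <= 0
            sparse.hstack([-eye, -eye]),   # -v - t <= 0
        ], format="csr")
        b_ub = np.zeros(2 * n)
        t_hi = np.maximum(np.abs(self.lb), np.abs(self.ub))
        bounds = list(zip(self.lb, self.ub)) + list(zip(np.zeros(n), t_hi))
        obj = np.concatenate([np.zeros(n), np.ones(n)])
        res = self._linprog(obj, A_fix, b_fix, bounds, A_ub=A_ub, b_ub=b_ub)
        if res.status != 0:  # pragma: no cover - degenerate numerics
            raise ModelError(f"parsimonious stage failed: {res.message}")
        return res.x[:n]

    def variability(self, reactions: list[str] | None = None,
                    fraction_of_optimum: float = 1.0) -> dict[str, tuple[float, float]]:
        """Per-reaction [min, max] flux with the objective held at or above
        ``fraction_of_optimum`` times its optimum."""
        base = self.solve()
        if not base.optimal:
            raise ModelError(f"FVA base problem is {base.status}")
        A_eq = self.equality_matrix
        b_eq = np.zeros(A_eq.shape[0])
        bounds = list(zip(self.lb, self.ub))
        A_ub = sparse.csr_matrix(-self.c)
        b_ub = np.array([-fraction_of_optimum * base.objective_value])
        out: dict[str, tuple[float, float]] = {}
        for rid in reactions or self.reaction_ids:
            j = self.index[rid]
            obj = np.zeros(len(self.reaction_ids))
            obj[j] = 1.0
            lo = self._linprog(obj, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
            hi = self._linprog(-obj, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
            if lo.status != 0 or hi.status != 0:
                raise ModelError(f"FVA subproblem for {rid} failed")
            out[rid] = (float(lo.x[j]), float(hi.x[j]))
        return out


def solve_fba(model: MetabolicModel, condition=None,
              settings: SolverSettings | None = None) -> FluxSolution:
    """Solve FBA for ``model``, optionally under a growth condition.

    ``condition`` is any object with an ``apply(model) -> (model, ratio
    constraints)`` method (see :class:`redoxflux.conditions.Condition`);
    passing ``None`` solves the model as-is.
    """
    ratio_constraints: list[RatioConstraint] = []
    if condition is not None:
        model, ratio_constraints = condition.apply(model)
    problem = FbaProblem(model, settings)
    for rc in ratio_constraints:
        problem.add_ratio_constraint(rc)
    return problem.solve()


def flux_variability(model: MetabolicModel, condition=None,
                     fraction_of_optimum: float = 1.0,
                     reactions: list[str] | None = None,
                     settings: SolverSettings | None = None) -> dict[str, tuple[float, float]]:
    """Flux ranges compatible with near-optimal growth (see
    :meth:`FbaProblem.variability`)."""
    ratio_constraints: list[RatioConstraint] = []
    if condition is not None:
        model, ratio_constraints = condition.apply(model)
    problem = FbaProblem(model, settings)
    for rc in ratio_constraints:
        problem.add_ratio_constraint(rc)
    return problem.variability(reactions, fraction_of_optimum)
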