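"""Uniform sampling of the steady-state flux polytope.

The sampler is an artificially-centered hit-and-run chain over the
polytope {v : A_eq v = b, lb <= v <= ub} (stoichiometric rows plus any
ratio-constraint rows).  The equality constraints are eliminated by
moving to the null space of A_eq, so every iterate satisfies S v = 0 to
numerical precision by construction; only the box bounds clip the chord.

Chain mechanics: a set of warmup points is generated by optimizing
random directions over the polytope (polytope vertices); the chain
starts at their mean (an interior point) and each step picks the
direction through the current point and a randomly chosen stored point
relative to the running center, then samples uniformly along the
feasible chord.  Directions are symmetric and independent of the
current point, so the uniform distribution is stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .fba import FbaProblem, RatioConstraint, SolverSettings
from .model import MetabolicModel, ModelError

__all__ = ["FluxSampleSet", "HitAndRunSampler", "sample_fluxes",
           "check_sample_validity", "save_samples_tsv", "load_samples_tsv"]


@dataclass
class FluxSampleSet:
    """Sampled steady-state flux vectors for one condition."""

    condition: str
    reaction_ids: list[str]
    samples: np.ndarray  # (n_samples, n_reactions)
    seed: int
    warmup: int
    thinning: int

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(reaction_id)]

    def medians(self) -> dict[str, float]:
        med = np.median(self.samples, axis=0)
        return dict(zip(self.reaction_ids, med.tolist()))


class HitAndRunSampler:
    """ACHR sampler over {v : A_eq v = b_eq, lb <= v <= ub}.

    ``A_eq`` may have zero rows (a plain box).  Fails loudly on
    unbounded coordinates or an infeasible polytope.
    """

    def __init__(self, A_eq: np.ndarray, b_eq: np.ndarray,
                 lb: np.ndarray, ub: np.ndarray, seed: int = 0,
                 n_warmup_points: int | None = None):
        self.lb = np.asarray(lb, float)
        self.ub = np.asarray(ub, float)
        n = len(self.lb)
        if not (np.all(np.isfinite(self.lb)) and np.all(np.isfinite(self.ub))):
            bad = [i for i in range(n)
                   if not (np.isfinite(self.lb[i]) and np.isfinite(self.ub[i]))]
            raise ModelError(f"polytope unbounded along coordinates {bad}")
        A_eq = np.asarray(A_eq, float).reshape(-1, n)
        self.A_eq = A_eq
        self.b_eq = np.asarray(b_eq, float)
        self.rng = np.random.default_rng(seed)
        self.N = null_space(A_eq) if A_eq.shape[0] else np.eye(n)
        if self.N.shape[1] == 0:
            self.N = np.zeros((n, 0))
        self.dim = self.N.shape[1]
        self._points = list(self._make_warmup(n_warmup_points))
        self._max_points = 500
        self.x = np.mean(self._points, axis=0)
        self.center = self.x.copy()
        self._n_seen = 1

    def _solve_dir(self, c: np.ndarray) -> np.ndarray:
        res = linprog(c, A_eq=self.A_eq if self.A_eq.shape[0] else None,
                      b_eq=self.b_eq if self.A_eq.shape[0] else None,
                      bounds=list(zip(self.lb, self.ub)), method="highs")
        if res.status != 0:
            raise ModelError(f"polytope infeasible or degenerate: {res.message}")
        return res.x

    def _make_warmup(self, count: int | None) -> np.ndarray:
        """Warmup vertices: minimize and maximize every coordinate (the
        flux-variability vertices), so the direction pool spans each
        coordinate's extremes, plus optional random-direction vertices."""
        n = len(self.lb)
        points = []
        if self.dim:
            for j in range(n):
                c = np.zeros(n)
                c[j] = 1.0
                if np.linalg.norm(self.N.T @ c) < 1e-12:
                    continue  # coordinate fixed by the equality rows
                points.append(self._solve_dir(c))
                points.append(self._solve_dir(-c))
            for _ in range(count or 0):
                points.append(self._solve_dir(self.N @ self.rng.standard_normal(self.dim)))
        if not points:
            points = [self._solve_dir(np.zeros(n))]
        return np.array(points)

    def _step(self) -> None:
        if self.dim == 0:
            return
        # alternate artificially-centered directions (stored point minus the
        # running center; good for elongated polytopes) with isotropic
        # null-space directions (guarantees irreducibility)
        if self.rng.random() < 0.5:
            pick = self._points[self.rng.integers(len(self._points))]
            direction = pick - self.center
        else:
            direction = self.N @ self.rng.standard_normal(self.dim)
        # project onto the null space to scrub numerical drift
        direction = self.N @ (self.N.T @ direction)
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            return
        direction /= norm
        # feasible chord: lb <= x + t*d <= ub
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = (self.lb - self.x) / direction
            hi = (self.ub - self.x) / direction
        t_lo = np.where(direction > 1e-12, lo, np.where(direction < -1e-12, hi, -np.inf))
        t_hi = np.where(direction > 1e-12, hi, np.where(direction < -1e-12, lo, np.inf))
        t_min, t_max = np.max(t_lo), np.min(t_hi)
        if t_max <= t_min:
            return
        t = self.rng.uniform(t_min, t_max)
        self.x = np.clip(self.x + t * direction, self.lb, self.ub)
        self._n_seen += 1
        self.center += (self.x - self.center) / self._n_seen

    def sample(self, n_samples: int, warmup_steps: int = 0, thinning: int = 1) -> np.ndarray:
        for _ in range(warmup_steps):
            self._step()
        out = np.empty((n_samples, len(self.lb)))
        for i in range(n_samples):
            for _ in range(thinning):
                self._step()
            out[i] = self.x
            # feed accepted samples back into the direction pool (ACHR)
            if len(self._points) < self._max_points:
                self._points.append(self.x.copy())
            else:
                self._points[self.rng.integers(self._max_points)] = self.x.copy()
        return out


def sample_fluxes(
    model: MetabolicModel,
    condition=None,
    n_samples: int = 10000,
    seed: int = 0,
    thinning: int = 100,
    warmup: int | None = None,
    settings: SolverSettings | None = None,
) -> FluxSampleSet:
    """Sample steady-state flux vectors uniformly for one condition.

    Growth is left free (no optimality constraint), matching the usual
    sampler default.  Warm-up defaults to 10x the polytope dimension.
    Reproducible given ``seed``.
    """
    ratio_constraints: list[RatioConstraint] = []
    name = "model"
    if condition is not None:
        model, ratio_constraints = condition.apply(model)
        name = getattr(condition, "name", "condition")
    problem = FbaProblem(model, settings)
    for rc in ratio_constraints:
        problem.add_ratio_constraint(rc)
    feas = problem.solve()
    if not feas.optimal:
        raise ModelError(f"condition {name!r} is {feas.status}; cannot sample")
    A_eq = problem.equality_matrix.toarray()
    sampler = HitAndRunSampler(A_eq, np.zeros(A_eq.shape[0]),
                               problem.lb, problem.ub, seed=seed)
    warmup = warmup if warmup is not None else 10 * sampler.dim
    samples = sampler.sample(n_samples, warmup_steps=warmup, thinning=thinning)
    return FluxSampleSet(name, problem.reaction_ids, samples, seed, warmup, thinning)


@dataclass
class SampleValidityReport:
    max_sv_per_row: np.ndarray
    bound_violations: int
    violating_rows: list[int] = field(default_factory=list)
    empirical_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def all_valid(self) -> bool:
        return self.bound_violations == 0 and not self.violating_rows


def check_sample_validity(
    sample_set: FluxSampleSet,
    model: MetabolicModel,
    ratio_constraints: list[RatioConstraint] | None = None,
    tol: float = 1e-6,
) -> SampleValidityReport:
    """Validate every sampled row: steady state (max |S v| per row),
    bound violations, and per-reaction empirical ranges."""
    if sample_set.samples.shape[1] != len(model.reactions):
        raise ModelError("sample matrix shape does not match model reaction count")
    order = [sample_set.reaction_ids.index(rid) for rid in model.reaction_ids]
    V = sample_set.samples[:, order]
    S = model.stoichiometric_matrix()
    rows = [S]
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for rc in ratio_constraints or []:
        rows.append(rc.row(index, len(model.reaction_ids))[None, :])
    A = np.vstack(rows)
    resid = np.abs(A @ V.T).max(axis=0)
    lb, ub = model.bounds_arrays()
    bad = (V < lb - tol) | (V > ub + tol)
    violating = sorted(set(np.nonzero(bad.any(axis=1) | (resid > tol))[0].tolist()))
    ranges = {rid: (float(V[:, j].min()), float(V[:, j].max()))
              for rid, j in index.items()}
    return SampleValidityReport(
        max_sv_per_row=resid,
        bound_violations=int(bad.sum()),
        violating_rows=violating,
        empirical_ranges=ranges,
    )


def save_samples_tsv(sample_set: FluxSampleSet, path: str | Path) -> None:
    """TSV matrix with # metadata header lines and reaction-id columns."""
    with open(path, "w") as fh:
        fh.write(f"#condition\t{sample_set.condition}\n")
        fh.write(f"#seed\t{sample_set.seed}\n")
        fh.write(f"#warmup\t{sample_set.warmup}\n")
        fh.write(f"#thinning\t{sample_set.thinning}\n")
        fh.write("\t".join(sample_set.reaction_ids) + "\n")
        np.savetxt(fh, sample_set.samples, delimiter="\t", fmt="%.10g")


def load_samples_tsv(path: str | Path) -> FluxSampleSet:
    meta = {"condition": "?", "seed": 0, "warmup": 0, "thinning": 1}
    header: list[str] = []
    data_start = 0
    with open(path) as fh:
        for line in fh:
            data_start += 1
            if line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("\t")
                meta[key] = value
            else:
                header = line.rstrip("\n").split("\t")
                break
    samples = np.loadtxt(path, delimiter="\t", skiprows=data_start, ndmin=2)
    return FluxSampleSet(str(meta["condition"]), header, samples,
                         int(meta["seed"]), int(meta["warmup"]), int(meta["thinning"]))
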