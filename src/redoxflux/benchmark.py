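"""Benchmarks against the published genome-scale model iAS473.

These routines reproduce the headline simulation numbers of the
published *Methylacidiphilum fumariolicum* reconstruction — Table-style
growth rates and yields, the complex-I directionality switch, the H2
feasibility threshold, and the ETC flux comparisons — given a local
copy of the model's SBML file.  The file itself is distributed in the
model's public repository and is not bundled here; download it once and
pass its path (default ``data/iAS473.xml`` at the repository root).

Reaction ids follow the published model's namespace (FALDHpp, HYD4pp,
NADH16pp, CYTCBB3pp1, ATPS4rpp, ...).  The formaldehyde- and
H2-oxidation denominators are discovered from the network by listing the
oxidative consumers of formaldehyde and H2, so minor id differences do
not break the ratio constraints.
"""

from __future__ import annotations

from pathlib import Path

from .conditions import Condition, find_min_h2_uptake, find_switch_fraction
from .curation import compute_yields
from .fba import RatioConstraint, SolverSettings, solve_fba
from .io import load_sbml
from .model import MetabolicModel, ModelError

__all__ = ["load_ias473", "consumers_of", "run_benchmarks", "DEFAULT_MODEL_PATH"]

DEFAULT_MODEL_PATH = Path("data") / "iAS473.xml"


def load_ias473(path: str | Path = DEFAULT_MODEL_PATH) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: place the published iAS473 SBML (from the "
            "model's public GitHub repository) at this path to run the "
            "external benchmarks"
        )
    return load_sbml(path)


def consumers_of(model: MetabolicModel, met_id: str,
                 skip: set[str] | None = None) -> list[str]:
    """Reactions consuming ``met_id`` in their forward direction,
    excluding exchanges, the biomass objective and any ids in ``skip``."""
    skip = skip or set()
    out = []
    for r in model.reactions:
        if r.is_exchange or r.id == model.objective_id or r.id in skip:
            continue
        if r.stoichiometry.get(met_id, 0.0) < 0:
            out.append(r.id)
    return out


def _first_metabolite(model: MetabolicModel, *candidates: str) -> str:
    for mid in candidates:
        if model.has_metabolite(mid):
            return mid
    raise ModelError(f"none of {candidates} present in model")


def _first_exchange(model: MetabolicModel, *candidates: str) -> str:
    for rid in candidates:
        if model.has_reaction(rid):
            return rid
    raise ModelError(f"none of {candidates} present in model")


def ch4_condition(model: MetabolicModel, uptake: float = 3.5, ngam: float = 3.5,
                  faldh_fraction: float | None = 0.2) -> Condition:
    """Methanotrophic condition on the published model: fixed CH4 uptake,
    NGAM, optionally the formaldehyde-split constraint."""
    ex_ch4 = _first_exchange(model, "EX_ch4_e", "EX_ch4(e)")
    ratios = []
    if faldh_fraction is not None:
        fald = _first_metabolite(model, "fald_c", "fald_p")
        denom = tuple(sorted(set(consumers_of(model, fald)) | {"FALDHpp"}))
        ratios.append(RatioConstraint("FALDHpp", denom, faldh_fraction))
    return Condition(
        name=f"iAS473 CH4 (q={uptake:g})",
        uptake_bounds={ex_ch4: uptake},
        ratio_constraints=ratios,
        maintenance=None,  # GAM is embedded in the published biomass reaction
        reversible_overrides={"ATPM": (ngam, 1000.0)},
        substrate_exchange=ex_ch4,
        o2_exchange=_first_exchange(model, "EX_o2_e", "EX_o2(e)"),
        co2_exchange=_first_exchange(model, "EX_co2_e", "EX_co2(e)"),
    )


def autotrophic_condition(model: MetabolicModel, h2_uptake: float = 13.2,
                          hyd_fraction: float = 0.76, ngam: float = 3.5) -> Condition:
    ex_h2 = _first_exchange(model, "EX_h2_e", "EX_h2(e)")
    ex_co2 = _first_exchange(model, "EX_co2_e", "EX_co2(e)")
    ex_ch4 = _first_exchange(model, "EX_ch4_e", "EX_ch4(e)")
    h2 = _first_metabolite(model, "h2_c", "h2_p")
    denom = tuple(sorted(set(consumers_of(model, h2)) | {"HYD4pp"}))
    return Condition(
        name=f"iAS473 H2+CO2 (q={h2_uptake:g})",
        uptake_bounds={ex_h2: h2_uptake, ex_co2: 1000.0, ex_ch4: 0.0},
        ratio_constraints=[RatioConstraint("HYD4pp", denom, hyd_fraction)],
        reversible_overrides={"NADH16pp": (-1000.0, 1000.0), "ATPM": (ngam, 1000.0)},
        substrate_exchange=ex_h2,
        o2_exchange=_first_exchange(model, "EX_o2_e", "EX_o2(e)"),
        co2_exchange=ex_co2,
    )


def c3_condition(model: MetabolicModel, substrate: str, carbon_uptake: float = 3.5,
                 ngam: float = 3.5) -> Condition:
    exchanges = {
        "propane": ("EX_prpn_e", "EX_ppan_e", "EX_prpan_e"),
        "isopropanol": ("EX_2ppoh_e", "EX_ipoh_e", "EX_iproh_e"),
        "acetone": ("EX_acetone_e", "EX_actn_e", "EX_act_e"),
    }[substrate]
    ex = _first_exchange(model, *exchanges)
    return Condition(
        name=f"iAS473 {substrate}",
        uptake_bounds={ex: carbon_uptake / 3.0,
                       _first_exchange(model, "EX_ch4_e", "EX_ch4(e)"): 0.0},
        reversible_overrides={"ATPM": (ngam, 1000.0)},
        substrate_exchange=ex,
        o2_exchange=_first_exchange(model, "EX_o2_e", "EX_o2(e)"),
        co2_exchange=_first_exchange(model, "EX_co2_e", "EX_co2(e)"),
    )


def run_benchmarks(path: str | Path = DEFAULT_MODEL_PATH) -> dict[str, float]:
    """Recompute the published model's headline numbers.

    Returns a mapping with structural counts, Table-style growth rates,
    the complex-I switch fraction, the H2 feasibility threshold, and the
    ETC flux comparisons.  Raises ``FileNotFoundError`` when the SBML is
    not available locally.
    """
    model = load_ias473(path)
    settings = SolverSettings(parsimonious=True)
    out: dict[str, float] = {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_orphan_reactions": sum(1 for r in model.reactions if not r.gene_rule.strip()),
    }

    cond = ch4_condition(model, faldh_fraction=None)
    sol = solve_fba(model, cond, settings)
    if sol.optimal:
        out["mu_ch4"] = sol.objective_value
        out["y_o2_ch4"] = compute_yields(sol, cond).y_o2

    cond_r = ch4_condition(model, faldh_fraction=0.2)
    sol_r = solve_fba(model, cond_r, settings)
    if sol_r.optimal:
        out["mu_ch4_faldh20"] = sol_r.objective_value
        out["y_o2_ch4_faldh20"] = compute_yields(sol_r, cond_r).y_o2

    auto = autotrophic_condition(model)
    sol_a = solve_fba(model, auto, settings)
    if sol_a.optimal:
        out["mu_h2co2"] = sol_a.objective_value
        out["atps_flux_f076"] = sol_a.fluxes.get("ATPS4rpp", float("nan"))

    # switch fraction and threshold on the published network
    def _auto(h2: float, f: float) -> Condition:
        return autotrophic_condition(model, h2_uptake=h2, hyd_fraction=f)

    f_star = find_switch_fraction(model, 13.2, condition_builder=_auto)
    if f_star is not None:
        out["switch_fraction"] = f_star
    out["min_h2_uptake"] = find_min_h2_uptake(model, f=1.0, condition_builder=_auto)

    for substrate in ("propane", "isopropanol", "acetone"):
        c3 = c3_condition(model, substrate)
        s3 = solve_fba(model, c3, settings)
        if s3.optimal:
            out[f"mu_{substrate}"] = s3.objective_value
            out[f"cyo_flux_{substrate}"] = s3.fluxes.get("CYTCBB3pp1", float("nan"))
    return out
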