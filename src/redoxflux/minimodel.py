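"""Deterministic mini methanotroph model generator.

Builds a ~50-reaction, 3-compartment (cytosol/periplasm/extracellular)
constraint-based model that embodies the network architecture of a
verrucomicrobial methanotroph:

* a menaquinone-based electron transport chain with a (optionally
  reversible) complex I, a menaquinol:cytochrome reductase surrogate for
  the alternative complex III, a proton-pumping cytochrome oxidase, and
  an ATP synthase whose H+/ATP stoichiometry is derived from the P/O
  ratio;
* methane oxidation by a menaquinol-consuming monooxygenase (PMMO), a
  cytochrome-coupled methanol dehydrogenase (XoxF type) that can also
  oxidize formaldehyde directly (the FALDHpp branch), the THF-mediated
  formaldehyde-to-formate route producing NADH and ATP, and formate
  dehydrogenase;
* exclusive CO2 assimilation through a lumped Calvin-Benson-Bassham
  reaction;
* periplasmic (quinone-coupled) and cytosolic (NAD-coupled)
  hydrogenases for autotrophic growth on H2+CO2;
* the C3 chain propane -> isopropanol -> acetone -> acetol ->
  methylglyoxal -> pyruvate (the last conversion lumped into one step);
* lumped glycolysis, pyruvate dehydrogenase and TCA, five lumped
  biomass precursor pools, growth- and non-growth-associated ATP
  maintenance.

Every internal reaction is elementally balanced (C, H, O, N, P, S) by
construction; the proton motive force is carried by a distinct
periplasmic proton pool with no exchange, and an irreversible proton
leak dissipates excess gradient.  The generator is deterministic for a
fixed config; mini-model growth rates reproduce the published model's
trade-off *structure*, not its numeric values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import Condition, build_condition
from .curation import BiomassSpec, MaintenanceSpec, normalize_biomass, set_maintenance
from .model import MetabolicModel, Metabolite, ModelError, Reaction

__all__ = ["MiniModelConfig", "ConditionFixture", "build_minimodel", "default_fixtures"]

BIG = 1000.0


@dataclass(frozen=True)
class MiniModelConfig:
    """Knobs of the generator.

    po_ratio sets the ATP-synthase H+/ATP stoichiometry given the proton
    yield of the NADH->O2 chain; aciii_protons is the number of protons
    the complex-III surrogate translocates per menaquinol (its true
    stoichiometry is unresolved, so it is a knob); gam/ngam are the ATP
    maintenance defaults; seed drives optional bound jitter for test
    variants only — the default model is seed-independent.
    """

    po_ratio: float = 2.5
    aciii_protons: int = 2
    gam: float = 10.86
    ngam: float = 3.5
    include_c3_pathway: bool = True
    include_hydrogenases: bool = True
    reversible_complex_i: bool = False
    bound_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.po_ratio <= 0:
            raise ModelError("po_ratio must be positive")
        if self.aciii_protons < 0 or self.aciii_protons != int(self.aciii_protons):
            raise ModelError("aciii_protons must be a nonnegative integer")


@dataclass
class ConditionFixture:
    """A named condition plus its expected qualitative outcome."""

    name: str
    condition: Condition
    growth_feasible: bool
    complex_i_sign: int | None = None  # +1 forward (NADH-oxidizing), -1 reverse, None unasserted


# metabolite id -> (name, compartment, formula, charge)
_METS: dict[str, tuple[str, str, str, int]] = {
    # extracellular
    "ch4_e": ("methane", "e", "CH4", 0),
    "o2_e": ("oxygen", "e", "O2", 0),
    "co2_e": ("carbon dioxide", "e", "CO2", 0),
    "nh4_e": ("ammonium", "e", "H4N", 1),
    "pi_e": ("phosphate", "e", "H3O4P", 0),
    "h2o_e": ("water", "e", "H2O", 0),
    "h_e": ("proton", "e", "H", 1),
    "h2_e": ("hydrogen", "e", "H2", 0),
    "prpn_e": ("propane", "e", "C3H8", 0),
    "ipoh_e": ("isopropanol", "e", "C3H8O", 0),
    "actn_e": ("acetone", "e", "C3H6O", 0),
    # periplasm
    "h_p": ("periplasmic proton", "p", "H", 1),
    "ficytc_p": ("oxidized cytochrome c", "p", "Fe", 3),
    "focytc_p": ("reduced cytochrome c", "p", "Fe", 2),
    # cytosol
    "ch4_c": ("methane", "c", "CH4", 0),
    "o2_c": ("oxygen", "c", "O2", 0),
    "co2_c": ("carbon dioxide", "c", "CO2", 0),
    "nh4_c": ("ammonium", "c", "H4N", 1),
    "pi_c": ("phosphate", "c", "H3O4P", 0),
    "h2o_c": ("water", "c", "H2O", 0),
    "h_c": ("proton", "c", "H", 1),
    "h2_c": ("hydrogen", "c", "H2", 0),
    "prpn_c": ("propane", "c", "C3H8", 0),
    "ipoh_c": ("isopropanol", "c", "C3H8O", 0),
    "actn_c": ("acetone", "c", "C3H6O", 0),
    "actol_c": ("acetol", "c", "C3H6O2", 0),
    "mgx_c": ("methylglyoxal", "c", "C3H4O2", 0),
    "meoh_c": ("methanol", "c", "CH4O", 0),
    "fald_c": ("formaldehyde", "c", "CH2O", 0),
    "for_c": ("formate", "c", "CH2O2", 0),
    "mqn_c": ("menaquinone (head-group surrogate)", "c", "C11H8O2", 0),
    "mql_c": ("menaquinol (head-group surrogate)", "c", "C11H10O2", 0),
    "atp_c": ("ATP", "c", "C10H16N5O13P3", 0),
    "adp_c": ("ADP", "c", "C10H15N5O10P2", 0),
    "nad_c": ("NAD+", "c", "C21H26N7O14P2", -1),
    "nadh_c": ("NADH", "c", "C21H27N7O14P2", -2),
    "nadp_c": ("NADP+", "c", "C21H25N7O17P3", -3),
    "nadph_c": ("NADPH", "c", "C21H26N7O17P3", -4),
    "g3p_c": ("glyceraldehyde 3-phosphate", "c", "C3H7O6P", 0),
    "pyr_c": ("pyruvate", "c", "C3H4O3", 0),
    "coa_c": ("coenzyme A", "c", "C21H36N7O16P3S", 0),
    "accoa_c": ("acetyl-CoA", "c", "C23H38N7O17P3S", 0),
    "prot_c": ("protein pool (alanine equivalent)", "c", "C3H7NO2", 0),
    "nucl_c": ("nucleotide pool (AMP equivalent)", "c", "C10H14N5O7P", 0),
    "lip_c": ("lipid pool (octanoate equivalent)", "c", "C8H16O2", 0),
    "carb_c": ("carbohydrate pool (glucan equivalent)", "c", "C6H10O5", 0),
    "cof_c": ("cofactor pool", "c", "C6H8N2O3", 0),
}

#: Raw biomass precursor demands (mmol per gDW before normalization).
_BIOMASS_PRECURSORS = {"prot_c": 6.0, "nucl_c": 0.5, "carb_c": 1.0,
                       "lip_c": 0.5, "cof_c": 0.2}

_C3_METS = {"prpn_e", "ipoh_e", "actn_e", "prpn_c", "ipoh_c", "actn_c",
            "actol_c", "mgx_c"}
_H2_METS = {"h2_e", "h2_c"}

# exchange id stem -> (default max uptake, max secretion); substrates are
# closed by default and opened by conditions.
_EXCHANGES = {
    "ch4_e": (0.0, BIG), "o2_e": (BIG, BIG), "co2_e": (0.0, BIG),
    "nh4_e": (BIG, BIG), "pi_e": (BIG, BIG), "h2o_e": (BIG, BIG),
    "h_e": (BIG, BIG), "h2_e": (0.0, BIG), "prpn_e": (0.0, BIG),
    "ipoh_e": (0.0, BIG), "actn_e": (0.0, BIG),
}


def _core_reactions(cfg: MiniModelConfig) -> list[Reaction]:
    atps_protons = (8.0 + cfg.aciii_protons) / cfg.po_ratio
    k = float(cfg.aciii_protons)
    ci_lb = -BIG if cfg.reversible_complex_i else 0.0
    r = Reaction
    rxns = [
        # --- C1 oxidation -------------------------------------------------
        r("PMMOipp", {"ch4_c": -1, "o2_c": -1, "mql_c": -1,
                      "meoh_c": 1, "h2o_c": 1, "mqn_c": 1},
          0, BIG, gene_rule="pmoCAB", subsystem="Methane oxidation",
          name="particulate methane monooxygenase (menaquinol-coupled)"),
        r("MEOHDHpp", {"meoh_c": -1, "ficytc_p": -2,
                       "fald_c": 1, "focytc_p": 2, "h_p": 2},
          0, BIG, gene_rule="xoxF", subsystem="Methane oxidation",
          name="methanol dehydrogenase (XoxF type, cytochrome-coupled)"),
        r("FALDHpp", {"fald_c": -1, "h2o_c": -1, "ficytc_p": -2,
                      "for_c": 1, "focytc_p": 2, "h_p": 2},
          0, BIG, gene_rule="xoxF", subsystem="Methane oxidation",
          name="direct formaldehyde oxidation by XoxF-MDH"),
        r("THFOX", {"fald_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
                    "for_c": 1, "nadh_c": 1, "h_c": 1, "atp_c": 1},
          0, BIG, gene_rule="folD and fhs", subsystem="THF pathway",
          name="THF-mediated formaldehyde oxidation (lumped)"),
        r("FDH", {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1, "h_c": 1},
          0, BIG, gene_rule="fdhA", subsystem="THF pathway",
          name="formate dehydrogenase"),
        # --- carbon assimilation and central metabolism -------------------
        r("CBB", {"co2_c": -3, "atp_c": -9, "nadph_c": -6, "h_c": -6, "h2o_c": -5,
                  "g3p_c": 1, "adp_c": 9, "pi_c": 8, "nadp_c": 6},
          0, BIG, gene_rule="cbbL and cbbS and prkB", subsystem="CBB cycle",
          name="Calvin-Benson-Bassham CO2 fixation (lumped)"),
        r("GLYC", {"g3p_c": -1, "nad_c": -1, "adp_c": -2, "pi_c": -1,
                   "pyr_c": 1, "nadh_c": 1, "atp_c": 2, "h2o_c": 1, "h_c": 1},
          -BIG, BIG, gene_rule="gap and pyk", subsystem="Glycolysis",
          name="lower glycolysis / gluconeogenesis (lumped)"),
        r("PDH", {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
                  "accoa_c": 1, "co2_c": 1, "nadh_c": 1, "h_c": 1},
          0, BIG, gene_rule="aceEF and lpd", subsystem="Glycolysis",
          name="pyruvate dehydrogenase"),
        r("TCA", {"accoa_c": -1, "nad_c": -3, "mqn_c": -1, "adp_c": -1,
                  "pi_c": -1, "h2o_c": -2,
                  "coa_c": 1, "co2_c": 2, "nadh_c": 3, "mql_c": 1,
                  "atp_c": 1, "h_c": 3},
          0, BIG, gene_rule="gltA and sdhABCD", subsystem="TCA cycle",
          name="tricarboxylic acid cycle (lumped)"),
        r("THD", {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1},
          -BIG, BIG, gene_rule="sthA", subsystem="Redox balancing",
          name="soluble transhydrogenase"),
        # --- electron transport chain -------------------------------------
        r("NADH16pp", {"nadh_c": -1, "h_c": -5, "mqn_c": -1,
                       "nad_c": 1, "mql_c": 1, "h_p": 4},
          ci_lb, BIG, gene_rule="nuoA and nuoN", subsystem="ETC",
          name="NADH:menaquinone oxidoreductase (complex I)"),
        r("ACIIIpp", {"mql_c": -1, "ficytc_p": -2, "h_c": -k,
                      "mqn_c": 1, "focytc_p": 2, "h_p": 2.0 + k},
          0, BIG, gene_rule="actAB", subsystem="ETC",
          name="menaquinol:cytochrome c reductase (ACIII surrogate)"),
        r("CYO1_KT", {"focytc_p": -2, "o2_c": -0.5, "h_c": -4,
                      "ficytc_p": 2, "h2o_c": 1, "h_p": 2},
          0, BIG, gene_rule="ccoNOP", subsystem="ETC",
          name="cytochrome c oxidase (two protons translocated)"),
        r("ATPS4rpp", {"adp_c": -1, "pi_c": -1, "h_p": -atps_protons,
                       "atp_c": 1, "h2o_c": 1, "h_c": atps_protons},
          -BIG, BIG, gene_rule="atpABC", subsystem="ETC",
          name="ATP synthase"),
        r("HLEAKpp", {"h_p": -1, "h_c": 1},
          0, BIG, subsystem="ETC", name="proton leak (gradient dissipation)"),
        # --- maintenance and biomass --------------------------------------
        r("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
          0.0, BIG, subsystem="Maintenance", name="non-growth ATP maintenance"),
        r("BIOMASS", {m: -c for m, c in _BIOMASS_PRECURSORS.items()},
          0, BIG, subsystem="Biomass", name="biomass drain"),
        # --- precursor pools ----------------------------------------------
        r("PROTS", {"pyr_c": -1, "nh4_c": -1, "nadph_c": -1, "atp_c": -4,
                    "h2o_c": -3, "prot_c": 1, "nadp_c": 1, "adp_c": 4, "pi_c": 4},
          0, BIG, gene_rule="alaA", subsystem="Amino acid metabolism",
          name="protein pool synthesis (lumped)"),
        r("NUCS", {"pyr_c": -2, "g3p_c": -2, "nh4_c": -5, "atp_c": -6,
                   "nad_c": -2, "h2o_c": -3,
                   "nucl_c": 1, "co2_c": 2, "adp_c": 6, "pi_c": 7,
                   "nadh_c": 2, "h_c": 17},
          0, BIG, gene_rule="purF", subsystem="Nucleotide metabolism",
          name="nucleotide pool synthesis (lumped)"),
        r("LIPS", {"accoa_c": -4, "nadph_c": -4, "h_c": -8,
                   "lip_c": 1, "coa_c": 4, "nadp_c": 4, "h2o_c": 2},
          0, BIG, gene_rule="fabB", subsystem="Lipid metabolism",
          name="lipid pool synthesis (lumped)"),
        r("CARBS", {"g3p_c": -2, "atp_c": -1, "h2o_c": -2,
                    "carb_c": 1, "adp_c": 1, "pi_c": 3},
          0, BIG, gene_rule="glgA", subsystem="Carbohydrate metabolism",
          name="carbohydrate pool synthesis (lumped)"),
        r("COFS", {"pyr_c": -2, "nh4_c": -2, "atp_c": -2, "nadph_c": -1,
                   "cof_c": 1, "adp_c": 2, "pi_c": 2, "nadp_c": 1,
                   "h2o_c": 1, "h_c": 3},
          0, BIG, gene_rule="thiC", subsystem="Cofactor metabolism",
          name="cofactor pool synthesis (lumped)"),
    ]
    if cfg.include_hydrogenases:
        rxns += [
            r("HYD4pp", {"h2_c": -1, "mqn_c": -1, "mql_c": 1},
              0, BIG, gene_rule="hyd1d", subsystem="Hydrogen metabolism",
              name="periplasmic quinone-coupled hydrogenase"),
            r("NAD_H2", {"h2_c": -1, "nad_c": -1, "nadh_c": 1, "h_c": 1},
              0, BIG, gene_rule="hyd3b", subsystem="Hydrogen metabolism",
              name="cytosolic NAD-coupled hydrogenase"),
        ]
    if cfg.include_c3_pathway:
        rxns += [
            r("PMMO2pp", {"prpn_c": -1, "o2_c": -1, "mql_c": -1,
                          "ipoh_c": 1, "h2o_c": 1, "mqn_c": 1},
              0, BIG, gene_rule="pmoCAB", subsystem="C3 assimilation",
              name="propane monooxygenation by PMMO"),
            r("IPOHDH", {"ipoh_c": -1, "nad_c": -1,
                         "actn_c": 1, "nadh_c": 1, "h_c": 1},
              0, BIG, gene_rule="gmcA", subsystem="C3 assimilation",
              name="isopropanol dehydrogenase (GMC oxidoreductase)"),
            r("ACTNMO", {"actn_c": -1, "o2_c": -1, "nadh_c": -1, "h_c": -1,
                         "actol_c": 1, "h2o_c": 1, "nad_c": 1},
              0, BIG, gene_rule="acmAB", subsystem="C3 assimilation",
              name="acetone monooxygenase"),
            r("ACTOLDH", {"actol_c": -1, "nad_c": -1,
                          "mgx_c": 1, "nadh_c": 1, "h_c": 1},
              0, BIG, gene_rule="gmcB", subsystem="C3 assimilation",
              name="acetol dehydrogenase"),
            r("MGXDH", {"mgx_c": -1, "h2o_c": -1, "nad_c": -1,
                        "pyr_c": 1, "nadh_c": 1, "h_c": 1},
              0, BIG, gene_rule="mgsX", subsystem="C3 assimilation",
              name="methylglyoxal to pyruvate (three-step pathway, lumped)"),
        ]
    return rxns


def build_minimodel(config: MiniModelConfig | None = None) -> MetabolicModel:
    """Construct the mini methanotroph model (deterministic for a fixed
    config; ``seed`` only matters when ``bound_jitter`` > 0)."""
    cfg = config or MiniModelConfig()
    met_ids = dict(_METS)
    if not cfg.include_c3_pathway:
        met_ids = {k: v for k, v in met_ids.items() if k not in _C3_METS}
    if not cfg.include_hydrogenases:
        met_ids = {k: v for k, v in met_ids.items() if k not in _H2_METS}
    metabolites = [Metabolite(mid, name, comp, formula, charge)
                   for mid, (name, comp, formula, charge) in met_ids.items()]

    reactions = _core_reactions(cfg)
    for stem, (up, down) in _EXCHANGES.items():
        if stem not in met_ids:
            continue
        base = stem[:-2]
        reactions.append(Reaction(f"EX_{stem}", {stem: -1.0}, -up, down,
                                  subsystem="Exchange", name=f"{base} exchange"))
        reactions.append(Reaction(f"{base.upper()}t", {stem: -1.0, f"{base}_c": 1.0},
                                  -BIG, BIG, subsystem="Transport",
                                  name=f"{base} transport (diffusion)"))

    if cfg.bound_jitter > 0:
        rng = np.random.default_rng(cfg.seed)
        for rxn in reactions:
            if rxn.subsystem in ("Exchange", "Transport", "Biomass", "Maintenance"):
                continue
            scale = 1.0 + cfg.bound_jitter * rng.uniform(-1.0, 1.0)
            if rxn.upper_bound not in (0.0,):
                rxn.upper_bound = abs(rxn.upper_bound) * scale
            if rxn.lower_bound not in (0.0,):
                rxn.lower_bound = -abs(rxn.lower_bound) * scale

    model = MetabolicModel(metabolites, reactions, "BIOMASS", id="mini_methanotroph")
    model = normalize_biomass(model, BiomassSpec())
    model = set_maintenance(model, MaintenanceSpec(gam=cfg.gam, ngam=cfg.ngam,
                                                   po_ratio=cfg.po_ratio))
    return model


def default_fixtures(config: MiniModelConfig | None = None) -> list[ConditionFixture]:
    """The five standard growth scenarios: methanotrophic (CH4 at 3.5
    C-mmol gDW^-1 h^-1), autotrophic (13.2 mmol H2 with the 0.76
    periplasmic split and reversible complex I), and the three C3
    substrates at the same equivalent carbon uptake."""
    cfg = config or MiniModelConfig()
    maint = MaintenanceSpec(gam=cfg.gam, ngam=cfg.ngam, po_ratio=cfg.po_ratio)
    fixtures = [
        ConditionFixture("CH4", build_condition("CH4", 3.5, maint), True, complex_i_sign=+1),
        ConditionFixture("H2+CO2", build_condition("H2+CO2", maintenance=maint, h2_uptake=13.2),
                         True, complex_i_sign=None),
        ConditionFixture("propane", build_condition("propane", 3.5, maint), True, +1),
        ConditionFixture("isopropanol", build_condition("isopropanol", 3.5, maint), True, +1),
        ConditionFixture("acetone", build_condition("acetone", 3.5, maint), True, +1),
    ]
    return fixtures
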