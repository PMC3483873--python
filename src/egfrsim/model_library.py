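"""Construction of the EGFR-signaling models and their perturbation variants.

The normal-cell model couples a receptor layer (EGF binding, dimerization,
autophosphorylation, internalization with recycling/degradation) to three
downstream branches:

* **Ras/ERK** — SOS recruitment through both the direct Grb2 route and the
  Shc-dependent route, Ras-GDP→GTP exchange, Raf1 activation by Ras-GTP,
  double phosphorylation of MEK and ERK, first-order phosphatase
  back-reactions, and ERK-level negative feedback that inactivates SOS.
* **PI3K/Akt** — receptor-bound PI3K, PIP2→PIP3, PIP3–PDK1 membrane
  recruitment, PDK1-mediated Akt phosphorylation, and PTEN-catalysed
  PIP3→PIP2 hydrolysis.
* **STAT3** — receptor binding and phosphorylation of cytoplasmic STAT3,
  homodimerization, nuclear import, nuclear dephosphorylation and export.

The NSCLC variant applies the disease construction rules: EGFR over-expressed
three-fold; Ras, PI3K, Akt and STAT3 two-fold; mutant (L858R) receptor
kinetics with slowed autophosphorylation and EGF-dependent internalization
rate constants halved relative to wild type.  PTEN loss and erlotinib
treatment are further overlays.

All kinetic constants live in :data:`DEFAULT_CONSTANTS` so the calibration
module can rebuild any scenario from an edited constant set.  When a
supplementary SBML file is supplied, topology and constants come from it
verbatim instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import EgfrSimError, ValidationError
from .reaction_network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
)
from .simulation import Observable

#: Molecular weight of EGF (g/mol), the unit bridge for ng/ml doses.
EGF_MOLECULAR_WEIGHT = 6045.0

#: EGF stimulus used throughout the study conditions (ng/ml).
DEFAULT_EGF_DOSE = 50.0

#: Erlotinib dose used in the inhibition scenarios (µmol/L, the cellular IC50).
DEFAULT_ERLOTINIB_DOSE = 10.0

SCENARIO_NAMES = (
    "normal",
    "nsclc",
    "nsclc_pten_loss",
    "normal_erlotinib",
    "nsclc_erlotinib",
    "nsclc_pten_loss_erlotinib",
)

#: NSCLC construction rules (dimensionless fold changes).
EGFR_OVEREXPRESSION_FOLD = 3.0
DOWNSTREAM_OVEREXPRESSION_FOLD = 2.0
MUTANT_INTERNALIZATION_FACTOR = 0.5  # wt/mutant internalization rate ratio = 2


def egf_dose_to_concentration(dose_ng_per_ml: float) -> float:
    """Convert an EGF dose in ng/ml to nM (ng/ml = µg/L; µg/L ÷ g/mol = nM)."""
    if dose_ng_per_ml < 0:
        raise ValidationError(f"EGF dose must be >= 0, got {dose_ng_per_ml}")
    return dose_ng_per_ml * 1e3 / EGF_MOLECULAR_WEIGHT


def erlotinib_dose_to_concentration(dose_umol_per_l: float) -> float:
    """Convert an erlotinib dose in µmol/L to nM."""
    if dose_umol_per_l < 0:
        raise ValidationError(f"erlotinib dose must be >= 0, got {dose_umol_per_l}")
    return dose_umol_per_l * 1e3


@dataclass
class Scenario:
    """A named overlay set applied to the base model before simulation."""

    name: str = "normal"
    egf_dose: float = DEFAULT_EGF_DOSE
    erlotinib_dose: float | None = None
    overrides: dict[str, float] = field(default_factory=dict)
    clamp_egf: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValidationError(
                f"scenario name {self.name!r} not in {SCENARIO_NAMES}"
            )
        if self.erlotinib_dose is None:
            self.erlotinib_dose = (
                DEFAULT_ERLOTINIB_DOSE if self.name.endswith("erlotinib") else 0.0
            )
        if self.egf_dose < 0 or self.erlotinib_dose < 0:
            raise ValidationError("doses must be >= 0")


@dataclass
class ModificationRule:
    """A recorded edit applied during scenario construction."""

    kind: str  # scale_initial | scale_parameter | zero_species | add_reaction
    target: str
    factor: float | None = None

    def as_dict(self) -> dict:
        return {"kind": self.kind, "target": self.target, "factor": self.factor}


# --------------------------------------------------------------------------
# Calibrated fallback constants.
#
# First-order constants in s^-1, second-order in nM^-1 s^-1, Km in nM,
# initial amounts in nM.  The receptor-layer association/dissociation
# constants follow the range used by classic EGFR models; the cascade
# catalytic constants and phosphatase rates were fitted by the calibration
# module against the bundled kinetic-feature targets (see egfrsim.calibration
# and docs/methods.md).
# --------------------------------------------------------------------------
DEFAULT_CONSTANTS: dict[str, float] = {
    # receptor layer
    "kon_egf": 0.02, "koff_egf": 0.01,
    "kon_dim": 0.5, "koff_dim": 0.01,
    "k_phos": 0.5, "k_rdephos": 0.003,
    "k_int": 0.008, "k_recycle": 0.006, "k_degrade": 0.0015,
    "mutant_phos_scale": 1.0,           # set < 1 by the NSCLC build
    # Ras/ERK branch
    "kon_grb": 0.003, "koff_grb": 0.05,
    "kon_sos": 0.01, "koff_sos": 0.06,
    "kon_shc": 0.0045, "koff_shc": 0.6,
    "k_shcphos": 1.0, "k_pshc_release": 0.1,
    "kon_grb_shc": 0.003, "koff_grb_shc": 0.1,
    "kon_sos_shc": 0.01, "koff_sos_shc": 0.02,
    "kcat_sos": 4.0, "Km_ras": 30.0,
    "k_gap": 0.02,
    "kcat_raf": 0.05, "Km_raf": 30.0, "k_rafdeact": 0.012,
    "kcat_mek": 0.02, "Km_mek": 50.0, "k_mekptase": 0.008,
    "kcat_erk": 0.02, "Km_erk": 50.0, "k_erkptase": 0.0005,
    "kcat_fb": 0.0005, "Km_fb": 100.0, "k_fbrecover": 0.002,
    "k_mkp_induce": 0.017, "Km_mkp_induce": 5.0, "k_mkp_decay": 0.0055,
    "kcat_mkp": 0.105, "Km_mkp": 2.0,
    # PI3K/Akt branch
    "kon_pi3k": 0.04, "koff_pi3k": 0.05,
    "kcat_pi3k": 8.0, "Km_pip2": 200.0,
    "kcat_pten": 0.6, "Km_pip3": 50.0,
    "kon_pdk": 0.01, "koff_pdk": 0.3,
    "kcat_akt": 1.1, "Km_akt": 30.0, "k_aktptase": 0.12,
    # STAT3 branch
    "kon_stat": 0.032, "koff_stat": 0.4,
    "kcat_stat": 0.35, "k_statptase_c": 0.006,
    "kon_statdim": 0.003, "koff_statdim": 0.01,
    "k_import": 0.009, "k_statptase_n": 0.001, "k_export": 0.005,
    # erlotinib (effective ATP-pocket competition at the dimer level)
    "kon_erl": 2e-4, "koff_erl": 0.06,
}

#: Initial amounts of the normal model (nM); zero-initial species omitted.
DEFAULT_INITIAL_AMOUNTS: dict[str, float] = {
    "EGFR": 0.5,
    "Grb2": 80.0,
    "SOS": 40.0,
    "Shc": 100.0,
    "Ras_GDP": 120.0,
    "Raf": 100.0,
    "MEK": 200.0,
    "ERK": 600.0,
    "PI3K": 50.0,
    "PIP2": 600.0,
    "PDK1": 100.0,
    "Akt": 300.0,
    "PTEN": 50.0,
    "STAT3c": 300.0,
}

#: Receptor-containing surface complexes and the cargo released on endocytosis.
_SURFACE_COMPLEXES: dict[str, tuple[int, list[str]]] = {
    # species id -> (receptor copies, released cargo species)
    "EGF_EGFR": (1, []),
    "EGF_EGFR2": (2, []),
    "pEGF_EGFR2": (2, []),
    "R_Grb2": (2, ["Grb2"]),
    "R_Grb2_SOS": (2, ["Grb2", "SOS"]),
    "R_Shc": (2, ["Shc"]),
    "R_pShc": (2, ["Shc"]),
    "R_pShc_Grb2": (2, ["Shc", "Grb2"]),
    "R_pShc_Grb2_SOS": (2, ["Shc", "Grb2", "SOS"]),
    "R_PI3K": (2, ["PI3K"]),
    "R_STAT3": (2, ["STAT3c"]),
}


def _ma(k1: float, kr1: float | None = None) -> RateLaw:
    if kr1 is None:
        return RateLaw(MASS_ACTION_IRREVERSIBLE, k1=k1)
    return RateLaw(MASS_ACTION_REVERSIBLE, k1=k1, kr1=kr1)


def _mm(k2: float, Km: float) -> RateLaw:
    return RateLaw(MICHAELIS_MENTEN, k2=k2, Km=Km)


def build_normal_model(
    source: str | None = None,
    constants: Mapping[str, float] | None = None,
    initial_amounts: Mapping[str, float] | None = None,
) -> ReactionNetwork:
    """Build the normal-cell EGFR signaling network.

    When *source* points to an SBML file, topology and all constants are taken
    from it verbatim.  Otherwise the calibrated fallback topology documented
    in the module docstring is instantiated; *constants* and
    *initial_amounts* override individual defaults (used by calibration and
    scenario overrides).
    """
    if source is not None:
        from .sbml_io import read_sbml

        net, _ = read_sbml(source)
        net.metadata.setdefault("source", str(source))
        return net

    k = dict(DEFAULT_CONSTANTS)
    if constants:
        unknown = set(constants) - set(k)
        if unknown:
            raise ValidationError(f"unknown constants {sorted(unknown)}")
        k.update(constants)
    x0 = dict(DEFAULT_INITIAL_AMOUNTS)
    if initial_amounts:
        x0.update(initial_amounts)

    net = ReactionNetwork("normal")
    net.metadata["scenario"] = "normal"
    net.metadata["source"] = "fallback"
    net.metadata["constants"] = dict(k)
    net.metadata["modifications"] = []

    def sp(sid: str, compartment: str, init: float = 0.0, **kw) -> None:
        net.add_species(
            Species(sid, compartment=compartment, initial_amount=x0.get(sid, init), **kw)
        )

    # receptor layer
    sp("EGF", "extracellular")
    sp("EGFR", "membrane")
    sp("EGF_EGFR", "membrane", display_name="EGF-EGFR")
    sp("EGF_EGFR2", "membrane", display_name="EGF-EGFR2")
    sp("pEGF_EGFR2", "membrane", display_name="pEGF-EGFR2")
    sp("EGFR_endo", "endosome")
    sp("EGFR_deg", "endosome")
    # Ras/ERK branch
    for sid in ("Grb2", "SOS", "SOSi", "Shc"):
        sp(sid, "cytoplasm")
    for sid in ("R_Grb2", "R_Grb2_SOS", "R_Shc", "R_pShc", "R_pShc_Grb2",
                "R_pShc_Grb2_SOS", "Ras_GDP", "Ras_GTP"):
        sp(sid, "membrane")
    for sid in ("Raf", "aRaf", "MEK", "pMEK", "ppMEK", "ERK", "pERK", "ppERK", "MKP"):
        sp(sid, "cytoplasm")
    net.add_species(Species("MKP_gene", compartment="nucleus", initial_amount=1.0,
                            is_constant=True))
    # PI3K/Akt branch
    sp("PI3K", "cytoplasm")
    for sid in ("R_PI3K", "PIP2", "PIP3", "PIP3_PDK1"):
        sp(sid, "membrane")
    for sid in ("PDK1", "Akt", "pAkt", "PTEN"):
        sp(sid, "cytoplasm")
    # STAT3 branch
    sp("STAT3c", "cytoplasm")
    sp("R_STAT3", "membrane")
    sp("pSTAT3c", "cytoplasm", display_name="pSTAT3c")
    sp("STAT3dim_c", "cytoplasm", display_name="pSTAT3c-pSTAT3c")
    sp("STAT3dim_n", "nucleus", display_name="pSTAT3n-pSTAT3n")
    sp("STAT3n", "nucleus")

    def rxn(rid, reactants, products, law, modifiers=()):
        net.add_reaction(
            Reaction(rid, list(reactants), list(products), list(modifiers), law)
        )

    # receptor layer
    rxn("egf_binding", [("EGF", 1), ("EGFR", 1)], [("EGF_EGFR", 1)],
        _ma(k["kon_egf"], k["koff_egf"]))
    rxn("dimerization", [("EGF_EGFR", 2)], [("EGF_EGFR2", 1)],
        _ma(k["kon_dim"], k["koff_dim"]))
    rxn("autophosphorylation", [("EGF_EGFR2", 1)], [("pEGF_EGFR2", 1)],
        _ma(k["k_phos"] * k["mutant_phos_scale"]))
    rxn("receptor_dephosphorylation", [("pEGF_EGFR2", 1)], [("EGF_EGFR2", 1)],
        _ma(k["k_rdephos"]))
    for sid, (n_rec, cargo) in _SURFACE_COMPLEXES.items():
        rxn(f"internalization_{sid}", [(sid, 1)],
            [("EGFR_endo", n_rec)] + [(c, 1) for c in cargo],
            _ma(k["k_int"]))
    rxn("recycling", [("EGFR_endo", 1)], [("EGFR", 1)], _ma(k["k_recycle"]))
    rxn("degradation", [("EGFR_endo", 1)], [("EGFR_deg", 1)], _ma(k["k_degrade"]))

    # Ras/ERK branch
    rxn("grb2_binding", [("pEGF_EGFR2", 1), ("Grb2", 1)], [("R_Grb2", 1)],
        _ma(k["kon_grb"], k["koff_grb"]))
    rxn("sos_binding_direct", [("R_Grb2", 1), ("SOS", 1)], [("R_Grb2_SOS", 1)],
        _ma(k["kon_sos"], k["koff_sos"]))
    rxn("shc_binding", [("pEGF_EGFR2", 1), ("Shc", 1)], [("R_Shc", 1)],
        _ma(k["kon_shc"], k["koff_shc"]))
    rxn("shc_phosphorylation", [("R_Shc", 1)], [("R_pShc", 1)], _ma(k["k_shcphos"]))
    rxn("pshc_release", [("R_pShc", 1)], [("pEGF_EGFR2", 1), ("Shc", 1)],
        _ma(k["k_pshc_release"]))
    rxn("grb2_binding_shc", [("R_pShc", 1), ("Grb2", 1)], [("R_pShc_Grb2", 1)],
        _ma(k["kon_grb_shc"], k["koff_grb_shc"]))
    rxn("sos_binding_shc", [("R_pShc_Grb2", 1), ("SOS", 1)], [("R_pShc_Grb2_SOS", 1)],
        _ma(k["kon_sos_shc"], k["koff_sos_shc"]))
    rxn("ras_activation_direct", [("Ras_GDP", 1)], [("Ras_GTP", 1)],
        _mm(k["kcat_sos"], k["Km_ras"]), modifiers=["R_Grb2_SOS"])
    rxn("ras_activation_shc", [("Ras_GDP", 1)], [("Ras_GTP", 1)],
        _mm(k["kcat_sos"], k["Km_ras"]), modifiers=["R_pShc_Grb2_SOS"])
    rxn("ras_gap", [("Ras_GTP", 1)], [("Ras_GDP", 1)], _ma(k["k_gap"]))
    rxn("raf_activation", [("Raf", 1)], [("aRaf", 1)],
        _mm(k["kcat_raf"], k["Km_raf"]), modifiers=["Ras_GTP"])
    rxn("raf_deactivation", [("aRaf", 1)], [("Raf", 1)], _ma(k["k_rafdeact"]))
    rxn("mek_phosphorylation_1", [("MEK", 1)], [("pMEK", 1)],
        _mm(k["kcat_mek"], k["Km_mek"]), modifiers=["aRaf"])
    rxn("mek_phosphorylation_2", [("pMEK", 1)], [("ppMEK", 1)],
        _mm(k["kcat_mek"], k["Km_mek"]), modifiers=["aRaf"])
    rxn("mek_dephosphorylation_1", [("ppMEK", 1)], [("pMEK", 1)], _ma(k["k_mekptase"]))
    rxn("mek_dephosphorylation_2", [("pMEK", 1)], [("MEK", 1)], _ma(k["k_mekptase"]))
    rxn("erk_phosphorylation_1", [("ERK", 1)], [("pERK", 1)],
        _mm(k["kcat_erk"], k["Km_erk"]), modifiers=["ppMEK"])
    rxn("erk_phosphorylation_2", [("pERK", 1)], [("ppERK", 1)],
        _mm(k["kcat_erk"], k["Km_erk"]), modifiers=["ppMEK"])
    rxn("erk_dephosphorylation_1", [("ppERK", 1)], [("pERK", 1)],
        _mm(k["kcat_mkp"], k["Km_mkp"]), modifiers=["MKP"])
    rxn("erk_dephosphorylation_2", [("pERK", 1)], [("ERK", 1)],
        _mm(k["kcat_mkp"], k["Km_mkp"]), modifiers=["MKP"])
    rxn("erk_basal_dephosphorylation_1", [("ppERK", 1)], [("pERK", 1)], _ma(k["k_erkptase"]))
    rxn("erk_basal_dephosphorylation_2", [("pERK", 1)], [("ERK", 1)], _ma(k["k_erkptase"]))
    # slow transcriptional induction of the ERK phosphatase (delayed negative
    # feedback at the ERK level); the gene template is a clamped species so the
    # induction rate saturates in ppERK
    rxn("mkp_induction", [("ppERK", 1)], [("ppERK", 1), ("MKP", 1)],
        _mm(k["k_mkp_induce"], k["Km_mkp_induce"]), modifiers=["MKP_gene"])
    rxn("mkp_decay", [("MKP", 1)], [], _ma(k["k_mkp_decay"]))
    rxn("sos_feedback_inactivation", [("SOS", 1)], [("SOSi", 1)],
        _mm(k["kcat_fb"], k["Km_fb"]), modifiers=["ppERK"])
    rxn("sos_recovery", [("SOSi", 1)], [("SOS", 1)], _ma(k["k_fbrecover"]))

    # PI3K/Akt branch
    rxn("pi3k_binding", [("pEGF_EGFR2", 1), ("PI3K", 1)], [("R_PI3K", 1)],
        _ma(k["kon_pi3k"], k["koff_pi3k"]))
    rxn("pip3_production", [("PIP2", 1)], [("PIP3", 1)],
        _mm(k["kcat_pi3k"], k["Km_pip2"]), modifiers=["R_PI3K"])
    rxn("pten_hydrolysis", [("PIP3", 1)], [("PIP2", 1)],
        _mm(k["kcat_pten"], k["Km_pip3"]), modifiers=["PTEN"])
    rxn("pdk1_recruitment", [("PIP3", 1), ("PDK1", 1)], [("PIP3_PDK1", 1)],
        _ma(k["kon_pdk"], k["koff_pdk"]))
    rxn("akt_phosphorylation", [("Akt", 1)], [("pAkt", 1)],
        _mm(k["kcat_akt"], k["Km_akt"]), modifiers=["PIP3_PDK1"])
    rxn("akt_dephosphorylation", [("pAkt", 1)], [("Akt", 1)], _ma(k["k_aktptase"]))

    # STAT3 branch
    rxn("stat3_binding", [("pEGF_EGFR2", 1), ("STAT3c", 1)], [("R_STAT3", 1)],
        _ma(k["kon_stat"], k["koff_stat"]))
    rxn("stat3_phosphorylation", [("R_STAT3", 1)], [("pEGF_EGFR2", 1), ("pSTAT3c", 1)],
        _ma(k["kcat_stat"]))
    rxn("stat3_dephosphorylation_c", [("pSTAT3c", 1)], [("STAT3c", 1)],
        _ma(k["k_statptase_c"]))
    rxn("stat3_dimerization", [("pSTAT3c", 2)], [("STAT3dim_c", 1)],
        _ma(k["kon_statdim"], k["koff_statdim"]))
    rxn("stat3_nuclear_import", [("STAT3dim_c", 1)], [("STAT3dim_n", 1)],
        _ma(k["k_import"]))
    rxn("stat3_nuclear_dephosphorylation", [("STAT3dim_n", 1)], [("STAT3n", 2)],
        _ma(k["k_statptase_n"]))
    rxn("stat3_nuclear_export", [("STAT3n", 1)], [("STAT3c", 1)], _ma(k["k_export"]))

    return net


def _record(net: ReactionNetwork, rule: ModificationRule) -> None:
    net.metadata.setdefault("modifications", []).append(rule.as_dict())


def _scale_initial(net: ReactionNetwork, sid: str, factor: float) -> None:
    if sid not in net.species:
        raise EgfrSimError(f"cannot scale initial of missing species {sid!r}")
    net.species[sid].initial_amount *= factor
    net.touch()
    _record(net, ModificationRule("scale_initial", sid, factor))


def build_nsclc_model(
    base: ReactionNetwork | None = None,
    mutant_phos_scale: float | None = None,
    constants: Mapping[str, float] | None = None,
) -> ReactionNetwork:
    """Apply the NSCLC construction rules to a normal model.

    EGFR initial amount ×3; Ras, PI3K, Akt, STAT3 initial amounts ×2; mutant
    (L858R) receptor kinetics: autophosphorylation slowed by
    ``mutant_phos_scale`` and every EGF-dependent internalization rate
    constant halved.  The mutant scale factor is recorded as a global
    parameter, making the NSCLC model one parameter richer than the normal
    model.  Applying this build twice raises (guard against double scaling).
    """
    if base is None:
        base = build_normal_model(constants=constants)
    if base.metadata.get("nsclc"):
        raise EgfrSimError("NSCLC modification set already applied (double scaling guard)")
    net = base.copy("nsclc")
    net.metadata["scenario"] = "nsclc"
    net.metadata["nsclc"] = True
    scale = (
        mutant_phos_scale
        if mutant_phos_scale is not None
        else CALIBRATED_MUTANT_PHOS_SCALE
    )
    if not scale > 0:
        raise ValidationError("mutant_phos_scale must be > 0")

    missing = [s for s in ("EGFR", "Ras_GDP", "PI3K", "Akt", "STAT3c") if s not in net.species]
    if missing:
        raise EgfrSimError(f"base model is missing NSCLC target species: {missing}")

    _scale_initial(net, "EGFR", EGFR_OVEREXPRESSION_FOLD)
    for sid in ("Ras_GDP", "PI3K", "Akt", "STAT3c"):
        _scale_initial(net, sid, DOWNSTREAM_OVEREXPRESSION_FOLD)

    auto = net.reactions["autophosphorylation"]
    auto.rate_law.k1 *= scale
    _record(net, ModificationRule("scale_parameter", "autophosphorylation.k1", scale))
    for rid, rxn in net.reactions.items():
        if rid.startswith("internalization_"):
            rxn.rate_law.k1 *= MUTANT_INTERNALIZATION_FACTOR
            _record(net, ModificationRule("scale_parameter", f"{rid}.k1",
                                          MUTANT_INTERNALIZATION_FACTOR))
    # the 188th parameter: the mutant autophosphorylation scale factor
    net.set_parameter("mutant_phos_scale", scale)
    net.metadata["egfr_scaling"] = "total receptor (paper states 'the EGFR concentration')"
    net.touch()
    return net


def apply_pten_loss(network: ReactionNetwork) -> ReactionNetwork:
    """Eliminate PTEN activity: PTEN initial amount → 0, so the PTEN-catalysed
    PIP3→PIP2 flux is null at every state."""
    if "PTEN" not in network.species:
        raise EgfrSimError("network has no PTEN species")
    if "pten_hydrolysis" not in network.reactions:
        raise EgfrSimError("network has no PTEN-catalysed PIP3->PIP2 reaction")
    net = network.copy(network.name + "_pten_loss")
    net.metadata["scenario"] = net.name
    net.species["PTEN"].initial_amount = 0.0
    net.touch()
    _record(net, ModificationRule("zero_species", "PTEN", 0.0))
    return net


def apply_erlotinib(network: ReactionNetwork, dose_umol_per_l: float) -> ReactionNetwork:
    """Add an erlotinib bath with reversible binding to the ligand-bound,
    unphosphorylated receptor dimer, blocking autophosphorylation.

    The drug species is clamped at the given dose (converted to nM); the
    blocked dimer still undergoes EGF-dependent internalization.  Dose 0 adds
    the species at zero concentration and is a no-op on the dynamics.
    """
    conc = erlotinib_dose_to_concentration(dose_umol_per_l)
    net = network.copy(network.name + "_erlotinib")
    net.metadata["scenario"] = net.name
    k = net.metadata.get("constants", DEFAULT_CONSTANTS)
    net.add_species(Species("erlotinib", compartment="extracellular",
                            initial_amount=conc, is_constant=True))
    net.add_species(Species("EGF_EGFR2_erl", compartment="membrane"))
    net.add_reaction(Reaction(
        "erlotinib_binding",
        [("erlotinib", 1), ("EGF_EGFR2", 1)], [("EGF_EGFR2_erl", 1)],
        rate_law=_ma(k["kon_erl"], k["koff_erl"]),
    ))
    k_int_current = net.reactions["internalization_pEGF_EGFR2"].rate_law.k1
    net.add_reaction(Reaction(
        "internalization_EGF_EGFR2_erl",
        [("EGF_EGFR2_erl", 1)], [("EGFR_endo", 2)],
        rate_law=_ma(k_int_current),
    ))
    _record(net, ModificationRule("add_reaction", "erlotinib_binding", conc))
    return net


def set_egf(network: ReactionNetwork, dose_ng_per_ml: float, clamp: bool = False) -> None:
    """Set the EGF stimulus (in place) from a dose in ng/ml."""
    network.species["EGF"].initial_amount = egf_dose_to_concentration(dose_ng_per_ml)
    network.species["EGF"].is_constant = clamp
    network.touch()


def build_scenario(
    scenario: Scenario | str,
    constants: Mapping[str, float] | None = None,
    source: str | None = None,
) -> ReactionNetwork:
    """Build the network for a named scenario, EGF/erlotinib doses applied."""
    if isinstance(scenario, str):
        scenario = Scenario(scenario)
    base = build_normal_model(source=source, constants=constants)
    if scenario.name.startswith("nsclc"):
        net = build_nsclc_model(base, constants=constants)
    else:
        net = base
    if "pten_loss" in scenario.name:
        net = apply_pten_loss(net)
    if scenario.name.endswith("erlotinib"):
        net = apply_erlotinib(net, scenario.erlotinib_dose)
    for key, value in scenario.overrides.items():
        if key in net.species:
            net.species[key].initial_amount = float(value)
            net.touch()
            _record(net, ModificationRule("scale_initial", key, float(value)))
        elif key in net.parameters:
            net.set_parameter(key, float(value))
            _record(net, ModificationRule("scale_parameter", key, float(value)))
        else:
            raise ValidationError(f"override target {key!r} names no existing id")
    set_egf(net, scenario.egf_dose, clamp=scenario.clamp_egf)
    net.name = scenario.name
    net.metadata["scenario"] = scenario.name
    net.metadata["egf_dose_ng_ml"] = scenario.egf_dose
    net.metadata["erlotinib_dose_umol_l"] = scenario.erlotinib_dose
    return net


def standard_observables(network: ReactionNetwork) -> dict[str, Observable]:
    """The reported observables, filtered to species present in *network*."""
    raw: dict[str, dict[str, float]] = {
        "pEGFR_total": {
            sid: 1.0
            for sid in ("pEGF_EGFR2", "R_Grb2", "R_Grb2_SOS", "R_Shc", "R_pShc",
                        "R_pShc_Grb2", "R_pShc_Grb2_SOS", "R_PI3K", "R_STAT3")
        },
        "surface_EGFR": {
            "EGFR": 1.0, "EGF_EGFR": 1.0,
            **{sid: float(n) for sid, (n, _) in _SURFACE_COMPLEXES.items() if sid != "EGF_EGFR"},
            "EGF_EGFR2_erl": 2.0,
        },
        "RasGTP": {"Ras_GTP": 1.0},
        "Raf1active": {"aRaf": 1.0},
        "ppMEK": {"ppMEK": 1.0},
        "ppERK": {"ppERK": 1.0},
        "pPI3K": {"R_PI3K": 1.0},
        "pAkt": {"pAkt": 1.0},
        "PIP3": {"PIP3": 1.0, "PIP3_PDK1": 1.0},
        "STAT3c_dimer": {"STAT3dim_c": 1.0},
        "STAT3n_dimer": {"STAT3dim_n": 1.0},
    }
    out: dict[str, Observable] = {}
    for name, weights in raw.items():
        weights = {sid: w for sid, w in weights.items() if sid in network.species}
        if weights:
            out[name] = Observable(name, weights)
    return out


#: Mutant autophosphorylation scale factor fitted by the calibration module
#: against the NSCLC peak-delay targets (see egfrsim.calibration).
CALIBRATED_MUTANT_PHOS_SCALE = 0.01
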