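"""The default BMEC signaling network.

Five coupled pathway modules — inflammation (TNFR/TLR4 -> TAK1/IKK -> NFkB
with A20 and IkB feedback), cell survival (VEGFR/Tie2/FGFR -> PLCg/MEK/ERK,
PI3K/AKT, calcium, eNOS, AMPK/ULK, Wnt/beta-catenin), hypoxia regulation
(O2 -> PHD -| HIF1a/HIF2a -> Lon/BDNF/SEMA3G/Ang2 and p53/MDM2/BAX/Caspase3),
glucose metabolism (aerobic + anaerobic ATP production, AMPK energy sensing,
PFKFB3, TIGAR/NADPH) and oxidative stress (SDH reversal -> succinate
accumulation under low O2, reoxygenation-driven succinate oxidation -> ROS
burst via reverse electron transport, iNOS/NO/ONOO-, BH4/BH2 uncoupling,
Keap1/NRF2 defense, ROS damage to ZO-1/Claudin5 and ROS -> IKK crosstalk).

Baseline rate constants are derived by *balancing*: a designated parameter
per species is solved in closed form so that the declared reference state is
an exact steady state under the control environment (21% O2, 5.05 mmol/L
glucose, basal ligand tone).  The quiescence requirement — every species
within 0.9x-1.1x of its initial value over 7 days of control culture — then
holds by construction and is verified numerically, not searched for.

Rationales for every Hill coefficient n > 1 are collected in
docs/parameter_notes.md.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .network import (
    ConfigurationError,
    ModelNetwork,
    ParameterSet,
    RateLaw,
    Reaction,
    Regulator,
    SpeciesDef,
)
from .rhs import CompiledRHS


def A(species: str, K: float, n: float = 1.0) -> Regulator:
    return Regulator(species, "activate", K, n)


def I(species: str, K: float, n: float = 1.0) -> Regulator:
    return Regulator(species, "inhibit", K, n)


def L(species: str) -> Regulator:
    return Regulator(species, "linear")


class NetworkBuilder:
    """Declarative network assembly with steady-state balancing.

    A reaction declared with ``balance=<species>`` has its rate constant
    solved so that the named species has zero net flux at the reference
    (initial) state, given all other reactions.  Balances are resolved
    iteratively; a balance whose species is touched by another unsolved
    reaction waits for that reaction first.
    """

    def __init__(self) -> None:
        self.species: list[SpeciesDef] = []
        self.reactions: list[Reaction] = []
        self.values: dict[str, float] = {}
        self._balances: dict[str, str] = {}  # reaction id -> balanced species

    def sp(
        self,
        sid: str,
        init: float,
        compartment: str = "cytosol",
        tags: tuple[str, ...] = (),
    ) -> None:
        self.species.append(SpeciesDef(sid, compartment, init, frozenset(tags)))

    def rx(
        self,
        rid: str,
        module: str,
        *,
        reactants: list[tuple[str, int]] | None = None,
        products: list[tuple[str, int]] | None = None,
        regulators: list[Regulator] | None = None,
        kind: str = "mass_action",
        K: float | None = None,
        n: float = 1.0,
        param: str | None = None,
        value: float | None = None,
        balance: str | None = None,
    ) -> None:
        param = param or f"k_{rid}"
        self.reactions.append(
            Reaction(
                id=rid,
                reactants=list(reactants or []),
                products=list(products or []),
                regulators=list(regulators or []),
                rate_law=RateLaw(kind=kind, hill_K=K, hill_n=n),
                parameter_id=param,
                module=module,
            )
        )
        if balance is not None:
            if value is not None:
                raise ConfigurationError(f"{rid}: give value or balance, not both")
            self._balances[rid] = balance
        else:
            if value is None or value <= 0:
                raise ConfigurationError(f"{rid}: needs a positive rate constant")
            if param in self.values and self.values[param] != value:
                raise ConfigurationError(f"conflicting values for parameter {param}")
            self.values[param] = value

    # -- balancing -------------------------------------------------------

    def _solve_balances(self, network: ModelNetwork) -> None:
        ref = network.initial_state()
        stoich = network.stoichiometry_matrix()
        rxn_index = {r.id: j for j, r in enumerate(network.reactions)}
        sp_index = {s.id: i for i, s in enumerate(network.species)}
        unsolved = dict(self._balances)
        scale = np.maximum(ref, 1e-3)
        while unsolved:
            # unit-rate fluxes with unsolved constants set to 1; pending is a
            # pass-start snapshot so chained balances wait for the next pass
            pending = set(unsolved)
            trial = dict(self.values)
            for rid in unsolved:
                trial[network.get_reaction(rid).parameter_id] = 1.0
            f = CompiledRHS(network, ParameterSet(trial)).fluxes(ref)
            solved_mask = np.array(
                [r.id not in pending for r in network.reactions], dtype=float
            )
            progress = False
            for rid, sid in list(unsolved.items()):
                j, i = rxn_index[rid], sp_index[sid]
                blockers = [
                    r.id
                    for r in network.reactions
                    if r.id in pending and r.id != rid and stoich[i, rxn_index[r.id]] != 0
                ]
                if blockers:
                    continue
                net = float(stoich[i] @ (f * solved_mask))
                phi = float(f[j])
                s = float(stoich[i, j])
                if phi <= 0 or s == 0:
                    raise ConfigurationError(
                        f"cannot balance {sid} via {rid}: zero flux or stoichiometry"
                    )
                k = -net / (s * phi)
                if k <= 0:
                    raise ConfigurationError(
                        f"balancing {sid} via {rid} gives nonpositive rate {k:.3g}; "
                        "reference fluxes are inconsistent"
                    )
                self.values[network.get_reaction(rid).parameter_id] = k
                del unsolved[rid]
                progress = True
            if not progress:
                raise ConfigurationError(
                    f"circular balance dependencies among {sorted(unsolved)}"
                )
        # verify the reference state is an exact fixed point
        rhs = CompiledRHS(network, ParameterSet(self.values))
        dy = rhs(0.0, ref)
        resid = np.abs(dy) / scale
        worst = int(np.argmax(resid))
        if resid.max() > 1e-9:
            raise ConfigurationError(
                f"reference state not balanced: residual {resid.max():.3g} "
                f"on {network.species_ids[worst]}"
            )

    def build(self, metadata: dict | None = None) -> tuple[ModelNetwork, ParameterSet]:
        network = ModelNetwork(self.species, self.reactions, dict(metadata or {}))
        self._solve_balances(network)
        params = ParameterSet.with_default_bounds(self.values)
        network.validate()
        network.check_parameters(params)
        return network, params


# ---------------------------------------------------------------------------
# the default model
# ---------------------------------------------------------------------------

#: parameter groups addressed by in-silico target interventions
TARGET_GROUPS = {
    "succinate": ["kt_Succinate"],
    "p53": ["kt_p53", "kt_p53_hif", "kt_p53_ros"],
    "HIF1a": ["kt_HIF1a", "kon_HIF1a"],
    "IkB": ["kt_IKB", "kt_IKB_mrna", "kt_IKB_mrna_basal"],
}


def _declare_species(b: NetworkBuilder) -> None:
    # environment (clamped inputs)
    b.sp("O2", 0.21, "environment", ("environment",))
    b.sp("glucose", 5.05, "environment", ("environment",))
    # extracellular ligands, molecules per cell (basal autocrine tone)
    b.sp("TNFa", 1e3, "medium", ("ligand",))
    b.sp("LPS", 1e3, "medium", ("ligand",))
    b.sp("VEGF", 1e3, "medium", ("ligand",))
    b.sp("FGF", 1e3, "medium", ("ligand",))
    b.sp("Ang1", 2e4, "medium", ("ligand",))
    b.sp("Wnt", 1e3, "medium", ("ligand",))
    # inflammation
    b.sp("TNFR", 1.0, "membrane", ("receptor",))
    b.sp("TNFR_act", 0.01, "membrane", ("receptor",))
    b.sp("TLR4", 1.0, "membrane", ("receptor",))
    b.sp("TLR4_act", 0.01, "membrane", ("receptor",))
    b.sp("TRAF6", 1.0)
    b.sp("TRAF6_Ub", 0.02)
    b.sp("RIPK1", 1.0)
    b.sp("RIPK1_Ub", 0.02)
    b.sp("TAK1", 1.0, tags=("kinase",))
    b.sp("TAK1_p", 0.02, tags=("kinase",))
    b.sp("IKK", 1.0, tags=("kinase",))
    b.sp("IKK_p", 0.02, tags=("kinase",))
    b.sp("NFkB_IkB", 1.0)
    b.sp("NFkB_cyt", 0.02, tags=("transcription_factor",))
    b.sp("NFkB_nuc", 0.05, "nucleus", ("transcription_factor",))
    b.sp("IkBa", 0.1)
    b.sp("IkB_mRNA", 1.0, "nucleus")
    b.sp("A20", 1.0)
    b.sp("p38", 1.0, tags=("kinase",))
    b.sp("p38_p", 0.02, tags=("kinase",))
    b.sp("JNK", 1.0, tags=("kinase",))
    b.sp("JNK_p", 0.02, tags=("kinase",))
    b.sp("ERK", 1.0, tags=("kinase",))
    b.sp("ERK_p", 0.03, tags=("kinase",))
    b.sp("IL6", 1.0, "medium", ("marker",))
    b.sp("IL1b", 1.0, "medium", ("marker",))
    b.sp("CCL2", 1.0, "medium", ("marker",))
    # survival
    b.sp("VEGFR", 1.0, "membrane", ("receptor",))
    b.sp("VEGFR_pY1175", 0.01, "membrane", ("receptor",))
    b.sp("VEGFR_pY951", 0.01, "membrane", ("receptor",))
    b.sp("Tie2", 1.0, "membrane", ("receptor",))
    b.sp("Tie2_p", 0.05, "membrane", ("receptor",))
    b.sp("FGFR", 1.0, "membrane", ("receptor",))
    b.sp("FGFR_p", 0.01, "membrane", ("receptor",))
    b.sp("PLCg", 1.0, tags=("kinase",))
    b.sp("PLCg_p", 0.02, tags=("kinase",))
    b.sp("MEK", 1.0, tags=("kinase",))
    b.sp("MEK_p", 0.03, tags=("kinase",))
    b.sp("PI3K", 1.0, tags=("kinase",))
    b.sp("PI3K_p", 0.02, tags=("kinase",))
    b.sp("AKT", 1.0, tags=("kinase",))
    b.sp("AKT_p", 0.03, tags=("kinase",))
    b.sp("PKC", 1.0, tags=("kinase",))
    b.sp("PKC_p", 0.02, tags=("kinase",))
    b.sp("Ca_ER", 1.0, "ER", ("metabolite",))
    b.sp("Ca_cyt", 0.1, tags=("metabolite",))
    b.sp("eNOS", 1.0, tags=("kinase",))
    b.sp("eNOS_p", 0.05, tags=("kinase",))
    b.sp("AMPK", 1.0, tags=("kinase",))
    b.sp("AMPK_p", 0.05, tags=("kinase",))
    b.sp("ULK", 1.0, tags=("kinase",))
    b.sp("ULK_p", 0.05, tags=("kinase",))
    b.sp("beta_catenin", 1.0, tags=("transcription_factor",))
    # hypoxia regulation
    b.sp("PHD", 1.0)
    b.sp("HIF1a", 1.0, tags=("transcription_factor",))
    b.sp("HIF1a_nuc", 0.2, "nucleus", ("transcription_factor",))
    b.sp("HIF2a", 1.0, tags=("transcription_factor",))
    b.sp("HIF2a_nuc", 0.2, "nucleus", ("transcription_factor",))
    b.sp("Lon", 1.0, "mitochondrion")
    b.sp("BDNF", 1.0, "medium", ("marker",))
    b.sp("SEMA3G", 1.0, "medium", ("marker",))
    b.sp("Ang2", 1.0, "medium", ("marker",))
    b.sp("p53", 1.0, tags=("transcription_factor", "marker"))
    b.sp("MDM2", 1.0)
    b.sp("TIGAR", 1.0)
    b.sp("BAX", 1.0, "mitochondrion")
    b.sp("Casp3", 1.0, tags=("marker",))
    # metabolism
    b.sp("ATP", 1.0, tags=("metabolite",))
    b.sp("AMP", 0.1, tags=("metabolite",))
    b.sp("PFKFB3", 1.0, tags=("metabolite",))
    b.sp("NADPH", 1.0, tags=("metabolite",))
    # oxidative stress
    b.sp("SDH", 1.0, "mitochondrion")
    b.sp("Succinate", 1.0, "mitochondrion", ("metabolite",))
    b.sp("ROS", 1.0, tags=("radical", "marker"))
    b.sp("iNOS", 1.0)
    b.sp("NO", 1.0, tags=("radical",))
    b.sp("ONOO", 1.0, tags=("radical", "marker"))
    b.sp("BH4", 1.0, tags=("metabolite",))
    b.sp("BH2", 0.2, tags=("metabolite",))
    b.sp("Keap1", 1.0)
    b.sp("NRF2", 1.0, tags=("transcription_factor",))
    b.sp("ZO1", 1.0, "membrane", ("marker",))
    b.sp("Claudin5", 1.0, "membrane", ("marker",))


def _ligand(b: NetworkBuilder, lig: str, module: str, kd: float = 0.5) -> None:
    b.rx(f"syn_{lig}", module, products=[(lig, 1)],
         kind="zeroth_order_synthesis", param=f"kt_{lig}", balance=lig)
    b.rx(f"deg_{lig}", module, reactants=[(lig, 1)],
         kind="first_order_decay", param=f"kd_{lig}", value=kd)


def _receptor(
    b: NetworkBuilder,
    rec: str,
    act: str,
    lig: str,
    module: str,
    kon: float,
    kd: float = 0.05,
) -> None:
    """Ligand binding/activation cycle with receptor turnover."""
    b.rx(f"bind_{act}", module, reactants=[(lig, 1), (rec, 1)],
         products=[(act, 1)], param=f"kon_{act}", value=kon)
    b.rx(f"unbind_{act}", module, reactants=[(act, 1)],
         products=[(rec, 1), (lig, 1)], kind="first_order_decay",
         param=f"koff_{act}", balance=act)
    b.rx(f"deg_{act}", module, reactants=[(act, 1)],
         kind="first_order_decay", param=f"kd_{act}", value=kd)
    b.rx(f"deg_{rec}", module, reactants=[(rec, 1)],
         kind="first_order_decay", param=f"kd_{rec}", value=kd)
    b.rx(f"syn_{rec}", module, products=[(rec, 1)],
         kind="zeroth_order_synthesis", param=f"kt_{rec}", balance=rec)


def _cycle(
    b: NetworkBuilder,
    inactive: str,
    active: str,
    module: str,
    drives: list[tuple[str, float, list[Regulator]]],
) -> None:
    """Conserved activation/deactivation cycle.

    ``drives`` is a list of (parameter id, rate constant, regulators); the
    deactivation rate is balanced so the reference state is steady.
    """
    for pid, k, regs in drives:
        b.rx(f"{pid}__{active}", module, reactants=[(inactive, 1)],
             products=[(active, 1)], regulators=regs, param=pid, value=k)
    b.rx(f"deact_{active}", module, reactants=[(active, 1)],
         products=[(inactive, 1)], kind="first_order_decay",
         param=f"kdp_{active}", balance=active)


def _turnover_target(
    b: NetworkBuilder,
    sid: str,
    module: str,
    kd: float,
    inductions: list[tuple[str, float, list[Regulator]]],
    basal_param: str | None = None,
) -> None:
    """Species with basal synthesis (balanced), induced synthesis, decay."""
    for pid, k, regs in inductions:
        b.rx(f"{pid}__{sid}", module, products=[(sid, 1)], regulators=regs,
             kind="zeroth_order_synthesis", param=pid, value=k)
    b.rx(f"deg_{sid}", module, reactants=[(sid, 1)],
         kind="first_order_decay", param=f"kd_{sid}", value=kd)
    b.rx(f"syn_{sid}", module, products=[(sid, 1)],
         kind="zeroth_order_synthesis",
         param=basal_param or f"kt_{sid}", balance=sid)


def _build() -> tuple[ModelNetwork, ParameterSet]:
    b = NetworkBuilder()
    _declare_species(b)

    # ---------------- inflammation ----------------
    _receptor(b, "TNFR", "TNFR_act", "TNFa", "inflammation", kon=1e-5)
    _receptor(b, "TLR4", "TLR4_act", "LPS", "inflammation", kon=1e-5)
    _ligand(b, "TNFa", "inflammation")
    _ligand(b, "LPS", "inflammation")

    _cycle(b, "TRAF6", "TRAF6_Ub", "inflammation",
           [("kub_TRAF6", 6.0, [L("TLR4_act"), I("A20", 2.0)])])
    _cycle(b, "RIPK1", "RIPK1_Ub", "inflammation",
           [("kub_RIPK1", 6.0, [L("TNFR_act"), I("A20", 2.0)])])
    _cycle(b, "TAK1", "TAK1_p", "inflammation",
           [("kp_TAK1_TRAF6", 30.0, [L("TRAF6_Ub")]),
            ("kp_TAK1_RIPK1", 30.0, [L("RIPK1_Ub")])])
    _cycle(b, "IKK", "IKK_p", "inflammation",
           [("kp_IKK", 10.0, [L("TAK1_p")]),
            ("kp_IKK_ROS", 2.0, [A("ROS", 3.0, 2.0)])])

    # NFkB release / shuttling / resequestration (total NFkB conserved)
    b.rx("act_NFkB", "inflammation", reactants=[("NFkB_IkB", 1)],
         products=[("NFkB_cyt", 1)], regulators=[L("IKK_p")],
         param="kp_NFkB", value=5.0)
    b.rx("imp_NFkB", "inflammation", reactants=[("NFkB_cyt", 1)],
         products=[("NFkB_nuc", 1)], kind="first_order_decay",
         param="kin_NFkB", balance="NFkB_cyt")
    b.rx("seq_NFkB", "inflammation", reactants=[("NFkB_nuc", 1), ("IkBa", 1)],
         products=[("NFkB_IkB", 1)], param="kon_NFkB", balance="NFkB_nuc")

    b.rx("tx_IkB", "inflammation", products=[("IkB_mRNA", 1)],
         kind="hill_activation", K=0.15, n=2.0,
         regulators=[A("NFkB_nuc", 0.15, 2.0)], param="kt_IKB_mrna", value=2.0)
    b.rx("deg_IkB_mRNA", "inflammation", reactants=[("IkB_mRNA", 1)],
         kind="first_order_decay", param="kd_IKB_mrna", value=1.0)
    b.rx("tx_IkB_basal", "inflammation", products=[("IkB_mRNA", 1)],
         kind="zeroth_order_synthesis", param="kt_IKB_mrna_basal",
         balance="IkB_mRNA")
    b.rx("deg_IkB", "inflammation", reactants=[("IkBa", 1)],
         kind="first_order_decay", param="kd_IKB", value=0.2)
    b.rx("tl_IkB", "inflammation", products=[("IkBa", 1)],
         regulators=[L("IkB_mRNA")], kind="zeroth_order_synthesis",
         param="kt_IKB", balance="IkBa")

    _turnover_target(b, "A20", "inflammation", kd=0.3,
                     inductions=[("kt_A20", 2.0, [A("NFkB_nuc", 0.15, 2.0)])],
                     basal_param="kt_A20_basal")
    for cyt in ("IL6", "IL1b", "CCL2"):
        _turnover_target(b, cyt, "inflammation", kd=0.15,
                         inductions=[(f"kt_{cyt}", 2.0,
                                      [A("NFkB_nuc", 0.25, 2.0)])],
                         basal_param=f"kt_{cyt}_basal")

    _cycle(b, "p38", "p38_p", "inflammation",
           [("kp_p38", 12.0, [L("TAK1_p")])])
    _cycle(b, "JNK", "JNK_p", "inflammation",
           [("kp_JNK", 12.0, [L("TAK1_p")])])
    _cycle(b, "ERK", "ERK_p", "survival",
           [("kp_ERK_TAK1", 5.0, [L("TAK1_p")]),
            ("kp_ERK_MEK", 5.0, [L("MEK_p")]),
            ("kp_ERK_Tie2", 1.0, [L("Tie2_p")])])

    # ---------------- survival ----------------
    # VEGFR with two phospho-sites (Y1175 -> PLCg arm, Y951 -> PI3K arm)
    b.rx("bind_VEGFR_pY1175", "survival",
         reactants=[("VEGF", 1), ("VEGFR", 1)], products=[("VEGFR_pY1175", 1)],
         param="kon_VEGFR_1175", value=1e-5)
    b.rx("unbind_VEGFR_pY1175", "survival", reactants=[("VEGFR_pY1175", 1)],
         products=[("VEGFR", 1), ("VEGF", 1)], kind="first_order_decay",
         param="koff_VEGFR_1175", balance="VEGFR_pY1175")
    b.rx("deg_VEGFR_pY1175", "survival", reactants=[("VEGFR_pY1175", 1)],
         kind="first_order_decay", param="kd_VEGFR_p", value=0.05)
    b.rx("bind_VEGFR_pY951", "survival",
         reactants=[("VEGF", 1), ("VEGFR", 1)], products=[("VEGFR_pY951", 1)],
         param="kon_VEGFR_951", value=1e-5)
    b.rx("unbind_VEGFR_pY951", "survival", reactants=[("VEGFR_pY951", 1)],
         products=[("VEGFR", 1), ("VEGF", 1)], kind="first_order_decay",
         param="koff_VEGFR_951", balance="VEGFR_pY951")
    b.rx("deg_VEGFR_pY951", "survival", reactants=[("VEGFR_pY951", 1)],
         kind="first_order_decay", param="kd_VEGFR_p2", value=0.05)
    b.rx("deg_VEGFR", "survival", reactants=[("VEGFR", 1)],
         kind="first_order_decay", param="kd_VEGFR", value=0.05)
    b.rx("syn_VEGFR", "survival", products=[("VEGFR", 1)],
         kind="zeroth_order_synthesis", param="kt_VEGFR", balance="VEGFR")
    _ligand(b, "VEGF", "survival")

    _receptor(b, "Tie2", "Tie2_p", "Ang1", "survival", kon=1e-6)
    _ligand(b, "Ang1", "survival", kd=0.2)
    _receptor(b, "FGFR", "FGFR_p", "FGF", "survival", kon=1e-5)
    _ligand(b, "FGF", "survival")
    _ligand(b, "Wnt", "survival")

    _cycle(b, "PLCg", "PLCg_p", "survival",
           [("kp_PLCg_VEGFR", 10.0, [L("VEGFR_pY1175")]),
            ("kp_PLCg_FGFR", 10.0, [L("FGFR_p")])])
    _cycle(b, "MEK", "MEK_p", "survival",
           [("kp_MEK_PLCg", 10.0, [L("PLCg_p")]),
            ("kp_MEK_PKC", 10.0, [L("PKC_p")])])
    _cycle(b, "PI3K", "PI3K_p", "survival",
           [("kp_PI3K_VEGFR", 10.0, [L("VEGFR_pY951")]),
            ("kp_PI3K_FGFR", 10.0, [L("FGFR_p")])])
    _cycle(b, "AKT", "AKT_p", "survival",
           [("kp_AKT_PI3K", 10.0, [L("PI3K_p")]),
            ("kp_AKT_Tie2", 4.0, [L("Tie2_p")])])
    _cycle(b, "PKC", "PKC_p", "survival",
           [("kp_PKC", 10.0, [L("PLCg_p")])])

    # ER <-> cytosol calcium exchange (total conserved)
    b.rx("rel_Ca_basal", "survival", reactants=[("Ca_ER", 1)],
         products=[("Ca_cyt", 1)], kind="first_order_decay",
         param="krel_Ca", value=0.5)
    b.rx("rel_Ca_PLCg", "survival", reactants=[("Ca_ER", 1)],
         products=[("Ca_cyt", 1)], regulators=[L("PLCg_p")],
         param="krel_Ca_PLCg", value=25.0)
    b.rx("rel_Ca_ROS", "survival", reactants=[("Ca_ER", 1)],
         products=[("Ca_cyt", 1)], regulators=[A("ROS", 3.0, 2.0)],
         param="krel_Ca_ROS", value=1.0)
    b.rx("upt_Ca", "survival", reactants=[("Ca_cyt", 1)],
         products=[("Ca_ER", 1)], kind="first_order_decay",
         param="kon_Ca_SERCA", balance="Ca_cyt")

    _cycle(b, "eNOS", "eNOS_p", "survival",
           [("kp_eNOS", 1.0, [A("Ca_cyt", 0.3, 2.0)])])
    _cycle(b, "AMPK", "AMPK_p", "metabolism",
           [("kp_AMPK", 6.0, [A("AMP", 0.6, 2.0), I("ATP", 0.5, 2.0)]),
            ("kp_AMPK_PLCg", 2.0, [L("PLCg_p")])])
    _cycle(b, "ULK", "ULK_p", "metabolism",
           [("kp_ULK", 2.0, [L("AMPK_p")])])

    # Wnt stabilizes beta-catenin by suppressing its degradation
    b.rx("deg_beta_catenin", "survival", reactants=[("beta_catenin", 1)],
         kind="first_order_decay", regulators=[I("Wnt", 1e4)],
         param="kd_beta_catenin", value=0.3)
    b.rx("syn_beta_catenin", "survival", products=[("beta_catenin", 1)],
         kind="zeroth_order_synthesis", param="kt_beta_catenin",
         balance="beta_catenin")

    # ---------------- hypoxia regulation ----------------
    b.rx("deg_PHD", "hypoxia", reactants=[("PHD", 1)],
         kind="first_order_decay", param="kd_PHD", value=0.2)
    b.rx("syn_PHD", "hypoxia", products=[("PHD", 1)],
         kind="zeroth_order_synthesis", param="kt_PHD", balance="PHD")

    for hif, kon_name, kon_val in (
        ("HIF1a", "kon_HIF1a", 0.5),
        ("HIF2a", "kin_HIF2a", 0.5),
    ):
        b.rx(f"syn_{hif}", "hypoxia", products=[(hif, 1)],
             kind="zeroth_order_synthesis", param=f"kt_{hif}", value=2.0)
        b.rx(f"deg_{hif}_basal", "hypoxia", reactants=[(hif, 1)],
             kind="first_order_decay", param=f"kd_{hif}", value=0.1)
        b.rx(f"imp_{hif}", "hypoxia", reactants=[(hif, 1)],
             products=[(f"{hif}_nuc", 1)], kind="first_order_decay",
             param=kon_name, value=kon_val)
        # O2-dependent prolyl hydroxylation -> degradation
        b.rx(f"deg_{hif}_PHD", "hypoxia", reactants=[(hif, 1)],
             kind="first_order_decay",
             regulators=[L("PHD"), A("O2", 0.05)],
             param=f"koh_{hif}", balance=hif)
        b.rx(f"deg_{hif}_nuc", "hypoxia", reactants=[(f"{hif}_nuc", 1)],
             kind="first_order_decay", param=f"kd_{hif}_nuc",
             balance=f"{hif}_nuc")

    for tgt in ("Lon", "BDNF", "SEMA3G", "Ang2"):
        _turnover_target(
            b, tgt, "hypoxia", kd=0.7,
            inductions=[(f"kt_{tgt}_hif1", 1.5, [A("HIF1a_nuc", 0.6, 2.0)]),
                        (f"kt_{tgt}_hif2", 1.5, [A("HIF2a_nuc", 0.6, 2.0)])],
            basal_param=f"kt_{tgt}_basal")

    # p53 stress integration with MDM2 negative feedback
    b.rx("syn_p53_hif", "hypoxia", products=[("p53", 1)],
         kind="zeroth_order_synthesis",
         regulators=[A("HIF1a_nuc", 0.6, 2.0)], param="kt_p53_hif", value=1.5)
    b.rx("syn_p53_ros", "hypoxia", products=[("p53", 1)],
         kind="zeroth_order_synthesis",
         regulators=[A("ROS", 4.0, 3.0)], param="kt_p53_ros", value=0.5)
    b.rx("deg_p53_MDM2", "hypoxia", reactants=[("p53", 1)],
         kind="first_order_decay", regulators=[L("MDM2")],
         param="kd_p53_MDM2", value=0.4)
    b.rx("deg_p53", "hypoxia", reactants=[("p53", 1)],
         kind="first_order_decay", param="kd_p53", value=0.05)
    b.rx("syn_p53", "hypoxia", products=[("p53", 1)],
         kind="zeroth_order_synthesis", param="kt_p53", balance="p53")

    _turnover_target(b, "MDM2", "hypoxia", kd=0.3,
                     inductions=[("kt_MDM2", 0.6, [A("p53", 1.5, 2.0)])],
                     basal_param="kt_MDM2_basal")
    _turnover_target(b, "TIGAR", "hypoxia", kd=0.3,
                     inductions=[("kt_TIGAR", 0.6, [A("p53", 1.5, 2.0)])],
                     basal_param="kt_TIGAR_basal")
    b.rx("syn_NADPH", "metabolism", products=[("NADPH", 1)],
         kind="zeroth_order_synthesis",
         regulators=[L("TIGAR"), A("glucose", 1.0)],
         param="kt_NADPH", value=0.3)
    b.rx("deg_NADPH", "metabolism", reactants=[("NADPH", 1)],
         kind="first_order_decay", param="kd_NADPH", balance="NADPH")
    # BAX carries the apoptotic commitment switch: p53-driven induction plus
    # steep self-amplification (mitochondrial outer-membrane permeabilization
    # is self-reinforcing).  Sustained p53 during long OGD latches BAX high;
    # short OGD transients stay below the threshold and are reversible.
    _turnover_target(b, "BAX", "hypoxia", kd=0.2,
                     inductions=[("kt_BAX", 0.8, [A("p53", 2.0, 3.0)]),
                                 ("kt_BAX_self", 0.8, [A("BAX", 2.5, 6.0)])],
                     basal_param="kt_BAX_basal")
    # executioner caspase activity follows BAX with a high threshold
    _turnover_target(
        b, "Casp3", "hypoxia", kd=0.15,
        inductions=[("kt_Casp3_BAX", 1.0, [A("BAX", 3.2, 4.0)])],
        basal_param="kt_Casp3_basal")

    # ---------------- metabolism ----------------
    b.rx("syn_ATP_aerobic", "metabolism", reactants=[("AMP", 1)],
         products=[("ATP", 1)],
         regulators=[A("glucose", 1.0), A("O2", 0.03), I("ONOO", 1.3, 4.0)],
         param="k_ATP_aerobic", value=12.0)
    b.rx("syn_ATP_anaerobic", "metabolism", reactants=[("AMP", 1)],
         products=[("ATP", 1)],
         regulators=[A("glucose", 1.0), L("PFKFB3")],
         param="k_ATP_anaerobic", value=1.2)
    b.rx("use_ATP", "metabolism", reactants=[("ATP", 1)],
         products=[("AMP", 1)], kind="first_order_decay",
         param="k_ATP_use", balance="ATP")
    _turnover_target(b, "PFKFB3", "metabolism", kd=0.3,
                     inductions=[("kt_PFKFB3_O2", 0.5, [I("O2", 0.05)])],
                     basal_param="kt_PFKFB3_basal")

    # ---------------- oxidative stress ----------------
    b.rx("deg_SDH", "oxidative_stress", reactants=[("SDH", 1)],
         kind="first_order_decay", param="kd_SDH", value=0.1)
    b.rx("syn_SDH", "oxidative_stress", products=[("SDH", 1)],
         kind="zeroth_order_synthesis", param="kt_SDH", balance="SDH")
    # SDH flux reversal under low O2 accumulates succinate; restored O2
    # drives its rapid oxidation
    b.rx("ox_Succinate", "oxidative_stress", reactants=[("Succinate", 1)],
         kind="first_order_decay", regulators=[L("SDH"), A("O2", 0.02)],
         param="kd_Succinate", value=0.5)
    b.rx("syn_Succinate", "oxidative_stress", products=[("Succinate", 1)],
         kind="zeroth_order_synthesis",
         regulators=[L("SDH"), I("O2", 0.02)],
         param="kt_Succinate", balance="Succinate")
    # reverse electron transport: succinate oxidation at restored O2 -> ROS
    b.rx("prod_ROS_RET", "oxidative_stress", products=[("ROS", 1)],
         kind="zeroth_order_synthesis",
         regulators=[A("Succinate", 15.0, 2.0), A("O2", 0.02), L("SDH")],
         param="k_ROS_RET", value=6.0)
    b.rx("prod_ROS_BH2", "oxidative_stress", products=[("ROS", 1)],
         kind="zeroth_order_synthesis", regulators=[A("BH2", 0.6, 2.0)],
         param="k_ROS_BH2", value=1.0)
    b.rx("clr_ROS_NRF2", "oxidative_stress", reactants=[("ROS", 1)],
         kind="first_order_decay", regulators=[L("NRF2")],
         param="kd_ROS_NRF2", value=0.6)
    b.rx("clr_ROS_NADPH", "oxidative_stress", reactants=[("ROS", 1)],
         kind="first_order_decay", regulators=[L("NADPH")],
         param="kd_ROS_NADPH", value=0.5)
    b.rx("prod_ROS_basal", "oxidative_stress", products=[("ROS", 1)],
         kind="zeroth_order_synthesis", param="kt_ROS", balance="ROS")

    _turnover_target(b, "iNOS", "oxidative_stress", kd=0.15,
                     inductions=[("kt_iNOS_ROS", 1.0, [A("ROS", 3.0, 2.0)])],
                     basal_param="kt_iNOS_basal")
    b.rx("prod_NO_eNOS", "oxidative_stress", products=[("NO", 1)],
         kind="zeroth_order_synthesis", regulators=[L("eNOS_p")],
         param="k_NO_eNOS", value=6.0)
    b.rx("prod_NO_iNOS", "oxidative_stress", products=[("NO", 1)],
         kind="zeroth_order_synthesis", regulators=[L("iNOS")],
         param="k_NO_iNOS", value=0.8)
    b.rx("deg_NO", "oxidative_stress", reactants=[("NO", 1)],
         kind="first_order_decay", param="kd_NO", balance="NO")
    b.rx("deg_ONOO", "oxidative_stress", reactants=[("ONOO", 1)],
         kind="first_order_decay", param="kd_ONOO", value=0.25)
    b.rx("form_ONOO", "oxidative_stress", products=[("ONOO", 1)],
         kind="zeroth_order_synthesis", regulators=[L("NO"), A("ROS", 1.0)],
         param="kon_ONOO", balance="ONOO")
    b.rx("ox_BH4", "oxidative_stress", reactants=[("BH4", 1)],
         products=[("BH2", 1)], kind="first_order_decay",
         regulators=[A("ROS", 3.0, 2.0)], param="k_BH4_ox", value=1.5)
    b.rx("red_BH2", "oxidative_stress", reactants=[("BH2", 1)],
         products=[("BH4", 1)], kind="first_order_decay",
         regulators=[L("NADPH")], param="k_BH2_red", balance="BH2")

    b.rx("deg_Keap1", "oxidative_stress", reactants=[("Keap1", 1)],
         kind="first_order_decay", param="kd_Keap1", value=0.2)
    b.rx("syn_Keap1", "oxidative_stress", products=[("Keap1", 1)],
         kind="zeroth_order_synthesis", param="kt_Keap1", balance="Keap1")
    b.rx("deg_NRF2_Keap1", "oxidative_stress", reactants=[("NRF2", 1)],
         kind="first_order_decay",
         regulators=[L("Keap1"), I("ROS", 2.5, 2.0)],
         param="kd_NRF2_Keap1", value=0.5)
    b.rx("deg_NRF2", "oxidative_stress", reactants=[("NRF2", 1)],
         kind="first_order_decay", param="kd_NRF2", value=0.05)
    b.rx("syn_NRF2", "oxidative_stress", products=[("NRF2", 1)],
         kind="zeroth_order_synthesis", param="kt_NRF2", balance="NRF2")

    # Tight junction proteins turn over on a timescale of days, so damage
    # accumulated during the insult is effectively persistent within a
    # 30 h protocol.  ROS attacks them above a sharp burst threshold;
    # AKT signaling (FGF/VEGF/Tie2-driven) protects by suppressing the
    # ROS-driven degradation.
    for tj in ("ZO1", "Claudin5"):
        b.rx(f"deg_{tj}_ROS", "oxidative_stress", reactants=[(tj, 1)],
             kind="first_order_decay",
             regulators=[A("ROS", 5.0, 6.0), I("AKT_p", 0.1, 2.0)],
             param=f"kd_{tj}_ROS", value=0.8)
        b.rx(f"deg_{tj}", "oxidative_stress", reactants=[(tj, 1)],
             kind="first_order_decay", param=f"kd_{tj}", value=1e-4)
        b.rx(f"syn_{tj}", "oxidative_stress", products=[(tj, 1)],
             kind="zeroth_order_synthesis", param=f"kt_{tj}", balance=tj)

    meta = {
        "name": "bmec-default",
        "target_groups": {k: list(v) for k, v in TARGET_GROUPS.items()},
    }
    network, params = b.build(meta)
    network.metadata["n_species"] = len(network.species)
    network.metadata["n_reactions"] = len(network.reactions)
    network.metadata["baseline_parameters"] = dict(params.values)
    return network, params


@lru_cache(maxsize=1)
def _cached() -> tuple[ModelNetwork, ParameterSet]:
    return _build()


def build_default_network() -> ModelNetwork:
    """The default BMEC network (construction is deterministic)."""
    return _cached()[0]


def default_parameters() -> ParameterSet:
    """Baseline parameter set with 0.5x-2x default bounds."""
    return _cached()[1].copy()


def default_model() -> tuple[ModelNetwork, ParameterSet]:
    net, params = _cached()
    return net, params.copy()
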