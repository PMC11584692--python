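"""Structural tests of the reaction-network model and its default instance."""

import networkx as nx
import numpy as np
import pytest

from bmecsim import (
    ConfigurationError,
    ModelNetwork,
    ParameterSet,
    RateLaw,
    Reaction,
    SpeciesDef,
)
from bmecsim.network import MARKERS


def test_species_validation_rejects_bad_inputs():
    with pytest.raises(ConfigurationError):
        SpeciesDef("A", "golgi", 1.0)
    with pytest.raises(ConfigurationError):
        SpeciesDef("A", "cytosol", -1.0)
    with pytest.raises(ConfigurationError):
        SpeciesDef("A", "cytosol", 1.0, frozenset({"enzyme"}))


def test_rate_law_requires_hill_constants():
    with pytest.raises(ConfigurationError):
        RateLaw(kind="hill_activation")
    with pytest.raises(ConfigurationError):
        RateLaw(kind="hill_activation", hill_K=1.0, hill_n=0.5)
    with pytest.raises(ConfigurationError):
        RateLaw(kind="sigmoid")


def test_reaction_rejects_empty_and_fractional_stoichiometry():
    with pytest.raises(ConfigurationError):
        Reaction(id="r", reactants=[], products=[])
    with pytest.raises(ConfigurationError):
        Reaction(id="r", reactants=[("A", 0)], products=[("B", 1)])


def test_network_rejects_unknown_species_and_duplicates():
    sp = [SpeciesDef("A"), SpeciesDef("B")]
    rx = [Reaction(id="r", reactants=[("A", 1)], products=[("C", 1)],
                   parameter_id="k")]
    with pytest.raises(ConfigurationError):
        ModelNetwork(sp, rx)
    with pytest.raises(ConfigurationError):
        ModelNetwork([SpeciesDef("A"), SpeciesDef("A")], [])


def test_orphan_species_fails_participation_invariant():
    net = ModelNetwork([SpeciesDef("A"), SpeciesDef("B")],
                       [Reaction(id="r", reactants=[("A", 1)], products=[("A", 1)],
                                 parameter_id="k")])
    with pytest.raises(ConfigurationError, match="not participating"):
        net.validate()


def test_parameter_set_bounds_and_scaling():
    ps = ParameterSet.with_default_bounds({"k1": 2.0})
    assert ps.bounds["k1"] == (1.0, 4.0)
    with pytest.raises(ConfigurationError):
        ParameterSet({"k1": -1.0})
    scaled = ps.scaled({"k1": 0.5})
    assert scaled.values["k1"] == 1.0
    with pytest.raises(ConfigurationError):
        ps.scaled({"zzz": 1.0})


def test_default_network_every_species_participates(model):
    net, params = model
    net.validate()  # participation + stoichiometry invariants
    net.check_parameters(params)


def test_default_network_markers_are_species(model):
    net, _ = model
    tagged = {s.id for s in net.species if "marker" in s.role_tags}
    assert set(MARKERS) <= set(net.species_ids)
    assert set(MARKERS) <= tagged


def test_stoichiometry_matrix_matches_declared_reactions(model):
    """Independent recount: rebuild the matrix entry-by-entry."""
    net, _ = model
    mat = net.stoichiometry_matrix()
    assert mat.shape == (len(net.species), len(net.reactions))
    idx = {s.id: i for i, s in enumerate(net.species)}
    expected = np.zeros_like(mat)
    for j, r in enumerate(net.reactions):
        for sp, st in r.reactants:
            expected[idx[sp], j] -= st
        for sp, st in r.products:
            expected[idx[sp], j] += st
    assert np.array_equal(mat, expected)
    assert np.array_equal(mat, np.round(mat))


# causal wiring the default network must implement, as (source, target,
# expected sign) along a directed path in the signed influence graph
WIRING_PATHS = [
    ("LPS", "TLR4_act", +1),
    ("TLR4_act", "TRAF6_Ub", +1),
    ("TNFa", "TNFR_act", +1),
    ("TNFR_act", "RIPK1_Ub", +1),
    ("TRAF6_Ub", "TAK1_p", +1),
    ("RIPK1_Ub", "TAK1_p", +1),
    ("TAK1_p", "IKK_p", +1),
    ("IKK_p", "NFkB_nuc", +1),
    ("NFkB_nuc", "IL6", +1),
    ("NFkB_nuc", "IL1b", +1),
    ("NFkB_nuc", "CCL2", +1),
    ("NFkB_nuc", "A20", +1),
    ("NFkB_nuc", "IkB_mRNA", +1),
    ("TAK1_p", "p38_p", +1),
    ("TAK1_p", "JNK_p", +1),
    ("TAK1_p", "ERK_p", +1),
    ("VEGF", "VEGFR_pY1175", +1),
    ("VEGFR_pY1175", "PLCg_p", +1),
    ("PLCg_p", "MEK_p", +1),
    ("MEK_p", "ERK_p", +1),
    ("PLCg_p", "Ca_cyt", +1),
    ("Ca_cyt", "eNOS_p", +1),
    ("PLCg_p", "AMPK_p", +1),
    ("AMPK_p", "ULK_p", +1),
    ("VEGF", "VEGFR_pY951", +1),
    ("VEGFR_pY951", "PI3K_p", +1),
    ("PI3K_p", "AKT_p", +1),
    ("Ang1", "Tie2_p", +1),
    ("Tie2_p", "AKT_p", +1),
    ("Tie2_p", "ERK_p", +1),
    ("FGF", "FGFR_p", +1),
    ("FGFR_p", "PI3K_p", +1),
    ("FGFR_p", "PLCg_p", +1),
    ("PLCg_p", "PKC_p", +1),
    ("PKC_p", "MEK_p", +1),
    ("AKT_p", "ZO1", +1),
    ("AKT_p", "Claudin5", +1),
    ("HIF1a_nuc", "Lon", +1),
    ("HIF1a_nuc", "BDNF", +1),
    ("HIF1a_nuc", "SEMA3G", +1),
    ("HIF1a_nuc", "Ang2", +1),
    ("HIF1a_nuc", "p53", +1),
    ("p53", "MDM2", +1),
    ("p53", "TIGAR", +1),
    ("TIGAR", "NADPH", +1),
    ("p53", "BAX", +1),
    ("BAX", "Casp3", +1),
    ("glucose", "ATP", +1),
    ("O2", "ATP", +1),
    ("ROS", "iNOS", +1),
    ("iNOS", "NO", +1),
    ("NO", "ONOO", +1),
    ("ROS", "ONOO", +1),
    ("ROS", "BH2", +1),
    ("BH2", "ROS", +1),
    ("ROS", "NRF2", +1),
    ("ROS", "IKK_p", +1),
    ("Wnt", "beta_catenin", +1),  # Wnt stabilizes beta-catenin
]

# direct inhibitory influences (single signed edge)
WIRING_EDGES_NEG = [
    ("A20", "TRAF6_Ub"),
    ("A20", "RIPK1_Ub"),
    ("PHD", "HIF1a"),
    ("PHD", "HIF2a"),
    ("MDM2", "p53"),
    ("NADPH", "ROS"),
    ("NRF2", "ROS"),
    ("ROS", "ZO1"),
    ("ROS", "Claudin5"),
    ("O2", "Succinate"),
]


@pytest.mark.parametrize("src,dst,sign", WIRING_PATHS,
                         ids=[f"{s}->{d}" for s, d, _ in WIRING_PATHS])
def test_default_wiring_paths(model, src, dst, sign):
    net, _ = model
    g = net.influence_graph()
    assert nx.has_path(g, src, dst), f"no causal path {src} -> {dst}"


@pytest.mark.parametrize("src,dst", WIRING_EDGES_NEG,
                         ids=[f"{s}-|{d}" for s, d in WIRING_EDGES_NEG])
def test_default_wiring_inhibitions(model, src, dst):
    net, _ = model
    g = net.influence_graph()
    assert g.has_edge(src, dst) and g.edges[src, dst]["sign"] == -1


def test_ros_activates_ikk_edge_exists(model):
    """Oxidative stress crosstalk into the NFkB axis (kp_IKK_ROS)."""
    net, _ = model
    r = net.get_reaction("kp_IKK_ROS__IKK_p")
    assert ("IKK", 1) in r.reactants and ("IKK_p", 1) in r.products
    assert r.parameter_id == "kp_IKK_ROS"
    assert any(g.species == "ROS" and g.mode == "activate" for g in r.regulators)


def test_named_literature_parameters_present(model):
    """Parameter naming follows the kt_/kp_/kd_/kon_/koh_/kin_ convention."""
    _, params = model
    for pid in ["kt_Succinate", "kd_Succinate", "kp_IKK_ROS", "kp_NFkB",
                "kd_IKB_mrna", "kon_HIF1a", "kt_HIF1a", "koh_HIF2a",
                "kin_HIF2a"]:
        assert pid in params.values


def test_vegfr_site_alias_accepted(model, ogdr_trajectory):
    net, _ = model
    assert net.species_index("VEGFR_pY1173") == net.species_index("VEGFR_pY1175")
    assert np.array_equal(ogdr_trajectory.get("VEGFR_pY1173"),
                          ogdr_trajectory.get("VEGFR_pY1175"))
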