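"""Network container, BiGG JSON round-trip, classes, subsystem imputation."""

import pytest

import metapgs as mp
from metapgs.exceptions import ModelFormatError, ModelValidationError
from metapgs.grr import GeneRef, OrRule
from metapgs.model import MetabolicNetwork, Metabolite, Reaction, gene_subsystem_map


def _mini(subsystems=("S1", "S1"), genes_rule2="g1"):
    mets = [
        Metabolite("a_e", "A", "e", "C2H4"),
        Metabolite("b_c", "B", "c"),
        Metabolite("c_c", "C", "c"),
    ]
    rxns = [
        Reaction("EX_a", {"a_e": -1}, 0, 1000, rxn_class="exchange"),
        Reaction("R1", {"a_e": -1, "b_c": 1}, 0, 1000, grr=GeneRef("g1"), subsystem=subsystems[0]),
        Reaction("R2", {"b_c": -1, "c_c": 1}, 0, 1000, grr=mp.parse_grr(genes_rule2), subsystem=subsystems[1]),
        Reaction("BIO", {"c_c": -1}, 0, 1000, rxn_class="biomass"),
    ]
    return MetabolicNetwork(mets, rxns)


def test_toy_json_roundtrip(toy3_scenario, tmp_path):
    """load -> write -> load preserves stoichiometry, bounds, GRR trees,
    classes, and counts (4 reactions, 3 genes, 1 biomass)."""
    path = tmp_path / "toy3.json"
    mp.save_json(toy3_scenario.network, path)
    net = mp.load_model(path)
    assert net.summary()["reactions"] == 4
    assert net.summary()["genes"] == 3
    assert net.biomass_id == "BIOMASS"
    for orig in toy3_scenario.network.reactions:
        loaded = net.reaction(orig.id)
        assert loaded.stoichiometry == orig.stoichiometry
        assert loaded.lower_bound == orig.lower_bound
        assert loaded.upper_bound == orig.upper_bound
        assert loaded.grr == orig.grr
        assert loaded.rxn_class == orig.rxn_class

    # second round trip is exact as well
    path2 = tmp_path / "again.json"
    mp.save_json(net, path2)
    net2 = mp.load_model(path2)
    assert [r.id for r in net2.reactions] == [r.id for r in net.reactions]


def test_load_rejects_garbage(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(ModelFormatError):
        mp.load_model(bad)
    with pytest.raises(ModelFormatError):
        mp.load_model(bad, format="no-such-dialect")


def test_classes_partition(mixed_chain_scenario):
    net = mixed_chain_scenario.network
    classes = [r.rxn_class for r in net.reactions]
    assert all(c in mp.model.REACTION_CLASSES for c in classes)
    assert classes.count("biomass") == 1
    assert all(len(net.reaction(r.id).stoichiometry) == 1 for r in net.exchange_reactions)


def test_validation_errors():
    mets = [Metabolite("a_e", "", "e"), Metabolite("b_c", "", "c")]
    ex = Reaction("EX_a", {"a_e": -1}, 0, 1000, rxn_class="exchange")
    bio = Reaction("BIO", {"b_c": -1}, 0, 1000, rxn_class="biomass")
    mk = Reaction("R1", {"a_e": -1, "b_c": 1}, 0, 1000, grr=GeneRef("g1"))

    with pytest.raises(ModelValidationError):  # bounds inverted
        MetabolicNetwork(mets, [ex, Reaction("R1", {"a_e": -1, "b_c": 1}, 5, 1), bio])
    with pytest.raises(ModelValidationError):  # no biomass
        MetabolicNetwork(mets, [ex, mk], genes=["g1"])
    with pytest.raises(ModelValidationError):  # two biomass without disambiguation
        MetabolicNetwork(
            mets,
            [ex, mk, bio, Reaction("BIO2", {"b_c": -1}, 0, 1000, rxn_class="biomass")],
            genes=["g1"],
        )
    with pytest.raises(ModelValidationError):  # GRR references unknown gene
        MetabolicNetwork(mets, [ex, mk, bio], genes=["other"])
    with pytest.raises(ModelValidationError):  # multi-metabolite exchange
        MetabolicNetwork(
            mets,
            [Reaction("EX_bad", {"a_e": -1, "b_c": 1}, 0, 1000, rxn_class="exchange"), mk, bio],
            genes=["g1"],
        )


def test_biomass_disambiguation():
    mets = [Metabolite("a_e", "", "e"), Metabolite("b_c", "", "c")]
    rxns = [
        Reaction("EX_a", {"a_e": -1}, 0, 1000, rxn_class="exchange"),
        Reaction("R1", {"a_e": -1, "b_c": 1}, 0, 1000),
        Reaction("BIO1", {"b_c": -1}, 0, 1000, rxn_class="biomass"),
        Reaction("BIO2", {"b_c": -0.5}, 0, 1000, rxn_class="biomass"),
    ]
    net = MetabolicNetwork(mets, rxns, biomass_id="BIO2")
    assert net.biomass_id == "BIO2"
    assert net.reaction("BIO1").rxn_class == "internal"


def test_gene_subsystem_map_unanimity():
    # both reactions in one subsystem -> assigned
    assert gene_subsystem_map(_mini(("Glycolysis", "Glycolysis")))["g1"] == "Glycolysis"
    # spanning two subsystems -> unassigned
    assert gene_subsystem_map(_mini(("Glycolysis", "TCA")))["g1"] is None
    # gene confined to one annotated reaction keeps it; the isozyme partner too
    m = gene_subsystem_map(_mini(("S1", "S2"), genes_rule2="g1 or g2"))
    assert m["g2"] == "S2" and m["g1"] is None


def test_biomass_precursors(branched_scenario):
    pre = branched_scenario.network.biomass_precursors()
    assert pre == {"p1_c": 1.0, "p2_c": 2.0, "p3_c": 3.0}


def test_metabolite_elements():
    assert Metabolite("x", formula="C6H12O6").elements() == {"C": 6.0, "H": 12.0, "O": 6.0}
    # sodium is Na, not nitrogen
    assert "N" not in Metabolite("na", formula="Na").elements()
    assert Metabolite("na", formula="Na").elements() == {"Na": 1.0}
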