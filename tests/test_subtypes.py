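"""Hierarchical evolutionary-subtype rules."""

import numpy as np
import pytest

from clonevo.model import Clone, CloneTree, DriverEvent
from clonevo.simulate import (
    SimulationConfig,
    assign_drivers_by_subtype,
    simulate_clone_tree,
    simulate_region_composition,
    true_driver_events,
)
from clonevo.subtypes import SUBTYPES, classify_cohort, classify_tumor


def two_clone_tree():
    clones = {
        "C1": Clone("C1", [], frozenset({"R1", "R2"})),
        "C2": Clone("C2", [], frozenset({"R1"})),
    }
    return CloneTree("T1", clones, {"C1": None, "C2": "C1"})


def mut(eid, gene, clonality, regions=("R1", "R2")):
    return DriverEvent(eid, "mutation", gene, frozenset(regions), clonality, gene=gene)


def scna(label, clonality, regions=("R1", "R2")):
    return DriverEvent(
        f"scna:{label}", "scna_loss", label, frozenset(regions), clonality
    )


def classify(clone_events, events, vhl_status="mutated"):
    tree = two_clone_tree()
    for cid, eids in clone_events.items():
        tree.clones[cid].events = list(eids)
    return classify_tumor(tree, events, vhl_status)


class TestRules:
    def test_rule_i_two_clonal_drivers(self):
        events = {
            "v": mut("v", "VHL", "clonal"),
            "p": mut("p", "PBRM1", "clonal"),
            "s": mut("s", "SETD2", "clonal"),
        }
        call = classify({"C1": ["v", "p", "s"]}, events)
        assert call.subtype == "multiple_clonal_driver"
        assert call.matched_rule == 1

    def test_rule_i_excludes_vhl_from_count(self):
        events = {"v": mut("v", "VHL", "clonal"), "p": mut("p", "PBRM1", "clonal")}
        call = classify({"C1": ["v", "p"]}, events)
        assert call.subtype != "multiple_clonal_driver"

    def test_rule_ii_lone_bap1_clone(self):
        events = {
            "v": mut("v", "VHL", "clonal"),
            "b": mut("b", "BAP1", "subclonal", ("R1",)),
        }
        call = classify({"C1": ["v"], "C2": ["b"]}, events)
        assert call.subtype == "BAP1_driven"
        assert call.matched_rule == 2

    def test_rule_ii_blocked_by_core_comutation_in_clone(self):
        events = {
            "v": mut("v", "VHL", "clonal"),
            "b": mut("b", "BAP1", "subclonal", ("R1",)),
            "s": mut("s", "SETD2", "subclonal", ("R1",)),
        }
        call = classify({"C1": ["v"], "C2": ["b", "s"]}, events)
        assert call.subtype != "BAP1_driven"

    def test_rule_iii_pbrm1_then_setd2(self):
        events = {
            "v": mut("v", "VHL", "clonal"),
            "p": mut("p", "PBRM1", "clonal"),
            "s": mut("s", "SETD2", "subclonal", ("R1",)),
        }
        call = classify({"C1": ["v", "p"], "C2": ["s"]}, events)
        assert call.subtype == "PBRM1_SETD2"

    def test_followed_by_requires_strict_descent(self):
        # PBRM1 and SETD2 in the same clone do not satisfy rule iii
        events = {
            "v": mut("v", "VHL", "clonal"),
            "p": mut("p", "PBRM1", "subclonal", ("R1",)),
            "s": mut("s", "SETD2", "subclonal", ("R1",)),
        }
        call = classify({"C1": ["v"], "C2": ["p", "s"]}, events)
        assert call.subtype not in ("PBRM1_SETD2", "PBRM1_PI3K", "PBRM1_SCNA")

    def test_rule_iv_pbrm1_then_pi3k(self):
        events = {
            "v": mut("v", "VHL", "clonal"),
            "p": mut("p", "PBRM1", "clonal"),
            "m": mut("m", "MTOR", "subclonal", ("R1",)),
        }
        assert classify({"C1": ["v", "p"], "C2": ["m"]}, events).subtype == "PBRM1_PI3K"

    def test_rule_v_pbrm1_then_driver_scna(self):
        events = {
            "v": mut("v", "VHL", "clonal"),
            "p": mut("p", "PBRM1", "clonal"),
            "s": scna("loss_9p", "subclonal", ("R1",)),
        }
        assert classify({"C1": ["v", "p"], "C2": ["s"]}, events).subtype == "PBRM1_SCNA"

    def test_rule_vi_vhl_wildtype(self):
        events = {"s": mut("s", "SETD2", "clonal")}
        assert classify({"C1": ["s"]}, events, "wildtype").subtype == "VHL_wildtype"

    def test_methylation_blocks_rule_vi(self):
        events = {"s": mut("s", "SETD2", "clonal")}
        call = classify({"C1": ["s"]}, events, "methylated")
        assert call.subtype != "VHL_wildtype"

    def test_rule_vii_vhl_monodriver(self):
        events = {"v": mut("v", "VHL", "clonal")}
        call = classify({"C1": ["v"]}, events)
        assert call.subtype == "VHL_monodriver"
        assert call.matched_rule == 7

    def test_no_rule_matches_unassigned(self):
        # VHL mutated plus a non-core driver: rules i-v fail, vi fails
        # (VHL mutated), vii fails (TP53 is not core but SETD2 is)
        events = {
            "v": mut("v", "VHL", "clonal"),
            "s": mut("s", "SETD2", "subclonal", ("R1",)),
        }
        call = classify({"C1": ["v"], "C2": ["s"]}, events)
        assert call.subtype == "unassigned"
        assert call.matched_rule is None


class TestTemplateRoundTrip:
    @pytest.mark.parametrize("subtype", SUBTYPES)
    def test_template_classifies_as_requested(self, subtype):
        rng = np.random.default_rng(5)
        tree = simulate_clone_tree(4, rng, "T1")
        tree, _ = simulate_region_composition(tree, 7, rng)
        events, vhl_status = assign_drivers_by_subtype(tree, subtype, rng)
        for eid, ev in events.items():
            tree.clones[ev.clone_id].events.append(eid)
        drivers = true_driver_events(tree, events)
        call = classify_tumor(tree, drivers, vhl_status)
        assert call.subtype == subtype

    def test_unknown_subtype_fatal(self):
        rng = np.random.default_rng(0)
        tree = simulate_clone_tree(3, rng, "T1")
        with pytest.raises(ValueError):
            assign_drivers_by_subtype(tree, "nonsense", rng)


class TestCohortClassification:
    def test_empty_cohort(self):
        assert classify_cohort({}).empty

    def test_bilateral_case_uses_index_tumor(self):
        events = {"v": mut("v", "VHL", "clonal")}
        t1 = two_clone_tree()
        t1.clones["C1"].events = ["v"]
        t2 = two_clone_tree()
        df = classify_cohort(
            {"K1_left": (t1, events, "mutated"), "K1_right": (t2, {}, "wildtype")},
            case_of_tumor={"K1_left": "K1", "K1_right": "K1"},
        )
        assert len(df) == 1
        assert df.iloc[0]["tumor_id"] == "K1_left"

    def test_missing_tree_reported_distinctly(self):
        df = classify_cohort({"T1": (None, {}, "mutated")})
        assert df.iloc[0]["subtype"] == "unclassifiable_input"
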