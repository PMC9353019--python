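import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from seagrassdbn.network import (DEFAULT_LABEL_MAP, LABEL_RANKING,
                                 CompletenessError, CptRule, CptRuleTable,
                                 LabelMappingError, NodeSpec, OverlapError,
                                 SchemaError, StructureError, compile_cpt,
                                 default_network_path, load_default_network,
                                 load_network, validate_network)

from conftest import MONTH_STATES


def single_parent_table(rows, child="c", parent="p"):
    return CptRuleTable(child, (parent,), tuple(rows))


class TestCompileCpt:
    def test_published_row_weights_and_normalisation(self):
        """A Jun-Jul Z. noltei row maps its labels to (5/6, 1/6, 0.01, 0.01)
        and renormalises to a unit-sum distribution preserving the odds."""
        raw = np.array([DEFAULT_LABEL_MAP[l] for l in
                        ("very likely", "very unlikely",
                         "extremely unlikely", "extremely unlikely")])
        assert raw == pytest.approx([5 / 6, 1 / 6, 0.01, 0.01])
        table = single_parent_table([CptRule(
            (None,), ("very likely", "very unlikely",
                      "extremely unlikely", "extremely unlikely"))])
        cpt = compile_cpt(table, [("x", "y")], ("High", "Moderate", "Low", "Zero"))
        expected = raw / raw.sum()  # row sum 1.02
        assert cpt[("x",)] == pytest.approx(expected, abs=1e-9)
        assert cpt[("x",)] == pytest.approx(
            [0.81699, 0.16340, 0.00980, 0.00980], abs=5e-6)
        assert cpt[("x",)].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_nonzero_weight_becomes_certainty(self):
        table = single_parent_table([CptRule(
            (None,), ("impossible", "impossible", "impossible",
                      "extremely likely"))])
        cpt = compile_cpt(table, [("x",  "y")], ("a", "b", "c", "d"))
        assert cpt[("x",)] == pytest.approx([0, 0, 0, 1], abs=1e-12)

    def test_na_expands_to_identical_rows(self):
        table = single_parent_table([CptRule((None,), ("likely", "unlikely"))])
        cpt = compile_cpt(table, [tuple("abcde")], ("hi", "lo"))
        rows = [cpt[(s,)] for s in "abcde"]
        assert all(np.array_equal(rows[0], r) for r in rows)

    def test_month_group_antecedents(self):
        table = single_parent_table([
            CptRule((frozenset({"Jun", "Jul"}),), ("very likely", "very unlikely")),
            CptRule((frozenset(set(MONTH_STATES) - {"Jun", "Jul"}),),
                    ("unlikely", "likely")),
        ], parent="time_of_year")
        cpt = compile_cpt(table, [MONTH_STATES], ("hi", "lo"))
        assert cpt[("Jun",)][0] > 0.8
        assert cpt[("Jan",)][0] < 0.4

    def test_uncovered_combination_names_it(self):
        table = single_parent_table([CptRule(("x",), ("likely", "unlikely"))])
        with pytest.raises(CompletenessError, match="'p': 'y'"):
            compile_cpt(table, [("x", "y")], ("a", "b"))

    def test_overlapping_rules_error(self):
        table = single_parent_table([
            CptRule((None,), ("likely", "unlikely")),
            CptRule(("x",), ("unlikely", "likely")),
        ])
        with pytest.raises(OverlapError):
            compile_cpt(table, [("x", "y")], ("a", "b"))

    def test_unknown_label_error(self):
        table = single_parent_table([CptRule((None,), ("plausible", "unlikely"))])
        with pytest.raises(LabelMappingError, match="plausible"):
            compile_cpt(table, [("x",)], ("a", "b"))

    def test_non_monotone_label_map_rejected(self):
        bad = dict(DEFAULT_LABEL_MAP, likely=0.2)  # below "unlikely"
        table = single_parent_table([CptRule((None,), ("likely", "unlikely"))])
        with pytest.raises(LabelMappingError):
            compile_cpt(table, [("x",)], ("a", "b"), label_map=bad)

    @given(st.lists(st.sampled_from(LABEL_RANKING), min_size=2, max_size=5),
           st.integers(2, 4))
    def test_rows_always_normalised(self, labels, k):
        """Compiled rows lie on the simplex for any label combination with
        at least one nonzero weight."""
        if all(DEFAULT_LABEL_MAP[l] == 0 for l in labels):
            labels[0] = "50/50"
        table = single_parent_table(
            [CptRule((None,), tuple(labels))])
        cpt = compile_cpt(table, [tuple(f"s{i}" for i in range(k))],
                          tuple(f"c{i}" for i in range(len(labels))))
        flat = cpt.values.reshape(-1, len(labels))
        assert np.all(flat >= 0)
        assert np.allclose(flat.sum(axis=1), 1.0, atol=1e-9)
        # renormalising an already normalised row is a no-op
        again = flat / flat.sum(axis=1, keepdims=True)
        assert np.allclose(again, flat, atol=1e-12)

    @given(st.sampled_from(LABEL_RANKING[:-1]), st.sampled_from(LABEL_RANKING[:-1]))
    def test_label_monotonicity(self, la, lb):
        """A higher-ranked label always wins more normalised mass on its
        state than a lower-ranked one in the same two-state row."""
        ia, ib = LABEL_RANKING.index(la), LABEL_RANKING.index(lb)
        if ia == ib:
            return
        hi, lo = (la, lb) if ia < ib else (lb, la)
        table = single_parent_table([CptRule((None,), (hi, lo))])
        cpt = compile_cpt(table, [("x",)], ("a", "b"))
        assert cpt[("x",)][0] > cpt[("x",)][1]

    def test_compiles_full_published_table(self, baseline_rule_table,
                                           baseline_parent_states):
        cpt = compile_cpt(baseline_rule_table, baseline_parent_states,
                          ("High", "Moderate", "Low", "Zero"))
        flat = cpt.values.reshape(-1, 4)
        assert flat.shape == (12 * 2 * 2 * 2, 4)
        assert np.allclose(flat.sum(axis=1), 1.0, atol=1e-9)


class TestLoadNetwork:
    def test_default_network_loads_and_validates(self, default_net):
        assert validate_network(default_net) == []
        assert default_net.inter_edges == (("shoot_density", "shoot_density"),)
        assert default_net.states("shoot_density") == (
            "High", "Moderate", "Low", "Zero")
        assert set(default_net.cpts) == set(default_net.nodes)

    def test_three_state_variant(self, default_net3):
        assert validate_network(default_net3) == []
        assert default_net3.states("light") == (
            "above_saturation", "below_saturation", "below_limitation")

    def test_cycle_detected(self, tmp_path):
        doc = {
            "nodes": [{"name": "A", "states": ["x", "y"]},
                      {"name": "B", "states": ["x", "y"]}],
            "edges": [["A", "B"], ["B", "A"]],
        }
        p = tmp_path / "net.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(StructureError, match="cycle"):
            load_network(p)

    def test_empty_state_list_rejected(self, tmp_path):
        doc = {"nodes": [{"name": "A", "states": []}]}
        p = tmp_path / "net.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(SchemaError, match="empty state list"):
            load_network(p)

    def test_missing_cpt_rejected(self, tmp_path):
        doc = {"nodes": [{"name": "A", "states": ["x", "y"]}], "cpt_rules": {}}
        p = tmp_path / "net.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(SchemaError, match="without CPT"):
            load_network(p)

    def test_label_map_override_changes_weights(self, tmp_path):
        lm = dict(DEFAULT_LABEL_MAP)
        lm["extremely likely"] = 0.95
        net = load_default_network(2, label_map=lm)
        assert validate_network(net) == []


class TestValidateNetwork:
    def test_findings_for_broken_cpt(self, default_net):
        import copy
        net = copy.deepcopy(default_net)
        cpt = net.cpts["light"]
        cpt.values[...] = [0.5, 0.4]  # bypass compilation, break the sum
        findings = validate_network(net)
        assert len(findings) == 1 and "sum to 1" in findings[0]

    def test_finding_for_missing_cpt(self, default_net):
        import copy
        net = copy.deepcopy(default_net)
        del net.cpts["seed_density"]
        findings = validate_network(net)
        assert any("no CPT" in f for f in findings)


def test_node_spec_invariants():
    with pytest.raises(SchemaError):
        NodeSpec("n", ("only",))
    with pytest.raises(SchemaError):
        NodeSpec("n", ("a", "a"))


def test_shipped_network_files_exist():
    assert default_network_path(2).exists()
    assert default_network_path(3).exists()
    with pytest.raises(ValueError):
        default_network_path(4)
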