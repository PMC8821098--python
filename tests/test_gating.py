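"""Hierarchical gating engine, FMO thresholds and the packaged lung tree."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lungflow as lf
from lungflow.events import EventTable
from lungflow.gating import Gate, GatingError, GatingNode, GatingTree, ThresholdSet
from lungflow.panel import FLUOR_CHANNELS
from lungflow.pipeline import process_sample, recall_precision


def _blank_events(n):
    data = pd.DataFrame(0.0, index=range(n), columns=list(FLUOR_CHANNELS))
    data["FSC-A"] = 80_000.0
    data["FSC-W"] = 70_000.0
    data["SSC-A"] = 40_000.0
    return data


def _manual_thresholds(tree, cut=2.5):
    ts = ThresholdSet()
    for node in tree.iter_nodes():
        if node.gate is None:
            continue
        for axis, spec in zip(node.gate.axes, node.gate.cutpoints):
            if spec is None:
                ts.cutpoints[(node.name, axis)] = cut
    return ts


@pytest.fixture()
def routing_setup(tumor_tree):
    """Events table with filler debris (so the data-driven debris cut lands
    low) plus a uniform manual threshold set (arcsinh 2.5 ~ raw 915)."""
    n_filler = 50
    data = _blank_events(n_filler)
    data.loc[:, "FSC-A"] = 5000.0  # filler debris anchors the 10th pct cut
    data.loc[:, "SSC-A"] = 3000.0
    return data, _manual_thresholds(tumor_tree)


def _route_one(tumor_tree, routing_setup, **channels):
    filler, ts = routing_setup
    row = _blank_events(1)
    for k, v in channels.items():
        row[k] = float(v)
    table = EventTable(pd.concat([filler, row], ignore_index=True),
                      {"compensated": True})
    labeled, _ = lf.apply_tree(table, tumor_tree, ts)
    return labeled.data["label"].iloc[-1]


HI = 15_000.0


class TestEventRouting:
    def test_bec_route(self, tumor_tree, routing_setup):
        label = _route_one(tumor_tree, routing_setup, **{
            "PE-Cy7": HI, "FITC_AF488": HI, "PerCP-Cy5.5": HI})
        assert label == "BEC"

    def test_neutrophil_route(self, tumor_tree, routing_setup):
        label = _route_one(tumor_tree, routing_setup, **{
            "VioBlue": HI, "BV605": HI, "APC-Cy7_APC-eF780": HI})
        assert label == "neutrophil"

    def test_treg_route(self, tumor_tree, routing_setup):
        label = _route_one(tumor_tree, routing_setup, **{
            "VioBlue": HI, "APC-Cy7_APC-eF780": HI, "BV711": HI,
            "FITC_AF488": HI})
        assert label == "Treg"

    def test_llc1_route(self, tumor_tree, routing_setup):
        label = _route_one(tumor_tree, routing_setup, **{"FSC-A": 250_000.0})
        assert label == "LLC1"

    def test_dead_event_excluded_before_any_leaf(self, tumor_tree,
                                                 routing_setup):
        label = _route_one(tumor_tree, routing_setup, **{
            "7AAD": 25_000.0, "PE-Cy7": HI, "FITC_AF488": HI,
            "PerCP-Cy5.5": HI})
        assert label == "dead"

    def test_doublet_excluded(self, tumor_tree, routing_setup):
        label = _route_one(tumor_tree, routing_setup,
                           **{"FSC-W": 150_000.0, "VioBlue": HI})
        assert label == "doublet"

    def test_bead_scatter_excluded_first(self, tumor_tree, routing_setup):
        label = _route_one(tumor_tree, routing_setup,
                           **{"FSC-A": 25_000.0, "SSC-A": 250_000.0,
                              "7AAD": 25_000.0})
        assert label == "bead"


class TestPackagedTree:
    def test_leaf_population_counts(self, tree, tumor_tree):
        assert len(tree.leaf_labels) == 20
        assert len(tumor_tree.leaf_labels) == 21
        assert "LLC1" in tumor_tree.leaf_labels

    def test_first_immune_gate_removes_alveolar_macrophages(self, tree):
        lineage = tree.node("lineage")
        immune = dict(lineage.children)["++"]
        assert immune.name == "am_gate"
        assert set(immune.gate.axes) == {"CD44", "CD11b"}

    def test_exclusion_labels(self, tree):
        assert set(tree.exclusion_labels) == {"bead", "debris", "dead",
                                              "doublet"}

    def test_yaml_round_trip_preserves_labels(self, tumor_tree, tmp_path,
                                              profiles, presets, spill):
        path = tmp_path / "tree.yaml"
        tumor_tree.to_yaml(path)
        back = GatingTree.from_yaml(path)
        assert set(back.leaf_labels) == set(tumor_tree.leaf_labels)
        sample = lf.simulate_sample(profiles, presets["control"], 3000,
                                    spill, 12)
        sample.metadata["compensated"] = True
        ts = _manual_thresholds(tumor_tree)
        a, _ = lf.apply_tree(sample, tumor_tree, ts)
        b, _ = lf.apply_tree(sample, back, ts)
        assert (a.data["label"] == b.data["label"]).all()

    def test_gatingml_export_parses(self, tumor_tree, tmp_path, thresholds):
        import xml.etree.ElementTree as ET

        path = tmp_path / "tree.xml"
        lf.export_gatingml(tumor_tree, path, thresholds)
        root = ET.parse(path).getroot()
        gates = [e for e in root
                 if e.tag.endswith("RectangleGate")]
        assert len(gates) > 10


class TestThresholds:
    def test_zero_signal_fmo_gives_zero_cutpoints(self, tumor_tree):
        fmos = {m: EventTable(_blank_events(500), {})
                for m in tumor_tree.marker_axes()}
        ts = lf.derive_thresholds(tumor_tree, fmos)
        assert ts.cutpoints and all(v == 0.0 for v in ts.cutpoints.values())

    def test_percentile_100_is_channel_maximum(self, tumor_tree):
        rng = np.random.default_rng(0)
        fmos = {}
        for m in tumor_tree.marker_axes():
            data = _blank_events(500)
            for c in FLUOR_CHANNELS:
                data[c] = rng.uniform(0, 100, 500)
            fmos[m] = EventTable(data, {})
        ts = lf.derive_thresholds(tumor_tree, fmos, percentile=100)
        key = ("lineage", "CD45")
        chan = tumor_tree.channel_of["CD45"]
        expect = math.asinh(fmos["CD45"].data[chan].max() / 150.0)
        assert ts.cutpoints[key] <= expect + 1e-12
        assert ts.cutpoints[key] > 0

    def test_missing_fmo_lists_markers(self, tumor_tree):
        with pytest.raises(GatingError, match="CD45"):
            lf.derive_thresholds(tumor_tree, {})

    @pytest.mark.parametrize("marker,node,pop", [
        ("GITR", "treg_gitr", "CD4_T"),
        ("CD146", "endothelial", "LEC"),
        ("Ly6G", "neutrophil_gate", "eosinophil"),
    ])
    def test_true_negatives_rarely_exceed_cutpoint(self, labeled_control,
                                                   tumor_tree, thresholds,
                                                   marker, node, pop):
        """The FMO percentile construction caps the false-positive rate of
        truly negative populations near (100 - percentile)%."""
        labeled, _ = labeled_control
        chan = tumor_tree.channel_of[marker]
        sel = labeled.data.truth_label == pop
        vals = np.arcsinh(labeled.data.loc[sel, chan] / 150.0)
        cut = thresholds.cutpoints[(node, marker)]
        assert (vals > cut).mean() < 0.015


class TestApplyTree:
    def test_partition_property(self, labeled_control):
        labeled, pop_table = labeled_control
        labels = labeled.data["label"]
        assert (labels != "").all()
        terminal = pop_table[pop_table.kind.isin(
            ["leaf", "exclusion", "unassigned"])]
        assert terminal["count"].sum() == len(labeled)

    def test_sibling_order_robustness(self, panel, profiles, presets, spill,
                                      thresholds, tumor_tree, comp):
        """Reversing every node's child insertion order cannot change the
        assignment because sibling outcomes are mutually exclusive."""
        sample = lf.simulate_sample(profiles, presets["control"], 5000,
                                    spill, 31)
        comp_sample = lf.apply_compensation(sample, comp)
        a, _ = lf.apply_tree(comp_sample, tumor_tree, thresholds)

        def reverse(node):
            node.children = dict(reversed(list(node.children.items())))
            for _, child in node.distinct_children():
                reverse(child)

        flipped = lf.lung_gating_tree(include_tumor_leaf=True, panel=panel)
        reverse(flipped.root)
        b, _ = lf.apply_tree(comp_sample, flipped, thresholds)
        assert (a.data["label"] == b.data["label"]).all()

    def test_population_recovery_healthy_sample(self, labeled_control):
        labeled, _ = labeled_control
        rp = recall_precision(labeled)
        assert rp.recall.median() >= 0.90
        assert rp.precision.median() >= 0.90

    def test_shared_channel_triple_recovered(self, labeled_control):
        """CD146 (BEC), GITR (Treg) and SiglecH (pDC) share the FITC/AF488
        detector; all three populations must still be recovered."""
        labeled, _ = labeled_control
        rp = recall_precision(labeled).set_index("population")
        for pop in ("BEC", "Treg", "pDC"):
            assert rp.loc[pop, "recall"] >= 0.90, pop
            assert rp.loc[pop, "precision"] >= 0.90, pop

    def test_tumor_model_discrimination(self, profiles, presets, spill,
                                        comp, tumor_tree, thresholds,
                                        labeled_control):
        labeled_ctrl, _ = labeled_control
        assert (labeled_ctrl.data["label"] == "LLC1").sum() == 0
        iv = lf.simulate_sample(profiles, presets["intravenous"], 20_000,
                                spill, 41)
        labeled_iv, _ = process_sample(iv, comp, tumor_tree, thresholds)
        assert (labeled_iv.data["label"] == "LLC1").sum() > 0

    def test_missing_threshold_raises(self, tumor_tree, profiles, presets,
                                      spill):
        sample = lf.simulate_sample(profiles, presets["control"], 500, spill,
                                    2)
        with pytest.raises(GatingError, match="cutpoint"):
            lf.apply_tree(sample, tumor_tree, ThresholdSet())


class TestGatePrimitives:
    @given(
        cuts=st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
        seed=st.integers(0, 2**16),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_quadrant_partitions_for_any_cutpoints(self, cuts, seed):
        rng = np.random.default_rng(seed)
        g = Gate("quadrant2d", ("a", "b"), (None, None))
        x, y = rng.normal(size=(2, 200))
        masks = g.evaluate([x, y], list(cuts))
        total = sum(m.astype(int) for m in masks.values())
        assert (total == 1).all()

    def test_quadrant_masks_partition(self):
        rng = np.random.default_rng(0)
        g = Gate("quadrant2d", ("a", "b"), (None, None))
        x, y = rng.normal(size=(2, 1000))
        masks = g.evaluate([x, y], [0.1, -0.2])
        total = np.zeros(1000, int)
        for m in masks.values():
            total += m.astype(int)
        assert (total == 1).all()

    def test_threshold_tie_goes_negative(self):
        g = Gate("threshold1d", ("a",), (None,))
        masks = g.evaluate([np.array([1.0, 2.0, 3.0])], [2.0])
        assert list(masks["+"]) == [False, False, True]

    def test_interval_half_open(self):
        g = Gate("interval1d", ("a",), ((1.0, 2.0),))
        masks = g.evaluate([np.array([0.5, 1.0, 1.5, 2.0])], [(1.0, 2.0)])
        assert list(masks["in"]) == [False, True, True, False]

    def test_unknown_kind_rejected(self):
        with pytest.raises(GatingError):
            Gate("polygon", ("a",), (None,))
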