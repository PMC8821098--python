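"""Panel data model and channel-sharing resolvability."""

import random

import pytest

import lungflow as lf
from lungflow.gating import Gate, GatingNode, GatingTree
from lungflow.panel import DEFAULT_CHANNEL_MAP, AntibodyEntry, Panel, PanelError


def _mk(antigen, fluor, group=None):
    return AntibodyEntry(antigen=antigen, fluorochrome=fluor, dilution=100,
                         combined_group=group)


class TestPanelModel:
    def test_packaged_panel_design_counts(self, panel):
        assert len(panel.entries) == 25
        assert len(lf.detector_channels(panel)) == 13
        assert len(lf.marker_readouts(panel)) == 24
        assert lf.parameter_count(panel) == 27

    def test_combined_group_collapses_to_joint_readout(self, panel):
        assert "CD64/MerTK" in lf.marker_readouts(panel)
        assert "CD64" not in lf.marker_readouts(panel)

    def test_empty_panel(self):
        p = Panel(entries=(), channel_map=dict(DEFAULT_CHANNEL_MAP))
        assert lf.marker_readouts(p) == []
        assert lf.detector_channels(p) == set()
        assert lf.parameter_count(p) == 3  # viability + two scatter

    def test_same_antigen_two_fluorochromes_is_legal(self):
        p = Panel(entries=(_mk("CD45", "PE"), _mk("CD45", "APC")),
                  channel_map=dict(DEFAULT_CHANNEL_MAP))
        assert len(p.entries) == 2

    def test_duplicate_antigen_fluorochrome_pair_rejected(self):
        with pytest.raises(PanelError, match="duplicate"):
            Panel(entries=(_mk("CD45", "PE"), _mk("CD45", "PE")),
                  channel_map=dict(DEFAULT_CHANNEL_MAP))

    def test_unknown_fluorochrome_rejected(self):
        with pytest.raises(PanelError, match="BUV999"):
            Panel(entries=(_mk("CD45", "BUV999"),),
                  channel_map=dict(DEFAULT_CHANNEL_MAP))

    def test_fitc_and_af488_merge_into_one_detector(self):
        p = Panel(entries=(_mk("GITR", "FITC"), _mk("CD146", "AF488")),
                  channel_map=dict(DEFAULT_CHANNEL_MAP))
        assert lf.detector_channels(p) == {"FITC_AF488"}

    def test_invalid_dilution_rejected(self):
        with pytest.raises(PanelError, match="dilution"):
            AntibodyEntry(antigen="CD4", fluorochrome="PE", dilution=0)

    def test_channel_count_stability_under_new_entries(self, panel):
        base = len(lf.detector_channels(panel))
        extra_same = panel.entries + (_mk("CD199", "PE"),)
        p1 = Panel(entries=extra_same, channel_map=panel.channel_map)
        assert len(lf.detector_channels(p1)) == base
        cm = dict(panel.channel_map)
        cm["BUV395"] = "BUV395"
        p2 = Panel(entries=panel.entries + (_mk("CD199", "BUV395"),),
                   channel_map=cm)
        assert len(lf.detector_channels(p2)) == base + 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_readout_order_invariance(self, panel, seed):
        entries = list(panel.entries)
        random.Random(seed).shuffle(entries)
        shuffled = Panel(entries=tuple(entries), channel_map=panel.channel_map)
        assert lf.marker_readouts(shuffled) == lf.marker_readouts(panel)
        assert lf.detector_channels(shuffled) == lf.detector_channels(panel)


# --------------------------------------------------------------------------
# channel-sharing checks


def _toy_tree(nodes_spec, channel_of):
    """Build a toy tree from {name: (gate, children)} nested tuples."""
    return GatingTree(root=nodes_spec, channel_of=channel_of)


def _toy_panel():
    return Panel(
        entries=(_mk("CD146", "AF488"), _mk("GITR", "FITC"),
                 _mk("CD45", "VioBlue")),
        channel_map=dict(DEFAULT_CHANNEL_MAP),
    )


def _leaf(label):
    return GatingNode(f"leaf:{label}", leaf_label=label)


def enumerate_paths(tree):
    """Independent oracle: explicit stack-based enumeration of all
    root-to-terminal paths as lists of (gate, claimed outcome set)."""
    paths = []
    stack = [(tree.root, [])]
    while stack:
        node, acc = stack.pop()
        if node.gate is None:
            paths.append(acc)
            continue
        children = list(node.distinct_children())
        if not children:
            paths.append(acc)
        for outcomes, child in children:
            stack.append((child, acc + [(node.gate, frozenset(outcomes))]))
    return paths


def oracle_conflicts(panel, tree):
    """Brute-force resolvability oracle over enumerated paths.

    An axis constrains a step when the claimed outcome set pins it (for a
    threshold: a single side; for a quadrant: the claimed outcomes are not
    the full cross-product of the per-axis signs, or one axis has a single
    sign).  Two distinct co-channel readouts conflict on a path unless the
    earlier is pinned to "-".
    """
    chan = panel.readout_channels()
    found = set()
    for path in enumerate_paths(tree):
        used = []  # (readout, side)
        for gate, outcomes in path:
            outs = sorted(outcomes)
            if gate.kind in ("threshold1d", "ratio_fsc_w"):
                step = ([] if len(outs) == 2
                        else [(gate.axes[0], outs[0])])
            elif gate.kind == "quadrant2d":
                sx = {o[0] for o in outs}
                sy = {o[1] for o in outs}
                if len(outs) == len(sx) * len(sy):
                    step = []
                    if len(sx) == 1:
                        step.append((gate.axes[0], next(iter(sx))))
                    if len(sy) == 1:
                        step.append((gate.axes[1], next(iter(sy))))
                else:
                    step = [(gate.axes[0], "?"), (gate.axes[1], "?")]
            else:
                step = [(a, "?") for a in gate.axes]
            for k, (axis, side) in enumerate(step):
                if axis not in chan:
                    continue
                earlier = used + [s for s in step[:k] if s[0] in chan]
                for prev, prev_side in earlier:
                    if prev != axis and chan.get(prev) == chan[axis] \
                            and prev_side != "-":
                        found.add((chan[axis], prev, axis))
            used.extend(s for s in step if s[0] in chan)
    return found


class TestChannelSharing:
    def test_packaged_tree_is_resolvable(self, panel, tumor_tree):
        report = lf.check_sharing(panel, tumor_tree)
        assert report.resolvable
        assert report.conflicts == []
        shared = {c: r for c, r in report.channel_readouts.items()
                  if len(r) > 1}
        assert "FITC_AF488" in shared  # CD146 / GITR / SiglecH

    def test_constructed_conflict_is_flagged(self):
        panel = _toy_panel()
        # CD146 and GITR (one channel) gated at the same node
        root = GatingNode(
            "both", gate=Gate("quadrant2d", ("CD146", "GITR"), (None, None)),
            children={"++": _leaf("x")},
        )
        tree = GatingTree(root=root, channel_of=panel.readout_channels())
        report = lf.check_sharing(panel, tree)
        assert not report.resolvable
        assert len(report.conflicts) == 1
        chan, pair, _ = report.conflicts[0]
        assert chan == "FITC_AF488" and set(pair) == {"CD146", "GITR"}

    def test_sequential_conflict_positive_ancestor(self):
        panel = _toy_panel()
        inner = GatingNode("gitr",
                           gate=Gate("threshold1d", ("GITR",), (None,)),
                           children={"+": _leaf("treg")})
        root = GatingNode("cd146",
                          gate=Gate("threshold1d", ("CD146",), (None,)),
                          children={"+": inner})
        tree = GatingTree(root=root, channel_of=panel.readout_channels())
        assert not lf.check_sharing(panel, tree).resolvable

    def test_negative_ancestor_is_exempt(self):
        panel = _toy_panel()
        inner = GatingNode("gitr",
                           gate=Gate("threshold1d", ("GITR",), (None,)),
                           children={"+": _leaf("treg")})
        root = GatingNode("cd146",
                          gate=Gate("threshold1d", ("CD146",), (None,)),
                          children={"-": inner, "+": _leaf("bec")})
        tree = GatingTree(root=root, channel_of=panel.readout_channels())
        assert lf.check_sharing(panel, tree).resolvable

    def test_combined_group_pair_is_exempt(self):
        panel = Panel(
            entries=(_mk("CD64", "PE-Cy7", "mac"), _mk("MerTK", "PE-Cy7",
                                                       "mac")),
            channel_map=dict(DEFAULT_CHANNEL_MAP),
        )
        root = GatingNode("m", gate=Gate("threshold1d", ("CD64/MerTK",),
                                         (None,)),
                          children={"+": _leaf("mac")})
        tree = GatingTree(root=root, channel_of=panel.readout_channels())
        assert lf.check_sharing(panel, tree).resolvable

    def test_unknown_marker_raises(self, panel):
        root = GatingNode("x", gate=Gate("threshold1d", ("CD99",), (None,)),
                          children={"+": _leaf("y")})
        tree = GatingTree(root=root, channel_of={"CD99": "PE"})
        with pytest.raises(PanelError, match="CD99"):
            lf.check_sharing(panel, tree)

    def test_agrees_with_bruteforce_oracle(self, panel, tumor_tree):
        report = lf.check_sharing(panel, tumor_tree)
        oracle = oracle_conflicts(panel, tumor_tree)
        assert bool(report.conflicts) == bool(oracle)
        assert oracle == set()

    def test_oracle_agreement_on_conflicting_tree(self):
        panel = _toy_panel()
        inner = GatingNode("gitr",
                           gate=Gate("threshold1d", ("GITR",), (None,)),
                           children={"+": _leaf("treg")})
        root = GatingNode("cd146",
                          gate=Gate("threshold1d", ("CD146",), (None,)),
                          children={"+": inner})
        tree = GatingTree(root=root, channel_of=panel.readout_channels())
        report = lf.check_sharing(panel, tree)
        oracle = oracle_conflicts(panel, tree)
        assert bool(report.conflicts) and bool(oracle)
        got = {(c, frozenset(p)) for c, p, _ in report.conflicts}
        want = {(c, frozenset((a, b))) for c, a, b in oracle}
        assert got == want
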