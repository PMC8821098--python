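import pytest

import lungflow as lf
from lungflow.pipeline import (
    make_spillover_estimate,
    make_thresholds,
    process_sample,
)


@pytest.fixture(scope="session")
def panel():
    return lf.default_panel()


@pytest.fixture(scope="session")
def profiles():
    return lf.default_profiles()


@pytest.fixture(scope="session")
def spill():
    return lf.default_spillover()


@pytest.fixture(scope="session")
def tree(panel):
    return lf.lung_gating_tree(panel=panel)


@pytest.fixture(scope="session")
def tumor_tree(panel):
    return lf.lung_gating_tree(include_tumor_leaf=True, panel=panel)


@pytest.fixture(scope="session")
def presets():
    return lf.condition_presets()


@pytest.fixture(scope="session")
def comp(panel, spill):
    """Spillover estimate from one simulated bead acquisition."""
    return make_spillover_estimate(panel, spill, seed=101)


@pytest.fixture(scope="session")
def thresholds(tumor_tree, profiles, spill, comp, panel):
    """FMO thresholds shared by the gating-dependent tests."""
    return make_thresholds(tumor_tree, profiles, spill, comp, seed=101,
                           n_fmo=20_000, panel=panel)


@pytest.fixture(scope="session")
def labeled_control(profiles, presets, spill, comp, tumor_tree, thresholds,
                    panel):
    """A gated healthy sample (50k events) with ground truth."""
    sample = lf.simulate_sample(profiles, presets["control"], 50_000, spill,
                                202, panel=panel)
    labeled, pop_table = process_sample(sample, comp, tumor_tree, thresholds)
    return labeled, pop_table
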