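import pandas as pd
import pytest

from scfate import simgen


@pytest.fixture(scope="session")
def sim_config():
    return simgen.SimConfig(seed=1)


@pytest.fixture(scope="session")
def panel(sim_config):
    return simgen.generate_parents(sim_config)


@pytest.fixture(scope="session")
def panel_df(panel):
    """Marker panel in the markers-module schema."""
    return panel.markers.rename(
        columns={"ref": "allele_A", "alt": "allele_B"})[
        ["arm", "pos", "allele_A", "allele_B", "span"]]


@pytest.fixture(scope="session")
def repeat_mask(panel):
    return panel.repeat_mask()


def make_marker_table(positions, calls, arm="2L", spans=None, quals=None,
                      offspring_id="t"):
    """Hand-built MarkerTable for caller unit tests."""
    from scfate.markers import MarkerTable

    n = len(positions)
    spans = spans or [1] * n
    quals = quals or [99.0] * n
    df = pd.DataFrame({
        "arm": arm, "pos": positions,
        "allele_A": ["A"] * n, "allele_B": ["T"] * n,
        "span": spans, "call": calls, "depth": 20, "qual": quals,
        "b_frac": [1.0 if c == "B" else 0.0 for c in calls],
    })
    return MarkerTable(offspring_id, df)
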