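import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tapcall.quant import LOG2_IMPUTED, ProteinRecord, QuantMatrix, SampleDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_matrix(values, sample_ids, group_ids=None, scale_tag=LOG2_IMPUTED, observed=None, ibaq=None):
    """Build a QuantMatrix from a plain 2-D array for tests."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    group_ids = group_ids or [f"P{i}" for i in range(n)]
    proteins = [ProteinRecord(group_id=g, all_ids=(g,)) for g in group_ids]
    if observed is None:
        observed = np.isfinite(values)
    return QuantMatrix(
        proteins=proteins,
        samples=list(sample_ids),
        values=values,
        observed=np.asarray(observed, dtype=bool),
        ibaq=ibaq,
        scale_tag=scale_tag,
    )


def make_design(n_bait=2, n_ctrl=2, bait_condition="bait-TAP", control_condition="Ctrl-TAP", bait_name="BAIT"):
    rows = []
    for r in range(n_bait):
        rows.append(
            dict(sample_id=f"b{r+1}", condition=bait_condition, replicate=r + 1, role="bait", bait_name=bait_name)
        )
    for r in range(n_ctrl):
        rows.append(
            dict(sample_id=f"c{r+1}", condition=control_condition, replicate=r + 1, role="control", bait_name=None)
        )
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def tiny_design():
    return make_design(bait_name="PREY1")


@pytest.fixture
def tiny_matrix(tiny_design):
    """The exhaustively enumerable 3-protein, 2v2 instance (log2, fully observed)."""
    from tapcall.simulate import EXHAUSTIVE_FIXTURE as ex

    vals = np.array([ex["log2_values"][p] for p in ("PREY1", "PREY2", "PREY3")])
    return make_matrix(vals, ["b1", "b2", "c1", "c2"], group_ids=["PREY1", "PREY2", "PREY3"])
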