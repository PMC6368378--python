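import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from triomethyl import simulate as sim
from triomethyl.io import TrioDesign

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")


@pytest.fixture
def small_manifest():
    """60-probe / 12-gene synthetic manifest with rs and X/Y probes."""
    return sim.simulate_manifest(60, 12, n_rs=3, n_sex=4, seed=7)


@pytest.fixture
def small_cohort(small_manifest):
    """3-trio cohort over the small manifest, with planted events."""
    params = sim.TrioSimParams(
        n_trios=3, n_probes=60, n_genes=12, planted_fraction=0.05, seed=7
    )
    bm, truth = sim.simulate_trio_betas(params, small_manifest)
    return bm, truth, sim.trio_designs(3), params


@pytest.fixture
def one_trio():
    return TrioDesign("trio01", "child", "father", "mother")


@pytest.fixture
def tiny_beta(one_trio):
    """Hand-written beta matrix with known qualifying probes for one trio."""
    data = {
        # probe: (child, affected father, unaffected mother)
        "cg_hyper": (0.85, 0.90, 0.10),   # qualifies, affected_hyper
        "cg_hypo": (0.10, 0.15, 0.90),    # qualifies, affected_hypo
        "cg_pa_mid": (0.85, 0.50, 0.10),  # PA intermediate -> no
        "cg_all_hyper": (0.85, 0.90, 0.85),  # no state flip -> no
        "cg_mid": (0.5, 0.5, 0.5),        # all intermediate -> no
        "cg_missing": (0.85, np.nan, 0.10),  # missing member -> skipped
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=["child", "father", "mother"]
    ).rename_axis("probe_id")
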