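import numpy as np
import pandas as pd
import pytest

import bayesprog as bp
from bayesprog.network import Fragment, Network, NetworkEnsemble


@pytest.fixture(scope="session")
def default_cohort():
    cfg = bp.default_cohort_config(n_participants=300, seed=11)
    raw = bp.generate_cohort(cfg, seed=11)
    return cfg, raw


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    _, raw = default_cohort
    return bp.frame_from_raw(raw)


@pytest.fixture(scope="session")
def default_learner(default_frame):
    return bp.NetworkEnsembleLearner(n_networks=128, random_state=11).fit(
        default_frame)


def make_frame(columns: dict, roles: dict, snp_group=None) -> bp.CohortFrame:
    """Small helper: build a CohortFrame from plain arrays."""
    data = pd.DataFrame({k: np.asarray(v, dtype=float)
                         for k, v in columns.items()})
    data.index = [f"P{i:03d}" for i in range(len(data))]
    return bp.CohortFrame(data=data, roles=roles, snp_group=snp_group or {})


@pytest.fixture()
def chain_model():
    """Hand-specified a -> b@1 -> c@2 chain with known coefficients, plus a
    matching training frame drawn from exactly that model."""
    rng = np.random.default_rng(42)
    n = 400
    a = rng.normal(0.0, 1.0, n)
    b = 1.0 + 0.8 * a + rng.normal(0.0, 0.5, n)
    c = -0.5 + 1.5 * b + rng.normal(0.0, 0.7, n)
    frame = make_frame(
        {"a": a, "b@1": b, "c@2": c},
        {"a": "baseline", "b@1": "outcome", "c@2": "outcome"})
    frag_b = Fragment(child="b@1", parents=("a",), score=0.0, intercept=1.0,
                      coefficients=(0.8,), noise_sd=0.5)
    frag_c = Fragment(child="c@2", parents=("b@1",), score=0.0, intercept=-0.5,
                      coefficients=(1.5,), noise_sd=0.7)
    ensemble = NetworkEnsemble(
        networks=[Network(fragment_of={"b@1": frag_b, "c@2": frag_c})],
        trace=[0.0])
    return frame, ensemble
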