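"""Canonical simulation studies on planted-truth cohorts.

These studies are the package's own validation instruments: type-I
calibration of the perturbation tests on null cohorts, and structure/effect
recovery on the default cohort.  They are used by both the test suite and the
reproduction script, so their designs live here in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortFrame, split_column
from .network import NetworkEnsemble, NetworkEnsembleLearner
from .simulate import disease_state_perturbation, progression_perturbation
from .synthetic import (default_cohort_config, frame_from_raw, generate_cohort,
                        ground_truth_edges, null_cohort_config)

__all__ = ["aggregate_edge_frequency", "truth_edge_sets",
           "null_calibration_study", "recovery_study", "RecoveryReplicate"]


def aggregate_edge_frequency(ensemble: NetworkEnsemble,
                             frame: CohortFrame) -> dict[tuple[str, str], float]:
    """Edge frequencies with SNP coding columns collapsed onto their SNP.

    The three codings of one SNP are alternative representations of the same
    genetic parent; at most one appears per (child, network), so their
    frequencies add.
    """
    out: dict[tuple[str, str], float] = {}
    for (p, c), f in ensemble.edge_frequency.items():
        key = (frame.snp_group.get(p, p), c)
        out[key] = out.get(key, 0.0) + f
    return out


def truth_edge_sets(config) -> tuple[set, set]:
    """(planted level edges, all true dependencies incl. slope-induced)."""
    truth = ground_truth_edges(config)
    level = {(r.parent, r.child) for r in truth.itertuples() if r.kind == "level"}
    all_true = {(r.parent, r.child) for r in truth.itertuples()}
    return level, all_true


# ---------------------------------------------------------------------------
def null_calibration_study(
    n_replicates: int = 200,
    n_participants: int = 200,
    n_networks: int = 64,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Type-I error of both perturbation tests on null cohorts.

    Each replicate draws a cohort in which the candidate predictor has no
    path to the endpoint, learns an ensemble end-to-end, and runs the
    disease-state test (endpoint level at year 5) and the progression test
    (slope over years 4-7).  Returns per-replicate p-values.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for r, sub in enumerate(ss.spawn(n_replicates)):
        s = [int(x) for x in sub.generate_state(4) % (2 ** 31)]
        cfg = null_cohort_config(n_participants=n_participants, seed=s[0])
        frame = frame_from_raw(generate_cohort(cfg, seed=s[0]))
        learner = NetworkEnsembleLearner(
            n_networks=n_networks, random_state=s[1]).fit(frame)
        state = disease_state_perturbation(
            learner.ensemble_, frame, "x_pred", "y@5",
            n_permutations=n_permutations, seed=s[2])
        slope, _ = progression_perturbation(
            learner.ensemble_, frame, "x_pred", "y",
            n_permutations=n_permutations, seed=s[3])
        rows.append({"replicate": r, "p_state": state.p_value,
                     "p_slope": slope.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
@dataclass
class RecoveryReplicate:
    planted_min_frequency: float
    max_nonedge_frequency: float
    slope_p_value: float

    @property
    def success(self) -> bool:
        return (self.planted_min_frequency >= 0.5
                and self.max_nonedge_frequency <= 0.3
                and self.slope_p_value < 0.05)


def recovery_replicate(seed: int, n_participants: int = 300,
                       n_networks: int = 128,
                       n_permutations: int = 999) -> RecoveryReplicate:
    """One structure/effect recovery run on the default cohort."""
    ss = np.random.SeedSequence(seed)
    s = [int(x) for x in ss.generate_state(3) % (2 ** 31)]
    cfg = default_cohort_config(n_participants=n_participants, seed=s[0])
    frame = frame_from_raw(generate_cohort(cfg, seed=s[0]))
    learner = NetworkEnsembleLearner(
        n_networks=n_networks, random_state=s[1]).fit(frame)
    freq = aggregate_edge_frequency(learner.ensemble_, frame)
    level, all_true = truth_edge_sets(cfg)
    planted_min = min(freq.get(e, 0.0) for e in level)
    max_nonedge = max((f for e, f in freq.items() if e not in all_true),
                      default=0.0)
    slope, _ = progression_perturbation(
        learner.ensemble_, frame, "bst1", "moca",
        n_permutations=n_permutations, seed=s[2])
    return RecoveryReplicate(planted_min_frequency=planted_min,
                             max_nonedge_frequency=max_nonedge,
                             slope_p_value=slope.p_value)


def recovery_study(n_replicates: int = 20, seed: int = 0,
                   **kwargs) -> pd.DataFrame:
    """Replicated recovery study; one row per replicate."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for r, sub in enumerate(ss.spawn(n_replicates)):
        rep = recovery_replicate(int(sub.generate_state(1)[0] % (2 ** 31)),
                                 **kwargs)
        rows.append({"replicate": r,
                     "planted_min_frequency": rep.planted_min_frequency,
                     "max_nonedge_frequency": rep.max_nonedge_frequency,
                     "slope_p_value": rep.slope_p_value,
                     "success": rep.success})
    return pd.DataFrame(rows)
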