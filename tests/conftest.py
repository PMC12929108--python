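"""Shared fixtures.

``default_state_run`` executes the full window -> Fisher-z -> pooled
vectorization -> elbow/K-means path once per session on the default
12-subject synthetic cohort (master seed 20240401), because several tests
assert different properties of the same seeded end-to-end run.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from dfcstates import clustering, synthetic, windows

MASTER_SEED = 20240401


@dataclass
class DefaultRun:
    cohort: synthetic.SyntheticCohort
    z_list: list
    features: clustering.WindowFeatureMatrix
    truth: np.ndarray  # pooled majority ground-truth window labels
    elbow: clustering.ElbowCurve
    partition: clustering.StatePartition


def run_default_pipeline(seed_seq: np.random.SeedSequence) -> DefaultRun:
    cohort_seed = int(seed_seq.generate_state(1)[0] % (2**31))
    cohort = synthetic.default_cohort(seed=cohort_seed)
    spec = windows.WindowSpec(width=30, step=1)
    z_list, truths = [], []
    for subj in cohort.subjects:
        ts = windows.ROITimeSeries(subj.subject_id, subj.series, list(cohort.roi_labels))
        z_list.append(windows.fisher_z_series(windows.sliding_window_fc(ts, spec)))
        truths.append(synthetic.ground_truth_window_labels(subj.states, spec.width, spec.step))
    features = clustering.build_feature_matrix(z_list)
    elbow = clustering.select_k_elbow(
        features, k_range=range(2, 9), n_init=20,
        seed=seed_seq.spawn(1)[0], keep_partitions=True,
    )
    return DefaultRun(
        cohort=cohort,
        z_list=z_list,
        features=features,
        truth=np.concatenate(truths),
        elbow=elbow,
        partition=elbow.partitions[elbow.selected_k],
    )


@pytest.fixture(scope="session")
def default_state_run() -> DefaultRun:
    master = np.random.SeedSequence(MASTER_SEED)
    return run_default_pipeline(master.spawn(1)[0])
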