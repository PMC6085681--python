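"""Shared fixtures: one modest simulated study reused across test modules."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methpair import BetaMatrix, filter_probes
from methpair.simulate import SimulationConfig, simulate_dataset, cohort_features


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """Down-scaled study: 24 pairs, 2000 probes, spikes in every category."""
    return SimulationConfig(
        seed=7,
        n_probes=2000,
        n_dmp_hyper=60,
        n_dmp_hypo=40,
        feature_specs=cohort_features(n_unique_dmps=50),
        n_length_probes=15,
    )


@pytest.fixture(scope="session")
def study(study_config):
    return simulate_dataset(study_config)


@pytest.fixture(scope="session")
def filtered_matrix(study):
    matrix, _ = filter_probes(study.matrix, study.annotation.probes)
    return matrix


def paired_matrix_from_betas(disease: np.ndarray, normal: np.ndarray) -> BetaMatrix:
    """Build a minimal paired BetaMatrix from probes x patients β arrays."""
    disease = np.atleast_2d(np.asarray(disease, dtype=float))
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    n_probes, n_pat = disease.shape
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    cols, rows, data = [], [], []
    for j in range(n_pat):
        pat = f"P{j + 1:02d}"
        for tissue, suffix, grid in (("disease", "D", disease), ("normal", "N", normal)):
            cols.append(f"{pat}_{suffix}")
            rows.append({"patient": pat, "tissue": tissue, "batch": "B1"})
            data.append(grid[:, j])
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(probe_ids, name="probe_id"),
                          columns=cols)
    samples = pd.DataFrame(rows, index=pd.Index(cols, name="sample_id"))
    return BetaMatrix(values=values, samples=samples)
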