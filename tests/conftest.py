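"""Shared fixtures: toy atlas, reduced cohorts, and Monte-Carlo result caches.

The heavy Monte-Carlo simulations (null-calibration cohorts and
planted-effect cohorts) are computed once per session and shared by the
module-level property tests and the acceptance tests.  Cohort sizes are
reduced relative to the emulated study (10+10 or 12+12 subjects, 20 s at
128 Hz, a 12-region toy atlas with two regions per lobe group) so the
whole suite stays desk-scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plmnet.atlas import LOBE_GROUPS, LobePartition
from plmnet.model import LobeCentralityModel
from plmnet.pipeline import subject_lobe_table
from plmnet.signal import band_by_name
from plmnet.simulate import CohortSpec, generate_cohort

TOY_LABELS = tuple(f"r{i}" for i in range(12))

N_NULL_COHORTS = 600
N_PLANTED_COHORTS = 100


@pytest.fixture(scope="session")
def toy_partition() -> LobePartition:
    """12-region partition: two regions per lobe group, frontal = r0, r1."""
    return LobePartition({f"r{i}": g for i, g in enumerate(
        [g for g in LOBE_GROUPS for _ in range(2)])})


def reduced_spec(seed: int = 0, effect_size: float = 0.35, n: int = 10,
                 **overrides) -> CohortSpec:
    """A reduced-scale cohort spec on the toy atlas (alpha carrier)."""
    kwargs = dict(n_pd=n, n_hc=n, n_regions=12, region_labels=TOY_LABELS,
                  hub_regions=frozenset({"r0", "r1"}), fs=128.0,
                  duration_s=20.0, effect_size=effect_size, seed=seed)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def run_reduced_cohort(spec: CohortSpec, partition: LobePartition,
                       n_perm: int = 1999, all_pairs: bool = False):
    """Full pipeline (alpha band only) on a reduced cohort; returns Results."""
    cohort, signals = generate_cohort(spec)
    sig_map = dict(zip(cohort["subject_id"], signals))
    _, lobe = subject_lobe_table(sig_map, partition,
                                 bands=(band_by_name("alpha"),))
    model = LobeCentralityModel(lobe, cohort)
    return model.fit(n_perm=n_perm, seed=spec.seed, all_pairs=all_pairs)


@pytest.fixture(scope="session")
def null_pipeline_tests(toy_partition) -> pd.DataFrame:
    """Permutation-test tables from many null cohorts (effect_size = 0).

    One full pipeline run per cohort, 10+10 subjects; all p-values are
    null p-values by construction.
    """
    frames = []
    for seed in range(N_NULL_COHORTS):
        res = run_reduced_cohort(reduced_spec(seed=seed, effect_size=0.0),
                                 toy_partition)
        t = res.tests.copy()
        t["cohort"] = seed
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def planted_pipeline_results(toy_partition) -> list:
    """Fitted results from cohorts with the planted frontal effect (12+12)."""
    out = []
    for seed in range(N_PLANTED_COHORTS):
        out.append(run_reduced_cohort(reduced_spec(seed=seed, n=12),
                                      toy_partition, all_pairs=True))
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
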