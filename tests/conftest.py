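import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from tcrshare.io import Clone, RepertoireSample, StudyDesign
from tcrshare.simulate import (
    SimulationConfig,
    generate_human_cohorts,
    generate_mouse_study,
)


def make_sample(aa_counts: dict[str, int], **meta) -> RepertoireSample:
    """Sample from AA->count, with a distinct placeholder NT per AA."""
    meta.setdefault("sample_id", "s1")
    meta.setdefault("subject_id", meta["sample_id"])
    sample = RepertoireSample(**meta)
    for i, (aa, cnt) in enumerate(aa_counts.items()):
        sample.add_clone(
            Clone(junction_nt=f"NT{i}_{aa}", junction_aa=aa, duplicate_count=cnt)
        )
    return sample


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale stated world: 2 timepoints, 100 clones per sample."""
    return SimulationConfig(
        clones_per_sample=100,
        timepoints=2,
        chains=("alpha", "beta"),
        n_human_samples=2,
        human_clones_per_sample=80,
        stage_cases=(2, 2, 2, 2),
        sc_cells=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Mouse study + human cohorts generated once per session."""
    samples, truth = generate_mouse_study(small_config)
    bulk, staged, scores = generate_human_cohorts(small_config, truth)
    return {
        "config": small_config,
        "samples": samples,
        "truth": truth,
        "bulk": bulk,
        "staged": staged,
        "scores": scores,
    }


@pytest.fixture(scope="session")
def small_design(small_config):
    from tcrshare.simulate import default_design

    return default_design(small_config)


@pytest.fixture(scope="session")
def small_pools(small_world, small_design):
    """Per-subject pooled samples keyed by chain."""
    from tcrshare.io import pool_subject

    pools = {}
    for chain in small_world["config"].chains:
        pools[chain] = [
            pool_subject(
                [
                    s
                    for s in small_world["samples"]
                    if s.subject_id == sid and s.chain == chain
                ]
            )
            for sid, _ in small_design.subjects
        ]
    return pools


@pytest.fixture
def two_group_design():
    return StudyDesign(
        subjects=[("C1", "control"), ("C2", "control"), ("T1", "case"), ("T2", "case")],
        timepoints=[1, 2],
        young_timepoints=frozenset({1}),
        old_timepoints=frozenset({2}),
    )
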