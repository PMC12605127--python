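"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from cpfatools.lipid_library import LipidClass, LipidSpec
from cpfatools.conformer_engine import sample_conformers
from cpfatools.synthetic_data import SynthConfig, gen_pose_cloud


@pytest.fixture(scope="session")
def c18_ensembles():
    """Small C18 panel: SFA + MUFA/CpFA at three ring/bond positions."""
    specs = [LipidSpec(LipidClass.SFA, 18)]
    for cls in (LipidClass.MUFA, LipidClass.CpFA):
        for p in (2, 9, 17):
            specs.append(LipidSpec(cls, 18, p))
    return [sample_conformers(s, 25, seed=7) for s in specs]


@pytest.fixture(scope="session")
def two_cluster_cloud():
    """Planted 2-cluster pose cloud at separation/spread = 10."""
    cfg = SynthConfig(seed=13, poses_per_lipid=60)
    return cfg, gen_pose_cloud(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
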