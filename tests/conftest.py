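import numpy as np
import pytest

import cstcnet as c


@pytest.fixture(scope="session")
def toy_atlas():
    atlas, planted = c.make_toy_atlas()
    return atlas, planted


@pytest.fixture(scope="session")
def hc_voxel_cohort():
    """Three healthy-control 4-D sessions at default SNR, preprocessed."""
    cfg = c.SimulationConfig(n_per_group=3, groups=("HC",), seed=11)
    subjects, truth, atlas = c.generate_cohort(cfg)
    clean = []
    for sub in subjects:
        series, check = c.preprocess_subject(sub, atlas)
        assert check.keep
        clean.append(series)
    return cfg, subjects, clean, truth, atlas


@pytest.fixture(scope="session")
def roi_cohort():
    """30-per-group region-level cohort with the default planted effects,
    plus per-subject static and dFC-variability matrices."""
    cfg = c.SimulationConfig(n_per_group=30, seed=7)
    cohort = c.generate_roi_cohort(cfg)
    static, dyn_sd = [], []
    for sig in cohort.signals:
        x = sig[10:]
        static.append(c.static_network(x))
        dyn_sd.append(c.dfc_variability(c.dynamic_network(x)))
    return cohort, static, dyn_sd


def group_indices(cohort, group):
    phen = cohort.phenotype
    return phen.index[phen.group == group].tolist()
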