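import numpy as np
import pytest

import dispkin as dk


@pytest.fixture(scope="session")
def lev_constants():
    return dk.FixedConstants.for_drug("LEV")


@pytest.fixture(scope="session")
def brv_constants():
    return dk.FixedConstants.for_drug("BRV")


@pytest.fixture(scope="session")
def lev_putamen_params(lev_constants):
    """Population-median LEV putamen parameters."""
    return dk.default_truth("LEV")["putamen"]


@pytest.fixture(scope="session")
def noiseless_lev_dataset():
    """Noise-free LEV subject at the default study design (all regions)."""
    design = dk.StudyDesign(noise_scale=0.0)
    return dk.generate_subject(design, subject="clean-lev")


@pytest.fixture(scope="session")
def noiseless_brv_dataset():
    design = dk.StudyDesign(drug="BRV", dose_mg=100.0, noise_scale=0.0)
    return dk.generate_subject(design, subject="clean-brv")


@pytest.fixture(scope="session")
def noisy_lev_dataset():
    """One LEV subject at the default noise level (fixed seed)."""
    design = dk.StudyDesign(seed=11)
    return dk.generate_subject(design, subject="noisy-lev")


@pytest.fixture(scope="session")
def lev_5p_fit(noiseless_lev_dataset):
    return dk.fit_joint(noiseless_lev_dataset, "putamen", config="5p")
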