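"""Shared fixtures: phantoms and derived images are expensive, so they are
built once per session and reused read-only."""

import numpy as np
import pytest

from tractroi.dwi_model import fit_tensor, mean_b0, resample_isotropic
from tractroi.phantom import PhantomSpec, generate_phantom, make_t1w_contrast
from tractroi.roi_methods import RaterModel, tract_neighborhood
from tractroi.skeleton import skeletonize_fa


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_model="none", t1w_offset_mm=2.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    data, truth = generate_phantom(noiseless_spec)
    return data, truth


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_spec, noiseless_phantom):
    """1 mm resampled data, tensor fit, b0 map, T1W contrast, skeleton."""
    data, truth = noiseless_phantom
    data_1mm = resample_isotropic(data, 1.0)
    tensors = fit_tensor(data_1mm)
    return {
        "spec": noiseless_spec,
        "truth": truth,
        "data_1mm": data_1mm,
        "tensors": tensors,
        "b0_map": mean_b0(data_1mm),
        "t1w": make_t1w_contrast(truth, noiseless_spec),
        "skeleton": skeletonize_fa(tensors.fa_map),
        "neighborhood": tract_neighborhood(truth),
    }


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject with the default Rician noise, processed end to end."""
    from tractroi.pipeline import StudyConfig, process_subject, subject_spec

    cfg = StudyConfig()
    spec = subject_spec(cfg, 0)
    return process_subject(spec)


@pytest.fixture
def exact_rater():
    """A rater with no jitter: fully deterministic selections."""
    return RaterModel("exact", start_slice_jitter_sd=0.0,
                      inplane_jitter_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A reduced but complete study: 4 subjects, 2 raters, repeat-scan arm."""
    from tractroi.pipeline import StudyConfig, run_study
    from tractroi.tracking import TrackingConfig

    cfg = StudyConfig(
        n_subjects=4,
        n_repeat_scans=3,
        tracking=TrackingConfig(n_streamlines=300),
        master_seed=202,
    )
    return run_study(cfg)
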