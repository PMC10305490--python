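import numpy as np
import pytest

from rdnacn.io import DepthTrack
from rdnacn.refmodel import default_reference
from rdnacn.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """A 30-sample noisy cohort with default parameters, shared session-wide."""
    outdir = tmp_path_factory.mktemp("cohort_default")
    config = SimConfig(n_samples=30, seed=42)
    samples, truth = simulate_cohort(config, outdir)
    return outdir, config, samples, truth


@pytest.fixture(scope="session")
def noisefree_cohort(tmp_path_factory):
    """Deterministic-depth cohort: flat profile, no artifact boost, no noise."""
    outdir = tmp_path_factory.mktemp("cohort_noisefree")
    config = SimConfig(
        n_samples=6,
        seed=7,
        background_depth_dispersion=float("inf"),
        profile_smoothness=0.0,
        artifact_boost=1.0,
    )
    samples, truth = simulate_cohort(config, outdir)
    return outdir, config, samples, truth


def make_track(depths, ref_name="rDNA", start=1):
    return DepthTrack(ref_name, start, np.asarray(depths, dtype=np.int64))
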