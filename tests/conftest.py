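import numpy as np
import pytest

from isodrr import (DetectorSpec, RenderParams, ValidationRunConfig,
                    default_projections, generate_head_phantom, run_validation)

# test-profile detector: 256 px at 1.2 mm pitch spans the same ~30.7 cm
# field as the full-resolution 1024 px / 0.3 mm receptor
TEST_DET = DetectorSpec(n_u=256, n_v=256, pitch_mm=1.2)


@pytest.fixture(scope="session")
def head_phantom():
    """Default synthetic head phantom and its landmark catalogue."""
    return generate_head_phantom(seed=0)


@pytest.fixture(scope="session")
def study_projections():
    return {s.name: s for s in default_projections()}


def make_config(out_dir=None, **overrides) -> ValidationRunConfig:
    defaults = dict(
        seed=0,
        detector=TEST_DET,
        render=RenderParams(),
        observer_sigma_mm=0.0,
        observer_round_to_mm=False,
        out_dir=out_dir,
    )
    defaults.update(overrides)
    return ValidationRunConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """One full pipeline run: phantom -> three DRRs -> six distances ->
    zero-noise observers -> agreement stats, with artifacts on disk."""
    out = tmp_path_factory.mktemp("validation")
    return run_validation(make_config(out_dir=out)), out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
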