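import numpy as np
import pytest

import fbcwf as F
from fbcwf.pipeline import run_synthetic_study

# The canonical synthetic benchmark: L=32, 16 defocus groups spanning
# 1-4 um at 300 kV / Cs 2 mm, SNR 0.1, Lorentzian colored noise.  One
# fixed seed; heavy results are session fixtures shared by the tests.
STUDY_SEED = 11


def study_config(n_images: int) -> F.SimulationConfig:
    return F.SimulationConfig(L=32, n_images=n_images, n_defocus_groups=16,
                              snr=0.1, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def spec16():
    return F.compute_basis(16)


@pytest.fixture(scope="session")
def spec32():
    return F.compute_basis(32)


@pytest.fixture(scope="session")
def spec64():
    return F.compute_basis(64)


@pytest.fixture(scope="session")
def templates32(spec32):
    cfg = F.SimulationConfig(L=32, seed=STUDY_SEED)
    return F.make_templates(32, 4, seed=STUDY_SEED,
                            pixel_size_A=cfg.pixel_size_A)


@pytest.fixture(scope="session")
def study_1e3(spec32):
    return run_synthetic_study(study_config(1_000), spec=spec32, n_eval=200)


@pytest.fixture(scope="session")
def study_1e4(spec32):
    return run_synthetic_study(study_config(10_000), spec=spec32, n_eval=500)


def random_symmetric_coeffs(spec, rng, n=1, scale=None):
    """Random conjugate-symmetric coefficient stacks (real-image valued)."""
    a = rng.standard_normal((n, spec.size)) + 1j * rng.standard_normal((n, spec.size))
    if scale is not None:
        a *= scale[None, :]
    return F.basis.enforce_conjugate_symmetry(a, spec)
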