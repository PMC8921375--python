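import numpy as np
import pytest

from bprm.phantom import make_phantom_pair


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3, 2 mm phantom pair with a few bullae and air traps."""
    return make_phantom_pair(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                             n_bullae=3, n_traps=2, seed=7)


@pytest.fixture(scope="session")
def exp_side_truth(small_phantom):
    """Expiratory left/right side labels derived from the truth lung mask."""
    _, _, truth = small_phantom
    lt = truth.lung_truth["expiratory"]
    side = np.zeros(lt.shape, dtype=np.uint8)
    _, _, xx = np.indices(lt.shape)
    side[lt & (xx < lt.shape[2] // 2)] = 1
    side[lt & (xx >= lt.shape[2] // 2)] = 2
    return side


@pytest.fixture(scope="session")
def registered_phantom(small_phantom, exp_side_truth):
    """CPD-registered phantom pair (uses truth masks for the lungs)."""
    from bprm.registration import register_pair

    insp, exp, truth = small_phantom
    return register_pair(insp, exp, truth.side_truth, exp_side_truth)


def expiratory_sides(truth):
    lt = truth.lung_truth["expiratory"]
    side = np.zeros(lt.shape, dtype=np.uint8)
    _, _, xx = np.indices(lt.shape)
    side[lt & (xx < lt.shape[2] // 2)] = 1
    side[lt & (xx >= lt.shape[2] // 2)] = 2
    return side


@pytest.fixture(scope="session")
def study_phantom():
    """The full study-size phantom: 96^3 voxels at 1.5 mm."""
    return make_phantom_pair(shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5),
                             n_bullae=6, n_traps=4, seed=3)


@pytest.fixture(scope="session")
def study_registration(study_phantom):
    from bprm.registration import register_pair

    insp, exp, truth = study_phantom
    return register_pair(insp, exp, truth.side_truth, expiratory_sides(truth))
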