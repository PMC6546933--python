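import numpy as np
import pytest

import vepasl as v


@pytest.fixture(scope="session")
def protocol():
    return v.build_default_protocol()


@pytest.fixture(scope="session")
def geometry():
    return v.ArteryGeometry()


@pytest.fixture(scope="session")
def matrix(geometry):
    return v.build_encoding_matrix(geometry)


@pytest.fixture(scope="session")
def constants():
    return v.KineticConstants()


@pytest.fixture(scope="session")
def small_spec():
    """Phantom on a reduced grid with a proportionally smaller lesion."""
    return v.PhantomSpec(
        shape=(24, 24, 12),
        lesion_center_mm=(-20.0, 5.0, 0.0),
        lesion_radius_mm=12.0,
        peri_lesion_margin_mm=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return v.generate_truth(small_spec)


@pytest.fixture(scope="session")
def small_noiseless_series(small_truth, protocol, matrix, constants):
    return v.synthesize_series(
        small_truth, protocol, matrix, constants, noise_sd=0.0, seed=11
    )


def pure_single_artery_mask(truth, artery_index=None, min_share=0.99):
    """Gray-matter voxels supplied (almost) exclusively by one artery."""
    total = truth.total_cbf()
    share = np.where(total > 0, truth.cbf / np.maximum(total, 1e-12), 0.0)
    gm = truth.gm_pv > 0.5
    if artery_index is None:
        return gm & (share.max(axis=0) >= min_share)
    return gm & (share[artery_index] >= min_share)
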