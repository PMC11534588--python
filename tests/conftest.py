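import numpy as np
import pytest

import slicesr as S


@pytest.fixture(scope="session")
def flair_phantom():
    """One default FLAIR-like 96^3 phantom shared across tests."""
    return S.generate_phantom(S.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def normalized_phantom(flair_phantom):
    vol, scale = S.normalize_intensity(flair_phantom.volume,
                                       flair_phantom.brain_mask)
    return vol, scale


@pytest.fixture(scope="session")
def lr_axial(normalized_phantom):
    """Axial (slice axis 2) acquisition of the normalized phantom."""
    vol, _ = normalized_phantom
    acq = S.AcquisitionModel(2, S.SliceProfile())
    return S.apply_acquisition(vol, acq), acq


@pytest.fixture(scope="session")
def patch_pairs(normalized_phantom, lr_axial, flair_phantom):
    vol, _ = normalized_phantom
    lr, acq = lr_axial
    spec = S.ExtractionSpec(n_patches=8, seed=3)
    return S.extract_pairs(vol, lr, acq, flair_phantom.brain_mask, spec,
                           volume_id="fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
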