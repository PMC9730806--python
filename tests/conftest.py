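import numpy as np
import pytest

from mscascade.volumes import CasePair, LesionMask, Volume3D


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(data, dtype=np.float32)
    aff = np.diag(list(spacing) + [1.0])
    return Volume3D(data=data, spacing=np.asarray(spacing), affine=aff)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    aff = np.diag(list(spacing) + [1.0])
    return LesionMask(data=np.asarray(data, dtype=np.uint8),
                      spacing=np.asarray(spacing), affine=aff)


def make_case(baseline, followup, gt=None, spacing=(1.0, 1.0, 1.0)):
    return CasePair(
        baseline=make_volume(baseline, spacing),
        followup=make_volume(followup, spacing),
        gt_new_lesions=None if gt is None else make_mask(gt, spacing),
        case_id="test",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    data = rng.gamma(3.0, 20.0, size=(24, 24, 24)).astype(np.float32)
    return make_volume(data)
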