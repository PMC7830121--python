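import numpy as np
import pytest

from ldpgen.fixtures import LesionSceneSpec, ellipsoid_scene
from ldpgen.image_io import BinaryMask


@pytest.fixture
def small_mask():
    """Deterministic 6x5x4 binary mask with mixed content."""
    rng = np.random.default_rng(7)
    data = (rng.random((6, 5, 4)) < 0.4).astype(np.uint8)
    return BinaryMask(data=data, spacing=(1.0, 1.0, 1.0), source_name="small.nii")


@pytest.fixture
def three_scenes(tmp_path):
    """Three seeded synthetic lesion scenes written as NIfTI, mild to severe."""
    from ldpgen.fixtures import write_scene_nifti

    specs = [
        LesionSceneSpec(shape=(40, 40, 40), n_lesions=4, radius_mm=(2.0, 2.0, 2.0), seed=21),
        LesionSceneSpec(shape=(40, 40, 40), n_lesions=10, radius_mm=(2.5, 2.5, 2.5), seed=22),
        LesionSceneSpec(shape=(40, 40, 40), n_lesions=20, radius_mm=(3.0, 3.0, 3.0), seed=23),
    ]
    paths = []
    for i, spec in enumerate(specs, 1):
        p = tmp_path / f"scene{i}.nii"
        write_scene_nifti(ellipsoid_scene(spec), p)
        paths.append(str(p))
    return paths
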