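import numpy as np
import pytest

from histodense import preprocess, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def easy_seg_scene(i: int, size: int = 64) -> synthdata.SceneTruth:
    """Well-separated dark nuclei on a light field: the easy segmentation
    corpus used by the desk-scale training checks."""
    spec = synthdata.benign_like_patch_spec(
        size,
        n_nuclei=(3, 6),
        radius_range=(5.0, 8.0),
        overlap_allowance=-0.2,
        seed=100 + i,
    )
    return synthdata.generate_scene(spec)


def seg_training_set(n: int = 64, size: int = 64):
    xs, ys, counts = [], [], []
    for i in range(n):
        t = easy_seg_scene(i, size)
        xs.append(preprocess.gaussian_denoise(t.image, 1.0))
        ys.append(t.instance_mask > 0)
        counts.append(t.n_nuclei)
    return np.stack(xs), np.stack(ys), np.array(counts)


def classification_corpus(n: int = 150, size: int = 64):
    """Alternating benign-like / malignant-like patch scenes."""
    xs, ys = [], []
    for i in range(n):
        if i % 2 == 0:
            t = synthdata.generate_scene(synthdata.benign_like_patch_spec(size, seed=500 + i))
            ys.append(0)
        else:
            t = synthdata.generate_scene(synthdata.malignant_like_patch_spec(size, seed=500 + i))
            ys.append(1)
        xs.append(t.image)
    return np.stack(xs) / 255.0, np.array(ys)
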