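import numpy as np
import pytest

from stromaratio.tissue_model import BACKGROUND, STROMA, TUMOR, ClassMap, SlideMeta


def make_classmap(labels: np.ndarray, mpp: float = 100.0, slide_id: str = "t") -> ClassMap:
    labels = np.asarray(labels, dtype=np.uint8)
    meta = SlideMeta(
        slide_id=slide_id, mpp=mpp, width_px=labels.shape[1], height_px=labels.shape[0]
    )
    return ClassMap(labels=labels, meta=meta)


@pytest.fixture
def uniform_tumor_map() -> ClassMap:
    return make_classmap(np.full((64, 64), TUMOR), mpp=100.0)


@pytest.fixture
def uniform_stroma_map() -> ClassMap:
    return make_classmap(np.full((64, 64), STROMA), mpp=100.0)


@pytest.fixture
def toy_survival():
    """Two groups with hand-computable log-rank statistic."""
    return {
        "a": (np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])),
        "b": (np.array([4.0, 5.0, 6.0]), np.array([1, 1, 1])),
    }
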