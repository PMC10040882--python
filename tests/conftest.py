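import numpy as np
import pytest

from cellconcord import (
    AnnotationSet,
    CellLabel,
    CellRecord,
    LayoutConfig,
    REAL_LABELS,
    generate_layout,
)


def make_set(
    centers,
    labels=None,
    source_id="src",
    roi_id="roi",
    scores=None,
):
    """Annotation set from bare coordinates, for terse test construction."""
    cells = []
    for i, (x, y) in enumerate(centers):
        label = labels[i] if labels is not None else CellLabel.TUMOR
        if isinstance(label, str):
            label = CellLabel(label)
        score = scores[i] if scores is not None else None
        cells.append(
            CellRecord.from_point(float(x), float(y), label, source_id, score=score)
        )
    return AnnotationSet(roi_id=roi_id, source_id=source_id, cells=cells)


def random_set(rng, n, extent=500.0, source_id="src", roi_id="roi", scores=False):
    centers = rng.uniform(0, extent, size=(n, 2))
    labels = [REAL_LABELS[k] for k in rng.integers(0, 3, size=n)]
    s = rng.uniform(0, 1, size=n) if scores else None
    return make_set(centers, labels, source_id=source_id, roi_id=roi_id, scores=s)


@pytest.fixture(scope="session")
def small_truth():
    """A modest hard-core layout shared by several test modules."""
    cfg = LayoutConfig(n_cells=600, seed=7, roi_width=1200.0, roi_height=1200.0)
    return generate_layout(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230501)
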