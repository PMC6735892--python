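import numpy as np
import pytest

from cfskit.simulate import ImageSimParams, gen_foci_images


def match_truth_to_labels(truths, mask):
    """Map each generated nucleus to its segmentation label by centroid."""
    cents = mask.centroids
    out = {}
    for t in truths:
        best = min(
            cents,
            key=lambda cid: (cents[cid][0] - t.center[0]) ** 2
            + (cents[cid][1] - t.center[1]) ** 2,
        )
        out[t.cell_id] = best
    return out


@pytest.fixture(scope="session")
def small_image_set():
    """A modest QIBC scene shared by segmentation/gating/foci tests."""
    params = ImageSimParams(
        n_cells=120,
        image_shape=(1000, 1000),
        micronucleus_prob=0.2,
        seed=42,
    )
    images, truths = gen_foci_images(params)
    return params, images, truths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
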