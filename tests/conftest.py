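import numpy as np
import pytest

from abruptcut import boundary, channels, maskprep, synthetic


@pytest.fixture(scope="session")
def disk_mask():
    """Rasterized disk lesion, R=60, centered in a 161x161 grid."""
    yy, xx = np.mgrid[0:161, 0:161]
    return maskprep.LesionMask((yy - 80) ** 2 + (xx - 80) ** 2 <= 60**2)


@pytest.fixture(scope="session")
def disk_path(disk_mask):
    return boundary.trace_boundary(disk_mask)


@pytest.fixture(scope="session")
def disk_centroid(disk_mask):
    return boundary.centroid(disk_mask)


@pytest.fixture(scope="session")
def default_sample():
    """One benign synthetic lesion at default settings."""
    return synthetic.generate_lesion(synthetic.SyntheticLesionSpec(seed=3))


@pytest.fixture(scope="session")
def default_stack(default_sample):
    return channels.extract_channels(default_sample.image)


@pytest.fixture(scope="session")
def worked_example():
    """The 4-row x 5-col intensity array of the printed GLCM example."""
    return np.array(
        [
            [0, 1, 1, 3, 0],
            [0, 1, 2, 3, 0],
            [1, 2, 3, 2, 0],
            [1, 1, 2, 2, 0],
        ]
    )


def brute_force_glcm(img, region, dx, dy, levels, literal=False):
    """Independent O(H*W) pair-enumeration oracle for GLCM counts.

    ``dy`` shifts rows, ``dx`` shifts columns, mirroring compute_glcm. In
    literal mode the image is zeroed outside the region over its bounding
    box and all in-box pairs count.
    """
    img = np.asarray(img)
    region = np.asarray(region).astype(bool)
    rows, cols = np.nonzero(region)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = img[r0:r1, c0:c1].copy()
    subm = region[r0:r1, c0:c1]
    if literal:
        sub = sub * subm
    counts = np.zeros((levels, levels), dtype=np.int64)
    H, W = sub.shape
    for p in range(H):
        for q in range(W):
            p2, q2 = p + dy, q + dx
            if not (0 <= p2 < H and 0 <= q2 < W):
                continue
            if not literal and not (subm[p, q] and subm[p2, q2]):
                continue
            counts[sub[p, q], sub[p2, q2]] += 1
    return counts
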