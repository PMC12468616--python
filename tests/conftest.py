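import numpy as np
import pytest

from nengrade.synthetic import IHCPatchSpec, gen_ihc_patch


@pytest.fixture(scope="session")
def ihc_patch_30pct():
    """One seeded synthetic IHC patch: 700 nuclei, 30% DAB-positive."""
    spec = IHCPatchSpec(n_cells=700, positive_fraction=0.3, seed=11)
    img, truth = gen_ihc_patch(spec)
    return img, truth, spec


@pytest.fixture(scope="session")
def ihc_patch_negative():
    """Synthetic patch with 700 nuclei and no DAB signal at all."""
    spec = IHCPatchSpec(n_cells=700, positive_fraction=0.0, seed=7)
    img, truth = gen_ihc_patch(spec)
    return img, truth, spec


def planted_disk_mask(n_disks, size=1536, radius_range=(8, 20), seed=0):
    """Binary mask of well-separated planted disks plus their truth table."""
    from skimage.draw import disk as draw_disk

    rng = np.random.default_rng(seed)
    n_side = int(np.ceil(np.sqrt(n_disks / 0.9)))
    pitch = size / n_side
    assert pitch >= 4 * radius_range[0], "disks would violate the separation guarantee"
    mask = np.zeros((size, size), dtype=bool)
    cells = rng.choice(n_side * n_side, n_disks, replace=False)
    radii = rng.integers(radius_range[0], radius_range[1] + 1, n_disks)
    centers = []
    for cell, r in zip(cells, radii):
        row = (cell // n_side + 0.5) * pitch
        col = (cell % n_side + 0.5) * pitch
        rr, cc = draw_disk((row, col), int(r), shape=mask.shape)
        mask[rr, cc] = True
        centers.append((row, col, int(r)))
    return mask, centers
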