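"""Otsu partition, erosion profiles, structure classification, watershed edit."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from lungmech.core import AIR_LABELS, INTERMEDIATE, PROXIMAL, TERMINAL, VESSEL
from lungmech.segmentation import (
    ClassifierConfig,
    classify_structures,
    erosion_profile,
    otsu_partition,
    survival_depth,
    vessel_partition,
    watershed_edit,
)


def ball_mask(r, pad=3):
    n = int(2 * (r + pad)) + 1
    c = r + pad
    z, y, x = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r * r


def cyl_mask(r, L, pad=3):
    n = int(2 * (r + pad)) + 1
    c = r + pad
    z, y, x = np.ogrid[: L + 2 * pad, :n, :n]
    return ((y - c) ** 2 + (x - c) ** 2 <= r * r) & (z >= pad) & (z < pad + L)


# -- Otsu ---------------------------------------------------------------------


def test_otsu_two_level_image():
    vol = np.ones((8, 8, 8))
    vol[:4] = 0.0
    mask = otsu_partition(vol)
    assert mask[:4].all() and not mask[4:].any()


def test_otsu_constant_volume_rejected():
    with pytest.raises(ValueError):
        otsu_partition(np.ones((8, 8, 8)))


def test_otsu_equals_brute_force_variance_sweep(iso_phantom):
    """The chosen threshold maximizes between-class variance over a 256-bin
    histogram sweep (independent oracle)."""
    from skimage.filters import threshold_otsu

    _, series, _ = iso_phantom
    vol = series[0]
    thr = threshold_otsu(vol)
    counts, edges = np.histogram(vol, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    w = counts / counts.sum()
    best, best_var = None, -1.0
    for k in range(1, 256):
        w0, w1 = w[:k].sum(), w[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (w[:k] * centers[:k]).sum() / w0
        m1 = (w[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best = var, edges[k]
    assert abs(thr - best) < (edges[1] - edges[0]) * 2


def test_otsu_recovers_phantom_air_mask(iso_phantom_clean, dice_fn):
    _, series, gt = iso_phantom_clean
    mask = otsu_partition(series[0])
    assert dice_fn(mask, np.isin(gt.labels[0], AIR_LABELS)) >= 0.98


def test_vessel_partition_recovers_vessel_tree(iso_phantom_clean, dice_fn):
    _, series, gt = iso_phantom_clean
    mask = vessel_partition(series[0])
    assert dice_fn(mask, gt.labels[0] == VESSEL) >= 0.9


# -- erosion profiles ---------------------------------------------------------


def test_one_voxel_sheet_vanishes_after_one_step():
    sheet = np.zeros((10, 10, 10), bool)
    sheet[5] = True
    prof = erosion_profile(sheet)
    assert prof.depth == 1
    assert prof.volumes[1] == 0


@pytest.mark.parametrize("r", [5, 8, 12])
def test_erosion_survival_depth_matches_cityblock_edt(r):
    mask = ball_mask(r)
    prof = erosion_profile(mask)
    assert abs(prof.depth - survival_depth(mask)) <= 1


def test_cylinder_passes_and_sphere_fails_quasi_cylinder_test():
    """A long cylinder decays linearly under erosion and is elongated; an
    equal-radius sphere decays cubically with elongation ~ 1."""
    pc = erosion_profile(cyl_mask(20, 95))
    ps = erosion_profile(ball_mask(20))
    assert pc.rel_rmse < ps.rel_rmse
    assert pc.is_quasi_cylindrical()
    assert not ps.is_quasi_cylindrical()
    assert ps.elongation == pytest.approx(1.0, abs=0.15)


# -- classification -----------------------------------------------------------


def test_classify_cylinder_with_attached_spheres(dice_fn):
    """Bronchus-like tube -> proximal; attached alveolus-like bumps -> terminal."""
    zz, yy, xx = np.ogrid[:100, :60, :60]
    cyl = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2) & (zz > -1)
    sph = np.zeros((100, 60, 60), bool)
    for cz, cy, cx in [(25, 30, 52), (50, 52, 30), (75, 30, 8)]:
        sph |= (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= 5**2
    seg = classify_structures(cyl | sph)
    assert dice_fn(seg.labels == PROXIMAL, cyl) >= 0.9
    assert dice_fn(seg.labels == TERMINAL, sph & ~cyl) >= 0.9


def test_classify_phantom_tree(iso_segmentation, iso_phantom, dice_fn):
    """Trunk proximal, acinar duct intermediate, alveolar clusters terminal."""
    _, _, gt = iso_phantom
    seg = iso_segmentation
    for cls in (PROXIMAL, INTERMEDIATE, TERMINAL):
        assert dice_fn(seg.labels == cls, gt.labels[0] == cls) >= 0.85, cls


def test_single_isolated_sphere_is_terminal():
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        seg = classify_structures(ball_mask(8))
    assert set(np.unique(seg.labels)) == {0, TERMINAL}
    assert any("quasi-cylinder" in str(w.message) for w in rec)


def test_classification_is_a_partition(iso_segmentation):
    seg = iso_segmentation
    n_omega = int(seg.omega.sum())
    total = sum(int((seg.labels == c).sum()) for c in (PROXIMAL, INTERMEDIATE, TERMINAL))
    assert total == n_omega


def test_classification_commutes_with_90deg_rotation(iso_phantom):
    _, series, _ = iso_phantom
    mask = otsu_partition(series[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        l1 = classify_structures(mask).labels
        l2 = classify_structures(np.rot90(mask, axes=(1, 2))).labels
    assert np.array_equal(np.rot90(l1, axes=(1, 2)), l2)


# -- watershed editing --------------------------------------------------------


def two_touching_balls():
    z, y, x = np.ogrid[:40, :24, :24]
    a = (z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 64
    b = (z - 27) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 64
    return a | b


def test_watershed_splits_touching_spheres_at_neck():
    mask = two_touching_balls()
    markers = np.zeros(mask.shape, np.int32)
    markers[12, 12, 12] = 1
    markers[27, 12, 12] = 2
    out = watershed_edit(mask, markers)
    assert set(np.unique(out[mask])) == {1, 2}
    # the split plane lies near the geometric neck (z ~ 19-20)
    za = np.argwhere(out == 1)[:, 0]
    zb = np.argwhere(out == 2)[:, 0]
    assert za.max() <= 21 and zb.min() >= 18


def test_watershed_zero_markers_is_identity():
    mask = two_touching_balls()
    out = watershed_edit(mask, np.zeros(mask.shape, np.int32))
    assert np.array_equal(out.astype(bool), mask)


def test_watershed_marker_outside_omega_rejected():
    mask = two_touching_balls()
    markers = np.zeros(mask.shape, np.int32)
    markers[0, 0, 0] = 1
    with pytest.raises(ValueError, match=r"\(0, 0, 0\)"):
        watershed_edit(mask, markers)


def test_classifier_config_is_respected():
    # a lenient terminal cutoff reclassifies the alveolus-sized sphere
    zz, yy, xx = np.ogrid[:100, :60, :60]
    cyl = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2) & (zz > -1)
    seg = classify_structures(cyl, ClassifierConfig(prox_margin=3.0))
    assert (seg.labels == PROXIMAL).sum() > 0
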