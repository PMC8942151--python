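"""Phantom generator: determinism, analytic ground truth, displacement oracles."""

import numpy as np
import pytest

from lungmech.core import AIR_LABELS, INTERMEDIATE, TERMINAL
from lungmech.phantom import (
    AcinarCluster,
    Branch,
    DeformationSpec,
    PhantomSpec,
    analytic_displacement,
    demo_spec,
    generate_phantom,
    realize_geometry,
)


def test_identical_seed_gives_bit_identical_series():
    s1, g1 = generate_phantom(demo_spec("isotropic", n_steps=4, seed=7))
    s2, g2 = generate_phantom(demo_spec("isotropic", n_steps=4, seed=7))
    assert np.array_equal(s1.data, s2.data)
    assert all(np.array_equal(a, b) for a, b in zip(g1.labels, g2.labels))


def test_different_seed_changes_noise_only():
    s1, _ = generate_phantom(demo_spec("isotropic", n_steps=3, seed=1))
    s2, _ = generate_phantom(demo_spec("isotropic", n_steps=3, seed=2))
    assert not np.array_equal(s1.data, s2.data)


def test_zero_waveform_is_identity():
    """A breath with zero inflation leaves every phase identical and all
    ground-truth displacement fields zero."""
    spec = demo_spec("isotropic", n_steps=3, noise_sigma=0.0)
    spec.deformation.waveform = lambda p: np.zeros_like(np.asarray(p, dtype=float))
    series, gt = generate_phantom(spec)
    assert np.array_equal(series[0], series[1])
    assert np.array_equal(series[0], series[2])
    for f in gt.displacement_fields:
        assert np.all(f.vectors == 0)


def test_amplitude_zero_rejected():
    with pytest.raises(ValueError, match="amplitude"):
        DeformationSpec(amplitude=0.0)


def test_isotropic_volume_follows_cubic_scaling():
    spec = demo_spec("isotropic", n_steps=5, amplitude=0.08)
    _, gt = generate_phantom(spec)
    w = spec.deformation.w(np.arange(5))
    expected = gt.V_series[0] * (1 + 0.08 * w) ** 3
    np.testing.assert_allclose(gt.V_series, expected, rtol=1e-12)


def test_isotropic_analytic_sv_exponent_is_two_thirds():
    spec = demo_spec("isotropic", n_steps=6)
    _, gt = generate_phantom(spec)
    slope = np.polyfit(np.log(gt.V_series), np.log(gt.S_series), 1)[0]
    assert abs(slope - 2.0 / 3.0) < 1e-10


@pytest.fixture(scope="module")
def sphere_cluster_phantom():
    """Terminal units of radii 4-6 vx at off-lattice centres (voxelization
    fixture; fractional centres average out lattice-count fluctuations)."""
    s = 6.0
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size=s,
        acinar_clusters=[
            AcinarCluster((31.3 * s, 31.7 * s, 32.2 * s), 6 * s, 4, 16 * s),
            AcinarCluster((11.5 * s, 11.5 * s, 51.5 * s), 4 * s, 3, 6.2 * s),
        ],
        deformation=DeformationSpec("isotropic", 0.05, 3),
        noise_sigma=0.0,
    )
    return spec, generate_phantom(spec)[1]


def test_voxelized_label_volume_within_3pct(sphere_cluster_phantom):
    """Center-inclusion voxel counts track the analytic volume (radii >= 4)."""
    spec, gt = sphere_cluster_phantom
    for t in (0, 1):
        vox = (gt.labels[t] == TERMINAL).sum() * spec.voxel_size**3
        assert abs(vox / gt.V_series[t] - 1) < 0.03


def test_marching_cubes_surface_within_5pct():
    """Mesh area of voxelized labels vs analytic sphere surfaces (radii 6 vx)."""
    from lungmech.biomech import surface_area_mc

    s = 6.0
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size=s,
        acinar_clusters=[AcinarCluster((32 * s, 32 * s, 32 * s), 6 * s, 4, 16 * s)],
        deformation=DeformationSpec("isotropic", 0.05, 3),
        noise_sigma=0.0,
    )
    _, gt = generate_phantom(spec)
    area = surface_area_mc(gt.labels[0] == TERMINAL, s)
    assert abs(area / gt.S_series[0] - 1) < 0.05


def test_recruitment_event_adds_connected_component(recruit_phantom):
    from scipy import ndimage

    spec, _, gt = recruit_phantom
    events = sorted(s for _, s in spec.deformation.recruitment_events)
    full = np.ones((3, 3, 3), bool)

    def ncomp(t):
        return ndimage.label(np.isin(gt.labels[t], AIR_LABELS), structure=full)[1]

    first = events[0]
    assert ncomp(first) == ncomp(first - 1) + 1
    assert gt.recruited_ids == {u for u, _ in spec.deformation.recruitment_events}


def test_recruitment_vs_series_reaches_n_of_one(recruit_phantom):
    _, _, gt = recruit_phantom
    slope = np.polyfit(np.log(gt.V_series), np.log(gt.S_series), 1)[0]
    assert abs(slope - 1.0) < 1e-6


def test_analytic_displacement_isotropic_fixed_point_and_scaling():
    spec = demo_spec("isotropic", n_steps=5, amplitude=0.1)
    geom = realize_geometry(spec)
    c = geom.center
    # peak of the raised cosine at the middle step: w = 1, so u = eps*(x-c)
    peak = 2
    assert spec.deformation.w(peak) == pytest.approx(1.0)
    res = analytic_displacement(spec.deformation, [c], peak, geom)
    np.testing.assert_allclose(res.displacement, 0.0, atol=1e-12)
    res = analytic_displacement(spec.deformation, [c + (10, 0, 0)], peak, geom)
    np.testing.assert_allclose(res.displacement, [[1.0, 0.0, 0.0]], atol=1e-12)
    np.testing.assert_allclose(res.divergence, 0.3, atol=1e-12)


@pytest.mark.parametrize("mode", ["ductal_dominant", "alveolar_dominant"])
def test_analytic_divergence_matches_numerical_jacobian(mode):
    """Divergence of the analytic field equals the finite-difference trace of
    its Jacobian at interior points of the deforming structures."""
    spec = demo_spec(mode, n_steps=5)
    geom = realize_geometry(spec)
    d = spec.deformation
    if mode == "ductal_dominant":
        cyl = next(c for c in geom.cylinders if c.kind == "intermediate")
        pts = np.asarray([cyl.p0 + cyl.axis * (cyl.length / 2) + (0.0, 2.0, 1.0)])
    else:
        sp = geom.spheres[0]
        pts = np.asarray([sp.center + (1.0, 0.5, -0.5)])
    step = 2
    res = analytic_displacement(d, pts, step, geom)
    eps = 1e-6
    div_fd = 0.0
    for a in range(3):
        dp = np.zeros(3)
        dp[a] = eps
        up = analytic_displacement(d, pts + dp, step, geom).displacement
        um = analytic_displacement(d, pts - dp, step, geom).displacement
        div_fd += (up[0, a] - um[0, a]) / (2 * eps)
    assert abs(div_fd - res.divergence[0]) < 1e-6


def test_structure_out_of_grid_rejected_by_name():
    s = 6.0
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size=s,
        airway_tree=[Branch((50 * s, 32 * s, 32 * s), (1, 0, 0), 20 * s, 8 * s, "proximal")],
        deformation=DeformationSpec("isotropic", 0.05, 3),
    )
    with pytest.raises(ValueError, match="proximal"):
        generate_phantom(spec)


def test_unknown_mode_and_custom_rendering_rejected():
    with pytest.raises(ValueError, match="unknown deformation mode"):
        DeformationSpec(mode="sideways")
    spec = demo_spec("isotropic", n_steps=3)
    spec.deformation.mode = "custom_analytic"
    with pytest.raises(ValueError, match="custom_analytic"):
        generate_phantom(spec)


def test_spec_round_trips_through_dict():
    spec = demo_spec("recruitment", n_steps=6, seed=3)
    spec2 = PhantomSpec.from_dict(spec.to_dict())
    s1, _ = generate_phantom(spec)
    s2, _ = generate_phantom(spec2)
    assert np.array_equal(s1.data, s2.data)


def test_air_darker_than_tissue_by_five_sigma(iso_phantom_clean):
    spec, series, gt = iso_phantom_clean
    img = series[0]
    air = np.isin(gt.labels[0], AIR_LABELS)
    interior = air & (gt.labels[0] == gt.labels[0])  # all air voxels
    tissue = gt.labels[0] == 0
    gap = img[tissue].mean() - img[interior].mean()
    assert gap >= 5 * spec.noise_sigma
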