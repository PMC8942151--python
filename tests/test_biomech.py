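"""MLS divergence, curvature, volume/surface change, ROI aggregation."""

import numpy as np
import pytest

from lungmech.biomech import (
    MlsKernel,
    StrainMap,
    divergence_flux,
    mean_curvature,
    mls_divergence,
    roi_series,
    surface_area_div,
    surface_area_mc,
    surface_change,
    volume_change,
)
from lungmech.core import INTERMEDIATE, TERMINAL


@pytest.fixture(scope="module")
def kernel():
    return MlsKernel()


@pytest.fixture(scope="module")
def ball36():
    z, y, x = np.mgrid[:36, :36, :36].astype(float)
    mask = (z - 18) ** 2 + (y - 18) ** 2 + (x - 18) ** 2 <= 12**2
    return mask, (z, y, x)


# -- MLS divergence -----------------------------------------------------------


def test_constant_field_has_zero_divergence(ball36, kernel):
    mask, _ = ball36
    sm = mls_divergence(np.full((3, 36, 36, 36), 2.5), mask, kernel)
    assert np.abs(sm.values[sm.mask]).max() < 1e-12


def test_affine_field_divergence_exact_to_1e9(kernel):
    """Linear consistency: trace(A) recovered exactly on every well-conditioned
    voxel, including the boundary."""
    z, y, x = np.mgrid[:48, :48, :48].astype(float)
    omega = (z - 24) ** 2 + (y - 24) ** 2 + (x - 24) ** 2 <= 15**2
    A = np.array([[0.05, 0.01, 0.0], [0.02, 0.04, 0.0], [0.0, 0.01, 0.03]])
    u = np.einsum("ab,bzyx->azyx", A, np.stack([z, y, x])) + 0.3
    sm = mls_divergence(u, omega, kernel)
    assert sm.mask.sum() > 0.99 * omega.sum()
    assert np.abs(sm.values[sm.mask] - 0.12).max() < 1e-9


def test_radial_shell_divergence_matches_closed_form(kernel):
    """u_r = a r² on a thick spherical shell: ∇·u = 4 a r."""
    N, c, a = 48, 23.5, 0.002
    z, y, x = np.mgrid[:N, :N, :N].astype(float)
    r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
    shell = (r >= 8) & (r <= 16)
    u = np.stack([(z - c), (y - c), (x - c)]) * a * r[None]
    sm = mls_divergence(u, shell, kernel)
    interior = shell & (r >= 10) & (r <= 14) & sm.mask
    rel = np.abs(sm.values[interior] - 4 * a * r[interior]) / (4 * a * r[interior])
    assert rel.max() < 0.05


def test_empty_omega_rejected(kernel):
    with pytest.raises(ValueError):
        mls_divergence(np.zeros((3, 8, 8, 8)), np.zeros((8, 8, 8), bool), kernel)


def test_divergence_theorem_flux_consistency(ball36, kernel):
    """Σ_Ω ∇·u agrees with the outward surface flux Σ_∂Ω u·n̂ within 5%."""
    mask, (z, y, x) = ball36
    u = np.stack([(z - 18), (y - 18), (x - 18)]) * 0.04
    sm = mls_divergence(u, mask, kernel)
    vol_sum = float(sm.values[sm.mask].mean()) * int(mask.sum())
    flux = divergence_flux(u, mask)
    assert abs(vol_sum - flux) / abs(flux) < 0.05


# -- volume change ------------------------------------------------------------


def test_zero_strain_keeps_volume(ball36):
    mask, _ = ball36
    sm = StrainMap(np.zeros(mask.shape), mask.copy())
    dv, V = volume_change(sm, mask, voxel_volume=2.0)
    assert dv == 0.0
    assert V == mask.sum() * 2.0


def test_phantom_volume_tracks_cubic_law(iso_phantom, kernel):
    """Eq.-7 volume from analytic fields vs the analytic series (first-order
    in ε, so compare at 5%)."""
    spec, _, gt = iso_phantom
    om = np.isin(gt.labels[0], (INTERMEDIATE, TERMINAL))
    for t in (1, 2):
        sm = mls_divergence(gt.displacement_fields[t].vectors.astype(float), om, kernel)
        _, V = volume_change(sm, om, spec.voxel_size**3)
        assert abs(V / gt.V_series[t] - 1) < 0.05


def test_volume_change_matches_warped_label_count(iso_phantom, kernel):
    """Independent oracle: direct voxel count of the deformed labels."""
    spec, _, gt = iso_phantom
    om0 = np.isin(gt.labels[0], (INTERMEDIATE, TERMINAL))
    t = 2
    sm = mls_divergence(gt.displacement_fields[t].vectors.astype(float), om0, kernel)
    _, V = volume_change(sm, om0, 1.0)
    count_t = int(np.isin(gt.labels[t], (INTERMEDIATE, TERMINAL)).sum())
    assert abs(V - count_t) / count_t < 0.05


# -- curvature ----------------------------------------------------------------


def test_curvature_of_ball_is_two_over_R(ball36):
    mask, _ = ball36
    cf = mean_curvature(mask)
    assert abs(cf.band_mean() - 2.0 / 12.0) / (2.0 / 12.0) < 0.15


def test_curvature_of_half_space_is_zero():
    half = np.zeros((32, 32, 32), bool)
    half[:, :16, :] = True
    cf = mean_curvature(half)
    assert abs(cf.band_mean()) < 0.02


def test_curvature_of_cylinder_wall_is_one_over_R():
    z, y, x = np.mgrid[:48, :48, :48].astype(float)
    cyl = (y - 23.5) ** 2 + (x - 23.5) ** 2 <= 10**2
    cf = mean_curvature(cyl)
    lateral = cf.band & (z >= 10) & (z < 38)
    h = float(cf.values[lateral].mean())
    assert abs(h - 0.1) / 0.1 < 0.15


def test_curvature_needs_a_boundary():
    with pytest.raises(ValueError):
        mean_curvature(np.ones((8, 8, 8), bool))


def test_divergence_identity_surface_area(ball36):
    mask, _ = ball36
    cf = mean_curvature(mask)
    assert abs(surface_area_div(cf, mask) / (4 * np.pi * 144) - 1) < 0.05
    assert abs(surface_area_mc(mask) / (4 * np.pi * 144) - 1) < 0.05


# -- surface change -----------------------------------------------------------


def test_zero_field_zero_surface_change(ball36, kernel):
    mask, _ = ball36
    cf = mean_curvature(mask)
    assert surface_change(np.zeros((3, 36, 36, 36)), mask, cf, kernel) == 0.0


def test_ball_radial_growth_matches_8piRdR(ball36, kernel):
    """The calibration oracle: ball R = 12 under δR = 0.5."""
    mask, (z, y, x) = ball36
    R, dR = 12.0, 0.5
    u = np.stack([(z - 18), (y - 18), (x - 18)]) * (dR / R)
    cf = mean_curvature(mask)
    ds = surface_change(u, mask, cf, kernel)
    assert abs(ds / (8 * np.pi * R * dR) - 1) < 0.10


def test_isotropic_phantom_surface_tracks_v_two_thirds(iso_phantom, kernel):
    spec, _, gt = iso_phantom
    om = np.isin(gt.labels[0], (INTERMEDIATE, TERMINAL))
    cf = mean_curvature(om)
    S0 = surface_area_div(cf, om)
    V0 = float(om.sum())
    for t in (1, 2):
        u = gt.displacement_fields[t].vectors.astype(float)
        ds = surface_change(u, om, cf, kernel)
        sm = mls_divergence(u, om, kernel)
        _, V = volume_change(sm, om, 1.0)
        assert abs((S0 + ds) / S0 - (V / V0) ** (2.0 / 3.0)) < 0.05


# -- ROI aggregation ----------------------------------------------------------


def test_uniform_strain_roi_means(ball36):
    mask, _ = ball36
    smap = StrainMap(np.full(mask.shape, 0.09), mask.copy())
    out = roi_series([smap], mask, {"a": ((18, 18, 18), 6), "b": ((18, 18, 24), 5)})
    for r in out:
        assert r.mean_strain[0] == pytest.approx(0.09)
        assert r.sd_strain[0] == 0.0


def test_two_compartment_strains_recovered(kernel):
    """Left/right halves inflating at different rates: per-side ROI means
    recover the imposed 3ε-scale strains."""
    z, y, x = np.mgrid[:48, :48, :48].astype(float)
    left = (z - 14) ** 2 + (y - 24) ** 2 + (x - 24) ** 2 <= 9**2
    right = (z - 34) ** 2 + (y - 24) ** 2 + (x - 24) ** 2 <= 9**2
    omega = left | right
    u = np.zeros((3, 48, 48, 48))
    for mask, c, eps in ((left, 14.0, 0.05), (right, 34.0, 0.15)):
        for a, (g, cc) in enumerate(zip((z, y, x), (c, 24.0, 24.0))):
            u[a][mask] = eps * (g[mask] - cc)
    smap = mls_divergence(u, omega, kernel)
    out = roi_series([smap], omega, {"L": ((14, 24, 24), 10), "R": ((34, 24, 24), 10)})
    assert abs(out[0].mean_strain[0] / 0.15 - 1) < 0.10
    assert abs(out[1].mean_strain[0] / 0.45 - 1) < 0.10


def test_roi_outside_omega_rejected(ball36):
    mask, _ = ball36
    smap = StrainMap(np.zeros(mask.shape), mask.copy())
    with pytest.raises(ValueError, match="far"):
        roi_series([smap], mask, {"far": ((2, 2, 2), 1)})


def test_delta_v_additive_over_partition(ball36, kernel):
    mask, (z, y, x) = ball36
    u = np.stack([(z - 18), (y - 18), (x - 18)]) * 0.03
    smap = mls_divergence(u, mask, kernel)
    dv_all, _ = volume_change(smap, mask)
    halves = [mask & (z < 18), mask & (z >= 18)]
    dv_parts = sum(volume_change(smap, hm)[0] for hm in halves)
    assert abs(dv_parts - dv_all) / abs(dv_all) < 0.02


def test_pure_inflation_strain_nonnegative(iso_phantom, kernel):
    spec, _, gt = iso_phantom
    om = np.isin(gt.labels[0], (INTERMEDIATE, TERMINAL))
    peak = 2
    sm = mls_divergence(gt.displacement_fields[peak].vectors.astype(float), om, kernel)
    assert sm.values[sm.mask].mean() > 0
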