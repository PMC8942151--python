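"""Pairwise non-rigid registration and Lagrangian field composition.

The displacement between consecutive phase volumes is parametrized by a
cubic B-spline control grid and estimated by minimizing

    E(c) = SSD(fixed, moving ∘ (id + u_c))  +  λ · Σ ‖Δu_c‖²

(sum of squared intensity differences plus a Laplacian smoothness penalty on
the dense field), coarse-to-fine over an image pyramid, with gradient
descent and Armijo backtracking.  The convention is *pull-back*: the
returned field u maps a material point at x in the fixed frame (step n−1)
to x + u(x) in the moving frame (step n), so consecutive pairwise fields
compose forward in time.

Pairwise fields u*(x; (n−1)Δt, nΔt) are composed into Lagrangian fields
u(x; 0, nΔt) by the recursion

    r((n−1)Δt) = x + u(x; 0, (n−1)Δt)
    u(x; 0, nΔt) = u(x; 0, (n−1)Δt) + u*(r((n−1)Δt); (n−1)Δt, nΔt)

with trilinear interpolation of u* at the advected position; advected points
leaving the domain are clamped and masked.  Registration quality is assessed
by comparing the composed field with one direct first-to-last registration:

    ε_u(x) = (u(x; 0, T) − u*(x; 0, T)) / max|u*(x; 0, T)| .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DisplacementField


@dataclass
class BsplineModel:
    """Registration settings (all lengths in voxels of the finest level).

    spacing : control-point spacing of the cubic B-spline grid (≥ 4).
    lam : weight of the Laplacian regularization term.
    levels : multiresolution pyramid depth (level 0 = full resolution).
    max_iter : gradient-descent iterations per level.
    step_tol : relative objective decrease below which a level stops.
    """

    spacing: int = 8
    lam: float = 0.02
    levels: int = 3
    max_iter: int = 40
    step_tol: float = 1e-4
    order: int = 3

    def __post_init__(self) -> None:
        if self.spacing < 4:
            raise ValueError("control-point spacing must be >= 4 voxels")
        if self.lam < 0:
            raise ValueError("regularization weight must be >= 0")
        if self.order != 3:
            raise ValueError("only cubic B-splines are supported")


@dataclass
class RegistrationError:
    """Eq.-style composed-vs-direct error map ε_u and its summary."""

    values: np.ndarray  # per-voxel |ε_u| (dimensionless)
    mean: float
    max: float


# ---------------------------------------------------------------------------
# B-spline machinery
# ---------------------------------------------------------------------------


def _bspline3(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1.0
    m2 = (at >= 1.0) & (at < 2.0)
    out[m1] = 2.0 / 3.0 - at[m1] ** 2 + 0.5 * at[m1] ** 3
    out[m2] = (2.0 - at[m2]) ** 3 / 6.0
    return out


def _basis_matrix(dim: int, spacing: float) -> np.ndarray:
    """Dense (dim × K) cubic B-spline basis sampled at voxel positions."""
    K = int(np.ceil((dim - 1) / spacing)) + 3
    pos = (np.arange(K) - 1) * spacing  # one control point before the volume
    v = np.arange(dim, dtype=float)
    return _bspline3((v[:, None] - pos[None, :]) / spacing)


def _field_from_coeffs(coeffs: np.ndarray, B: list[np.ndarray]) -> np.ndarray:
    """Dense (3, Z, Y, X) field from (3, Kz, Ky, Kx) control coefficients."""
    u = coeffs
    for axis, Bax in enumerate(B):
        u = np.moveaxis(np.tensordot(Bax, u, axes=(1, axis + 1)), 0, axis + 1)
    return u


def _project_to_coeffs(g: np.ndarray, B: list[np.ndarray]) -> np.ndarray:
    """Adjoint of :func:`_field_from_coeffs` (B^T applied per axis)."""
    c = g
    for axis, Bax in enumerate(B):
        c = np.moveaxis(np.tensordot(Bax.T, c, axes=(1, axis + 1)), 0, axis + 1)
    return c


def _warp(volume: np.ndarray, u: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``volume`` at x + u(x) (trilinear, edge-clamped)."""
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in volume.shape), indexing="ij")
    coords = [g + ui for g, ui in zip(grids, u)]
    return ndimage.map_coordinates(volume, coords, order=order, mode="nearest")


def warp_volume(volume: np.ndarray, field: DisplacementField, order: int = 1) -> np.ndarray:
    """Warp a volume (or, with order=0, a label grid) by a displacement field."""
    return _warp(np.asarray(volume, dtype=float if order > 0 else np.float32),
                 field.vectors, order=order)


def _downsample(vol: np.ndarray) -> np.ndarray:
    sm = ndimage.gaussian_filter(vol, 1.0)
    return sm[tuple(slice(None, None, 2) for _ in range(3))]


def _upsample_field(u: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    factors = [s / c for s, c in zip(shape, u.shape[1:])]
    out = np.stack([ndimage.zoom(u[a], factors, order=1, mode="nearest") for a in range(3)])
    for a in range(3):
        out[a] *= factors[a]
    return out


# ---------------------------------------------------------------------------
# pairwise registration
# ---------------------------------------------------------------------------


def _solve_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    u_base: np.ndarray,
    model: BsplineModel,
    spacing: float,
) -> np.ndarray:
    """Minimize SSD + λ‖Δu‖² over B-spline coefficients at one level."""
    shape = fixed.shape
    B = [_basis_matrix(s, spacing) for s in shape]
    coeffs = np.zeros((3,) + tuple(b.shape[1] for b in B))
    grad_m = np.stack(np.gradient(moving))
    nvox = fixed.size

    def objective(c):
        u = u_base + _field_from_coeffs(c, B)
        warped = _warp(moving, u)
        res = warped - fixed
        ssd = float(np.mean(res**2))
        reg = 0.0
        if model.lam > 0:
            reg = sum(float(np.mean(ndimage.laplace(u[a]) ** 2)) for a in range(3))
        return ssd + model.lam * reg, u, res

    E, u, res = objective(coeffs)
    step = None
    for _ in range(model.max_iter):
        # dE/du: SSD term needs ∇moving sampled at the warped positions
        grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
        coords = [g + ui for g, ui in zip(grids, u)]
        g_dense = np.stack([
            2.0 * res * ndimage.map_coordinates(grad_m[a], coords, order=1, mode="nearest")
            for a in range(3)
        ]) / nvox
        if model.lam > 0:
            for a in range(3):
                g_dense[a] += 2.0 * model.lam * ndimage.laplace(ndimage.laplace(u[a])) / u[a].size
        g = _project_to_coeffs(g_dense, B)
        gnorm2 = float(np.sum(g**2))
        if gnorm2 == 0:
            break
        if step is None:
            # first step sized to move coefficients by ~0.5 voxel at most
            step = 0.5 / max(np.sqrt(g.max() ** 2 + g.min() ** 2), 1e-12)
        # Armijo backtracking (objective is monotone non-increasing)
        accepted = False
        for _ls in range(12):
            E_new, u_new, res_new = objective(coeffs - step * g)
            if E_new <= E - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        coeffs = coeffs - step * g
        rel = (E - E_new) / max(E, 1e-300)
        E, u, res = E_new, u_new, res_new
        step *= 1.6  # allow the line search to grow again
        if rel < model.step_tol:
            break
    return u


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    model: BsplineModel | None = None,
    from_step: int = 0,
    to_step: int | None = None,
    kind: str = "pairwise",
) -> DisplacementField:
    """Estimate the dense displacement field mapping ``fixed`` onto ``moving``.

    Returns u such that moving(x + u(x)) ≈ fixed(x): u advects material
    points of the fixed frame into the moving frame.
    """
    model = model or BsplineModel()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving volumes must share a grid")
    if not (np.all(np.isfinite(fixed)) and np.all(np.isfinite(moving))):
        raise ValueError("volumes contain non-finite voxels")
    # joint intensity normalization so λ is scale-free
    scale = max(float(np.ptp(fixed)), float(np.ptp(moving)), 1e-12)
    off = min(float(fixed.min()), float(moving.min()))
    fixed = (fixed - off) / scale
    moving = (moving - off) / scale

    pyramids = [(fixed, moving)]
    for _ in range(model.levels - 1):
        f, m = pyramids[-1]
        if min(f.shape) < 2 * model.spacing:
            break
        pyramids.append((_downsample(f), _downsample(m)))

    u = np.zeros((3,) + pyramids[-1][0].shape)
    for li, (f, m) in enumerate(reversed(pyramids)):
        if u.shape[1:] != f.shape:
            u = _upsample_field(u, f.shape)
        u = _solve_level(f, m, u, model, float(model.spacing))
    if to_step is None:
        to_step = from_step + 1
    return DisplacementField(u, kind=kind, from_step=from_step, to_step=to_step)


def register_series(
    volumes,
    model: BsplineModel | None = None,
) -> list[DisplacementField]:
    """Pairwise registrations between each step and the previous one."""
    vols = volumes.data if hasattr(volumes, "data") else np.asarray(volumes)
    return [
        register_pair(vols[n - 1], vols[n], model, from_step=n - 1)
        for n in range(1, len(vols))
    ]


# ---------------------------------------------------------------------------
# Lagrangian composition and the error metric
# ---------------------------------------------------------------------------


def compose_lagrangian(pairwise: list[DisplacementField]) -> list[DisplacementField]:
    """Compose consecutive pairwise fields into Lagrangian fields u(x; 0, n).

    Returns one field per step n = 1..N.  Each recursion step interpolates
    the next pairwise field at the advected position r = x + u(x; 0, n−1)
    (trilinear); advected positions outside the grid are clamped to the
    boundary and the voxel is masked out.
    """
    if not pairwise:
        raise ValueError("no pairwise fields to compose")
    shape = pairwise[0].grid_shape
    for i, f in enumerate(pairwise):
        if f.grid_shape != shape:
            raise ValueError("pairwise fields must share a grid")
        if f.from_step != pairwise[0].from_step + i:
            raise ValueError("pairwise fields must be consecutive")
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    u = np.zeros((3,) + shape)
    mask = np.ones(shape, dtype=bool)
    out = []
    for n, f in enumerate(pairwise, start=1):
        coords = [g + ui for g, ui in zip(grids, u)]
        inside = np.ones(shape, dtype=bool)
        for a, c in enumerate(coords):
            inside &= (c >= 0) & (c <= shape[a] - 1)
        inc = np.stack([
            ndimage.map_coordinates(f.vectors[a], coords, order=1, mode="nearest")
            for a in range(3)
        ])
        u = u + inc
        mask = mask & inside
        out.append(DisplacementField(u.copy(), kind="lagrangian", from_step=0,
                                     to_step=n, mask=mask.copy(),
                                     voxel_size=f.voxel_size))
    return out


def registration_error(
    composed: DisplacementField,
    direct: DisplacementField,
    omega: np.ndarray | None = None,
) -> RegistrationError:
    """ε_u = (composed − direct) / max|direct|, summarized over Ω.

    ``direct`` is a single registration of the last frame against the first
    one; the normalization uses the maximum vector magnitude of the direct
    field.  The error is reported as a per-voxel vector magnitude.
    """
    if composed.grid_shape != direct.grid_shape:
        raise ValueError("fields must share a grid")
    denom = float(direct.magnitude().max())
    if denom == 0:
        raise ValueError("direct field is identically zero: ε_u undefined")
    eps = np.sqrt(np.sum((composed.vectors - direct.vectors) ** 2, axis=0)) / denom
    sel = np.asarray(omega, dtype=bool) if omega is not None else np.ones(eps.shape, bool)
    sel = sel & composed.mask & direct.mask
    return RegistrationError(eps, float(eps[sel].mean()), float(eps[sel].max()))
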