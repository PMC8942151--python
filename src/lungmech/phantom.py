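"""Synthetic 4D micro-CT lung phantom with analytic ground truth.

The phantom emulates the morphology seen in high-resolution lung CT at the
acinar scale: a quasi-cylindrical bronchial tree (proximal trunk feeding
intermediate acinar ducts), clusters of quasi-spherical terminal airspaces
(alveoli), and a vascular tree, deformed over a breath by analytic fields.
Because the geometry is implicit (spheres and capped cylinders) the volume
and internal surface area of the airspaces, the Lagrangian displacement
field, and the voxel labels are all known exactly at every phase, so every
downstream stage of the pipeline can be validated without external data.

Greyscale model: tissue = 1.0, air = 0.0, blood (vessels) = 0.8, with
additive Gaussian noise.  Phase-contrast edge enhancement is deliberately
not simulated; the pipeline must work on plain attenuation-like contrast.

Deformation regimes
-------------------
``isotropic``
    Uniform scaling of the whole scene about the grid centre — the
    balloon-like limit where S ∝ V^(2/3).
``ductal_dominant``
    Radial expansion of the intermediate (acinar-duct) cylinders only;
    drives the surface–volume exponent below 2/3.
``alveolar_dominant``
    Expansion of the terminal units about their own centres with the ducts
    fixed; drives the exponent above 2/3.
``recruitment``
    No deformation; previously absent (gasless) terminal units appear at
    prescribed phase steps, the n ≈ 1 limit.

All unit spheres are kept pairwise disjoint and clear of the ducts so that
the analytic V/S of the airspace union is the plain sum of the primitive
formulas (cylinder surface includes both end caps).
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .core import (
    BACKGROUND,
    INTERMEDIATE,
    PROXIMAL,
    TERMINAL,
    VESSEL,
    DisplacementField,
    VolumeSeries,
    as_points,
)

TISSUE_GREY = 1.0
AIR_GREY = 0.0
VESSEL_GREY = 0.8

MODES = ("isotropic", "ductal_dominant", "alveolar_dominant", "recruitment", "custom_analytic")


def raised_cosine(p: float | np.ndarray) -> float | np.ndarray:
    """Default breath waveform: inhale half / exhale half of one breath.

    ``p`` is the phase fraction in [0, 1]; returns the inflation fraction
    w with w(0) = 0, w(0.5) = 1, w(1) = 0.
    """
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(p, dtype=float)))


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Branch:
    """One quasi-cylindrical branch segment, coordinates in µm (z, y, x)."""

    start: tuple[float, float, float]
    direction: tuple[float, float, float]
    length: float
    radius: float
    kind: str = "intermediate"  # 'proximal' or 'intermediate'

    def __post_init__(self) -> None:
        if self.kind not in ("proximal", "intermediate"):
            raise ValueError(f"branch kind must be proximal|intermediate, got {self.kind!r}")
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("branch length and radius must be positive")


@dataclass(frozen=True)
class AcinarCluster:
    """A cluster of identical terminal units on a spherical shell.

    Units are placed deterministically on a Fibonacci sphere of radius
    ``shell_radius`` (µm) around ``center``; they must remain pairwise
    disjoint, which is validated at generation time.
    """

    center: tuple[float, float, float]
    unit_radius: float
    n_units: int
    shell_radius: float | None = None

    def __post_init__(self) -> None:
        if self.unit_radius <= 0 or self.n_units < 1:
            raise ValueError("cluster needs positive unit radius and >= 1 unit")


@dataclass
class DeformationSpec:
    """Analytic deformation applied over one breath.

    amplitude is the peak fractional linear expansion ε (dimensionless);
    the scale factor at phase step s is λ(s) = 1 + ε·w(s/(n_steps-1)).
    ``recruitment_events`` lists (unit_id, appearance_step) pairs; a unit is
    present from its appearance step onward (units without an event are
    present from step 0).
    """

    mode: str = "isotropic"
    amplitude: float = 0.05
    n_steps: int = 10
    waveform: Callable[[np.ndarray], np.ndarray] | None = None
    recruitment_events: list[tuple[int, int]] = dc_field(default_factory=list)
    breath_duration: float = 0.76  # seconds, nominal breath length
    displacement_fn: Callable | None = None  # custom_analytic only

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown deformation mode {self.mode!r}")
        if not (0.0 < self.amplitude <= 0.5):
            raise ValueError("amplitude must lie in (0, 0.5]")
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3")

    def w(self, step: int | np.ndarray) -> np.ndarray:
        wf = self.waveform if self.waveform is not None else raised_cosine
        p = np.asarray(step, dtype=float) / (self.n_steps - 1)
        return np.asarray(wf(p), dtype=float)

    def scale(self, step: int) -> float:
        """λ(step) = 1 + ε·w."""
        if self.mode == "recruitment":
            return 1.0
        return 1.0 + self.amplitude * float(self.w(step))


@dataclass
class PhantomSpec:
    """Full description of a synthetic 4D acquisition (lengths in µm)."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 6.0
    airway_tree: list[Branch] = dc_field(default_factory=list)
    acinar_clusters: list[AcinarCluster] = dc_field(default_factory=list)
    vessel_tree: list[Branch] = dc_field(default_factory=list)
    deformation: DeformationSpec = dc_field(default_factory=DeformationSpec)
    noise_sigma: float = 0.05
    seed: int = 0
    supersample: int = 2  # 1 disables anti-aliased rendering

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 32 along every axis")
        min_r = min(
            [b.radius for b in list(self.airway_tree) + list(self.vessel_tree)]
            + [c.unit_radius for c in self.acinar_clusters],
            default=2 * self.voxel_size,
        )
        if min_r < 2 * self.voxel_size:
            raise ValueError("all radii must be >= 2 voxels")

    # -- flat serialization (config-file interface) -------------------------
    def to_dict(self) -> dict:
        def branch(b: Branch) -> dict:
            return {
                "start": list(b.start), "direction": list(b.direction),
                "length": b.length, "radius": b.radius, "kind": b.kind,
            }

        d = self.deformation
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size": self.voxel_size,
            "airway_tree": [branch(b) for b in self.airway_tree],
            "vessel_tree": [branch(b) for b in self.vessel_tree],
            "acinar_clusters": [
                {"center": list(c.center), "unit_radius": c.unit_radius,
                 "n_units": c.n_units, "shell_radius": c.shell_radius}
                for c in self.acinar_clusters
            ],
            "deformation": {
                "mode": d.mode, "amplitude": d.amplitude, "n_steps": d.n_steps,
                "recruitment_events": [list(e) for e in d.recruitment_events],
                "breath_duration": d.breath_duration,
            },
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "supersample": self.supersample,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        dd = d.get("deformation", {})
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            voxel_size=float(d["voxel_size"]),
            airway_tree=[Branch(tuple(b["start"]), tuple(b["direction"]),
                                b["length"], b["radius"], b.get("kind", "intermediate"))
                         for b in d.get("airway_tree", [])],
            vessel_tree=[Branch(tuple(b["start"]), tuple(b["direction"]),
                                b["length"], b["radius"], b.get("kind", "intermediate"))
                         for b in d.get("vessel_tree", [])],
            acinar_clusters=[AcinarCluster(tuple(c["center"]), c["unit_radius"],
                                           c["n_units"], c.get("shell_radius"))
                             for c in d.get("acinar_clusters", [])],
            deformation=DeformationSpec(
                mode=dd.get("mode", "isotropic"),
                amplitude=dd.get("amplitude", 0.05),
                n_steps=dd.get("n_steps", 10),
                recruitment_events=[tuple(e) for e in dd.get("recruitment_events", [])],
                breath_duration=dd.get("breath_duration", 0.76),
            ),
            noise_sigma=float(d.get("noise_sigma", 0.05)),
            seed=int(d.get("seed", 0)),
            supersample=int(d.get("supersample", 2)),
        )


@dataclass
class GroundTruth:
    """Exact per-step reference data for the generated series.

    V_series / S_series are the analytic volume (µm³) and internal surface
    area (µm²) of the *peripheral* airspace (intermediate ducts + terminal
    units, the proximal bronchus excluded) — the quantity the S = kV^n fit
    operates on.
    """

    displacement_fields: list[DisplacementField]
    labels: list[np.ndarray]
    V_series: np.ndarray
    S_series: np.ndarray
    recruited_ids: set[int]
    divergence: list[np.ndarray] | None = None


AnalyticField = namedtuple("AnalyticField", ["displacement", "divergence"])


# ---------------------------------------------------------------------------
# geometry realization (voxel units)
# ---------------------------------------------------------------------------


@dataclass
class _Sphere:
    center: np.ndarray
    radius: float
    unit_id: int


@dataclass
class _Cylinder:
    p0: np.ndarray
    axis: np.ndarray  # unit vector
    length: float
    radius: float
    kind: str
    index: int


@dataclass
class Geometry:
    """Phantom primitives in voxel units, plus the scene centre."""

    cylinders: list[_Cylinder]
    spheres: list[_Sphere]
    vessels: list[_Cylinder]
    center: np.ndarray


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (deterministic golden-spiral layout)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )


def realize_geometry(spec: PhantomSpec) -> Geometry:
    """Convert the µm specification into voxel-unit primitives."""
    vs = spec.voxel_size
    cylinders = []
    for i, b in enumerate(spec.airway_tree):
        ax = np.asarray(b.direction, dtype=float)
        ax = ax / np.linalg.norm(ax)
        cylinders.append(_Cylinder(np.asarray(b.start) / vs, ax, b.length / vs,
                                   b.radius / vs, b.kind, i))
    vessels = []
    for i, b in enumerate(spec.vessel_tree):
        ax = np.asarray(b.direction, dtype=float)
        ax = ax / np.linalg.norm(ax)
        vessels.append(_Cylinder(np.asarray(b.start) / vs, ax, b.length / vs,
                                 b.radius / vs, "vessel", i))
    spheres = []
    uid = 0
    for c in spec.acinar_clusters:
        shell = (c.shell_radius if c.shell_radius is not None else 2.1 * c.unit_radius) / vs
        ctr = np.asarray(c.center, dtype=float) / vs
        if c.n_units == 1:
            centers = ctr[None, :]
        else:
            centers = ctr[None, :] + shell * _fibonacci_directions(c.n_units)
        for p in centers:
            spheres.append(_Sphere(p, c.unit_radius / vs, uid))
            uid += 1
    center = (np.asarray(spec.grid_shape, dtype=float) - 1.0) / 2.0
    return Geometry(cylinders, spheres, vessels, center)


def _present(sphere_id: int, step: int, deformation: DeformationSpec) -> bool:
    for uid, s0 in deformation.recruitment_events:
        if uid == sphere_id:
            return step >= s0
    return True


def _deformed_geometry(geom: Geometry, deformation: DeformationSpec, step: int) -> Geometry:
    """Primitive set at a phase step under the analytic deformation."""
    lam = deformation.scale(step)
    mode = deformation.mode
    c = geom.center

    def scale_cyl(cy: _Cylinder, about_center: bool, radial_only: bool) -> _Cylinder:
        if about_center:
            return _Cylinder(c + lam * (cy.p0 - c), cy.axis, lam * cy.length,
                             lam * cy.radius, cy.kind, cy.index)
        if radial_only:
            return _Cylinder(cy.p0, cy.axis, cy.length, lam * cy.radius, cy.kind, cy.index)
        return cy

    def scale_sph(sp: _Sphere, about_center: bool, about_self: bool) -> _Sphere:
        if about_center:
            return _Sphere(c + lam * (sp.center - c), lam * sp.radius, sp.unit_id)
        if about_self:
            return _Sphere(sp.center, lam * sp.radius, sp.unit_id)
        return sp

    if mode == "isotropic":
        cyls = [scale_cyl(cy, True, False) for cy in geom.cylinders]
        sphs = [scale_sph(sp, True, False) for sp in geom.spheres]
        ves = [scale_cyl(cy, True, False) for cy in geom.vessels]
    elif mode == "ductal_dominant":
        cyls = [scale_cyl(cy, False, cy.kind == "intermediate") for cy in geom.cylinders]
        sphs = list(geom.spheres)
        ves = list(geom.vessels)
    elif mode == "alveolar_dominant":
        cyls = list(geom.cylinders)
        sphs = [scale_sph(sp, False, True) for sp in geom.spheres]
        ves = list(geom.vessels)
    elif mode == "recruitment":
        cyls = list(geom.cylinders)
        sphs = [sp for sp in geom.spheres if _present(sp.unit_id, step, deformation)]
        ves = list(geom.vessels)
    else:  # pragma: no cover - rejected earlier
        raise ValueError(f"mode {mode!r} has no implicit-geometry rendering")
    return Geometry(cyls, sphs, ves, c)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _sphere_inside(sp: _Sphere, z, y, x) -> np.ndarray:
    return (z - sp.center[0]) ** 2 + (y - sp.center[1]) ** 2 + (x - sp.center[2]) ** 2 \
        <= sp.radius**2


def _cylinder_inside(cy: _Cylinder, z, y, x) -> np.ndarray:
    dz, dy, dx = z - cy.p0[0], y - cy.p0[1], x - cy.p0[2]
    t = dz * cy.axis[0] + dy * cy.axis[1] + dx * cy.axis[2]
    rz = dz - t * cy.axis[0]
    ry = dy - t * cy.axis[1]
    rx = dx - t * cy.axis[2]
    return (t >= 0) & (t <= cy.length) & (rz**2 + ry**2 + rx**2 <= cy.radius**2)


def _bbox(prim, shape) -> tuple[slice, slice, slice] | None:
    if isinstance(prim, _Sphere):
        lo = prim.center - prim.radius - 1.0
        hi = prim.center + prim.radius + 1.0
    else:
        p1 = prim.p0 + prim.axis * prim.length
        lo = np.minimum(prim.p0, p1) - prim.radius - 1.0
        hi = np.maximum(prim.p0, p1) + prim.radius + 1.0
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _paint(mask: np.ndarray, prim, offset=(0.0, 0.0, 0.0)) -> None:
    """OR the primitive's (possibly sub-voxel offset) occupancy into ``mask``."""
    sl = _bbox(prim, mask.shape)
    if sl is None:
        return
    z, y, x = np.meshgrid(
        np.arange(sl[0].start, sl[0].stop, dtype=float) + offset[0],
        np.arange(sl[1].start, sl[1].stop, dtype=float) + offset[1],
        np.arange(sl[2].start, sl[2].stop, dtype=float) + offset[2],
        indexing="ij",
    )
    if isinstance(prim, _Sphere):
        mask[sl] |= _sphere_inside(prim, z, y, x)
    else:
        mask[sl] |= _cylinder_inside(prim, z, y, x)


def _occupancy(shape, primitives, supersample: int) -> np.ndarray:
    """Fraction of each voxel covered by the union of primitives."""
    if supersample <= 1:
        m = np.zeros(shape, dtype=bool)
        for p in primitives:
            _paint(m, p)
        return m.astype(np.float32)
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    frac = np.zeros(shape, dtype=np.float32)
    for oz in offs:
        for oy in offs:
            for ox in offs:
                m = np.zeros(shape, dtype=bool)
                for p in primitives:
                    _paint(m, p, (oz, oy, ox))
                frac += m
    frac /= ss**3
    return frac


def _labels_for(geom_t: Geometry, shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.uint8)
    for cy in geom_t.vessels:
        m = np.zeros(shape, dtype=bool)
        _paint(m, cy)
        labels[m] = VESSEL
    for cy in geom_t.cylinders:
        m = np.zeros(shape, dtype=bool)
        _paint(m, cy)
        labels[m] = PROXIMAL if cy.kind == "proximal" else INTERMEDIATE
    for sp in geom_t.spheres:
        m = np.zeros(shape, dtype=bool)
        _paint(m, sp)
        labels[m] = TERMINAL
    return labels


# ---------------------------------------------------------------------------
# analytic V / S of the peripheral airspace
# ---------------------------------------------------------------------------


def _peripheral_vs(geom_t: Geometry) -> tuple[float, float]:
    """Analytic volume and surface of intermediate ducts + terminal units.

    Cylinder surface includes both end caps; junction overlaps are ignored
    (the primitives are laid out disjoint, see module docstring).
    """
    V = 0.0
    S = 0.0
    for cy in geom_t.cylinders:
        if cy.kind != "intermediate":
            continue
        V += math.pi * cy.radius**2 * cy.length
        S += 2 * math.pi * cy.radius * cy.length + 2 * math.pi * cy.radius**2
    for sp in geom_t.spheres:
        V += 4.0 / 3.0 * math.pi * sp.radius**3
        S += 4.0 * math.pi * sp.radius**2
    return V, S


# ---------------------------------------------------------------------------
# analytic displacement
# ---------------------------------------------------------------------------


def analytic_displacement(
    deformation: DeformationSpec,
    points: Sequence,
    step: int,
    geometry: Geometry | None = None,
) -> AnalyticField:
    """Exact Lagrangian displacement (and its divergence) at reference points.

    ``points`` are reference-frame (step 0) coordinates in voxel units,
    (z, y, x) order.  Returns voxel-unit displacement vectors (N, 3) and the
    exact divergence of the returned field with respect to the reference
    coordinates (N,).  ``geometry`` (from :func:`realize_geometry`) is
    required for the structure-localized modes.
    """
    pts = as_points(points)
    lam = deformation.scale(step)
    mode = deformation.mode
    u = np.zeros_like(pts)
    div = np.zeros(pts.shape[0])

    if mode == "custom_analytic":
        if deformation.displacement_fn is None:
            raise ValueError("custom_analytic mode requires displacement_fn")
        return AnalyticField(*deformation.displacement_fn(pts, step))
    if mode == "recruitment":
        return AnalyticField(u, div)
    if mode == "isotropic":
        if geometry is None:
            raise ValueError("isotropic mode requires geometry (for the scene centre)")
        u = (lam - 1.0) * (pts - geometry.center)
        div[:] = 3.0 * (lam - 1.0)
        return AnalyticField(u, div)
    if geometry is None:
        raise ValueError(f"mode {mode!r} requires the phantom geometry")
    if mode == "ductal_dominant":
        for cy in geometry.cylinders:
            if cy.kind != "intermediate":
                continue
            d = pts - cy.p0
            t = d @ cy.axis
            radial = d - np.outer(t, cy.axis)
            inside = (t >= 0) & (t <= cy.length) & (np.sum(radial**2, axis=1) <= cy.radius**2)
            u[inside] = (lam - 1.0) * radial[inside]
            div[inside] = 2.0 * (lam - 1.0)
        return AnalyticField(u, div)
    if mode == "alveolar_dominant":
        for sp in geometry.spheres:
            d = pts - sp.center
            inside = np.sum(d**2, axis=1) <= sp.radius**2
            u[inside] = (lam - 1.0) * d[inside]
            div[inside] = 3.0 * (lam - 1.0)
        return AnalyticField(u, div)
    raise ValueError(f"unknown deformation mode {mode!r}")


def _field_grid(geom: Geometry, deformation: DeformationSpec, step: int, shape) -> tuple[np.ndarray, np.ndarray]:
    """Dense Lagrangian field (3, Z, Y, X) and divergence grid at a step."""
    lam = deformation.scale(step)
    mode = deformation.mode
    u = np.zeros((3,) + tuple(shape), dtype=np.float32)
    div = np.zeros(shape, dtype=np.float32)
    if mode == "recruitment":
        return u, div
    if mode == "isotropic":
        for a, n in enumerate(shape):
            coord = np.arange(n, dtype=np.float32) - geom.center[a]
            sh = [1, 1, 1]
            sh[a] = n
            u[a] += (lam - 1.0) * coord.reshape(sh)
        div[:] = 3.0 * (lam - 1.0)
        return u, div
    # structure-localized modes: evaluate per primitive bbox
    prims = []
    if mode == "ductal_dominant":
        prims = [cy for cy in geom.cylinders if cy.kind == "intermediate"]
    elif mode == "alveolar_dominant":
        prims = list(geom.spheres)
    for p in prims:
        sl = _bbox(p, shape)
        if sl is None:
            continue
        z, y, x = np.meshgrid(*(np.arange(s.start, s.stop, dtype=np.float32) for s in sl),
                              indexing="ij")
        if isinstance(p, _Sphere):
            inside = _sphere_inside(p, z, y, x)
            for a, (grid, c0) in enumerate(zip((z, y, x), p.center)):
                u[a][sl][inside] = (lam - 1.0) * (grid[inside] - c0)
            div[sl][inside] = 3.0 * (lam - 1.0)
        else:
            dz, dy, dx = z - p.p0[0], y - p.p0[1], x - p.p0[2]
            t = dz * p.axis[0] + dy * p.axis[1] + dx * p.axis[2]
            rz, ry, rx = dz - t * p.axis[0], dy - t * p.axis[1], dx - t * p.axis[2]
            inside = (t >= 0) & (t <= p.length) & (rz**2 + ry**2 + rx**2 <= p.radius**2)
            for a, comp in enumerate((rz, ry, rx)):
                u[a][sl][inside] = (lam - 1.0) * comp[inside]
            div[sl][inside] = 2.0 * (lam - 1.0)
    return u, div


# ---------------------------------------------------------------------------
# validation and generation
# ---------------------------------------------------------------------------


def _validate_fit(spec: PhantomSpec, geom: Geometry) -> None:
    """Every structure must stay inside the grid at maximal deformation."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    margin = 0.5
    steps = range(spec.deformation.n_steps)
    # peak of the waveform decides; checking all steps is cheap and exact
    for t in steps:
        g = _deformed_geometry(geom, spec.deformation, t)
        for cy in g.cylinders + g.vessels:
            p1 = cy.p0 + cy.axis * cy.length
            pad = cy.radius * np.sqrt(np.maximum(1.0 - cy.axis**2, 0.0))
            lo = np.minimum(cy.p0, p1) - pad
            hi = np.maximum(cy.p0, p1) + pad
            if np.any(lo < margin) or np.any(hi > shape - 1 - margin):
                raise ValueError(
                    f"branch (kind={cy.kind}, index={cy.index}) leaves the grid at step {t}"
                )
        for sp in g.spheres:
            if np.any(sp.center - sp.radius < margin) or np.any(
                sp.center + sp.radius > shape - 1 - margin
            ):
                raise ValueError(f"terminal unit {sp.unit_id} leaves the grid at step {t}")


def _validate_disjoint(geom: Geometry, spec: PhantomSpec) -> None:
    """Unit spheres must stay pairwise disjoint and clear of all cylinders."""
    lam_max = 1.0 + spec.deformation.amplitude
    sph = geom.spheres
    for i in range(len(sph)):
        for j in range(i + 1, len(sph)):
            d = np.linalg.norm(sph[i].center - sph[j].center)
            if d < lam_max * (sph[i].radius + sph[j].radius):
                raise ValueError(
                    f"terminal units {sph[i].unit_id} and {sph[j].unit_id} overlap"
                )
        for cy in geom.cylinders + geom.vessels:
            d = sph[i].center - cy.p0
            t = float(np.clip(d @ cy.axis, 0.0, cy.length))
            dist = np.linalg.norm(d - t * cy.axis)
            if dist < lam_max * (sph[i].radius + cy.radius):
                raise ValueError(
                    f"terminal unit {sph[i].unit_id} intersects branch index={cy.index}"
                )


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeSeries, GroundTruth]:
    """Render the 4D greyscale series and its exact ground truth.

    Deterministic: identical ``spec`` (including ``seed``) gives
    bit-identical output.
    """
    if spec.deformation.mode == "custom_analytic":
        raise ValueError("generate_phantom does not render custom_analytic deformations")
    geom = realize_geometry(spec)
    _validate_fit(spec, geom)
    _validate_disjoint(geom, spec)

    shape = tuple(spec.grid_shape)
    n = spec.deformation.n_steps
    rng = np.random.default_rng(spec.seed)
    vols = np.empty((n,) + shape, dtype=np.float32)
    labels = []
    fields = []
    divs = []
    V = np.empty(n)
    S = np.empty(n)
    vs = spec.voxel_size
    for t in range(n):
        g_t = _deformed_geometry(geom, spec.deformation, t)
        air = _occupancy(shape, g_t.cylinders + g_t.spheres, spec.supersample)
        ves = _occupancy(shape, g_t.vessels, spec.supersample)
        img = TISSUE_GREY - air * (TISSUE_GREY - AIR_GREY) - ves * (TISSUE_GREY - VESSEL_GREY)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)
        vols[t] = img
        labels.append(_labels_for(g_t, shape))
        u, dv = _field_grid(geom, spec.deformation, t, shape)
        fields.append(
            DisplacementField(u, kind="lagrangian", from_step=0, to_step=t,
                              voxel_size=vs)
        )
        divs.append(dv)
        v_t, s_t = _peripheral_vs(g_t)
        V[t] = v_t * vs**3
        S[t] = s_t * vs**2
    recruited = {uid for uid, s0 in spec.deformation.recruitment_events if s0 > 0}
    dt = spec.deformation.breath_duration / n
    series = VolumeSeries(vols, voxel_size=vs, times=np.arange(n) * dt)
    gt = GroundTruth(fields, labels, V, S, recruited, divergence=divs)
    return series, gt


# ---------------------------------------------------------------------------
# standard study phantoms
# ---------------------------------------------------------------------------


def demo_spec(
    mode: str = "isotropic",
    grid: int = 64,
    n_steps: int = 10,
    amplitude: float | None = None,
    noise_sigma: float = 0.05,
    seed: int = 0,
    voxel_size: float = 6.0,
    supersample: int = 2,
) -> PhantomSpec:
    """The package's standard phantom morphology for each deformation regime.

    The geometry is laid out on a 64³ reference grid (scaled for other grid
    sizes): a proximal trunk (r = 10 vx) feeding one intermediate acinar duct
    (r = 6.5 vx), three clusters of terminal units, and one vessel.  Default
    amplitudes: 0.05 for isotropic (a gentle tidal breath), 0.15 for the
    ductal/alveolar regimes (where only part of the scene deforms and a
    stronger signal mirrors the 50%-radius-increase limiting sketches).
    """
    if amplitude is None:
        amplitude = 0.05 if mode in ("isotropic", "recruitment") else 0.15
    s = grid / 64.0 * voxel_size  # µm per reference-layout voxel

    def pt(z, y, x):
        return (z * s, y * s, x * s)

    trunk = Branch(pt(4, 26, 20), (1, 0, 0), 22 * s, 10 * s, "proximal")
    duct = Branch(pt(26, 26, 20), (1, 0, 0), 32 * s, 6.5 * s, "intermediate")
    vessel = Branch(pt(4, 54, 10), (1, 0, 0), 36 * s, 6 * s, "intermediate")

    if mode == "recruitment":
        unit_r, shell, n_units = 5 * s, 9.5 * s, 5
        clusters = [
            AcinarCluster(pt(16, 46, 38), unit_r, n_units, shell),
            AcinarCluster(pt(42, 46, 38), unit_r, n_units, shell),
            AcinarCluster(pt(29, 18, 46), unit_r, n_units, shell),
        ]
        k = max(2, n_steps // 3)
        events = [(2, k), (7, min(n_steps - 2, k + 2)), (12, min(n_steps - 1, k + 4))]
        airways = [trunk]  # peripheral airspace is purely alveolar: n -> 1
    else:
        unit_r, shell, n_units = 4 * s, 8 * s, 5
        clusters = [
            AcinarCluster(pt(16, 46, 38), unit_r, n_units, shell),
            AcinarCluster(pt(42, 46, 38), unit_r, n_units, shell),
            AcinarCluster(pt(29, 18, 46), unit_r, n_units, shell),
        ]
        events = []
        airways = [trunk, duct]

    deformation = DeformationSpec(
        mode=mode, amplitude=amplitude, n_steps=n_steps, recruitment_events=events
    )
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        voxel_size=voxel_size,
        airway_tree=airways,
        acinar_clusters=clusters,
        vessel_tree=[vessel],
        deformation=deformation,
        noise_sigma=noise_sigma,
        seed=seed,
        supersample=supersample,
    )
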