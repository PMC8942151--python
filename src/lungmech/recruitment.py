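"""Skeleton-based detection of recruited (newly inflated) airspaces.

A previously gasless airspace that inflates during a breath appears in the
segmentation of phase n without any ancestor at phase 0, so image
registration cannot explain it.  Detection therefore compares topology:
the segmented airspace of each phase is reduced to a one-voxel-wide
skeleton, the baseline (phase 0) skeleton is advected by the Lagrangian
displacement field, and for every phase-skeleton voxel two distances are
computed:

    d_Ω = distance to the segmentation boundary ∂Ω(nΔt)
    d_s = distance to the deformed baseline skeleton s(r(nΔt); Ω(0))

A voxel of the phase skeleton that is farther from any deformed baseline
skeleton than from its own structure's wall (d_s > d_Ω) cannot belong to a
tracked structure and seeds a recruited component, which is then grown to
the full structure by a marker watershed inside Ω.  On a purely inflating
series the deformed baseline skeleton stays close to every phase skeleton
and no seeds arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skeletonize_3d
from skimage.segmentation import watershed

from .core import DisplacementField
from .segmentation import CROSS, FULL_CONN, SegmentedVolume


@dataclass
class Skeleton:
    """One-voxel-wide binary centerline representation at one phase."""

    voxels: np.ndarray
    phase: int = 0
    mask: np.ndarray | None = None  # valid region (deformed skeletons only)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class RecruitmentReport:
    """Seeds and segmented recruited structures at one phase."""

    phase: int
    seeds: np.ndarray              # boolean seed voxels (d_s > d_Ω, size-filtered)
    recruited_labels: np.ndarray   # integer labels of grown recruited structures
    n_components: int
    volumes: list[int] = dc_field(default_factory=list)  # voxels per component


def skeletonize(segmented: SegmentedVolume | np.ndarray, phase: int = 0) -> Skeleton:
    """Topology-preserving 3D thinning of Ω to a 1-voxel-wide skeleton."""
    omega = segmented.omega if isinstance(segmented, SegmentedVolume) else \
        np.asarray(segmented, dtype=bool)
    if not omega.any():
        raise ValueError("empty segmentation Ω")
    if isinstance(segmented, SegmentedVolume):
        phase = segmented.phase
    sk = _skeletonize_3d(omega).astype(bool)
    # the thinning can delete a small compact component outright; every
    # connected component must keep at least its deepest (EDT-max) voxel or
    # downstream distance comparisons would see phantom recruitment
    lab, n = ndimage.label(omega, structure=FULL_CONN)
    if n:
        covered = np.unique(lab[sk])
        missing = np.setdiff1d(np.arange(1, n + 1), covered)
        if missing.size:
            edt = ndimage.distance_transform_edt(omega)
            for i in missing:
                comp = lab == i
                sk[np.unravel_index(np.argmax(np.where(comp, edt, -1)), omega.shape)] = True
    return Skeleton(sk, phase)


def deform_skeleton(baseline: Skeleton, lagrangian: DisplacementField) -> Skeleton:
    """Advect each baseline skeleton voxel by the Lagrangian field.

    Positions are rounded to the nearest voxel (collisions collapse to a
    single marked voxel); advected positions outside the grid are clamped
    to the boundary and recorded in the skeleton's validity mask.
    """
    shape = baseline.voxels.shape
    if lagrangian.grid_shape != shape:
        raise ValueError("field must cover the skeleton grid")
    idx = np.argwhere(baseline.voxels)
    if idx.size == 0:
        return Skeleton(np.zeros(shape, dtype=bool), lagrangian.to_step)
    disp = np.stack([lagrangian.vectors[a][tuple(idx.T)] for a in range(3)], axis=1)
    new = np.rint(idx + disp).astype(int)
    inside = np.all((new >= 0) & (new < np.asarray(shape)), axis=1)
    new = np.clip(new, 0, np.asarray(shape) - 1)
    out = np.zeros(shape, dtype=bool)
    out[tuple(new.T)] = True
    mask = np.ones(shape, dtype=bool)
    if not inside.all():
        mask[tuple(new[~inside].T)] = False
    return Skeleton(out, lagrangian.to_step, mask)


def recruitment_detect(
    phase_skeleton: Skeleton,
    deformed_baseline: Skeleton,
    segmented: SegmentedVolume | np.ndarray,
    min_seed_size: int = 1,
) -> RecruitmentReport:
    """Seed and grow recruited structures at one phase.

    For every phase-skeleton voxel, d_Ω is the Euclidean distance to the
    segmentation boundary ∂Ω and d_s the Euclidean distance to the nearest
    deformed-baseline skeleton voxel; seeds are the voxels with d_s > d_Ω.
    Seed components smaller than ``min_seed_size`` voxels can be discarded
    to suppress skeleton jitter; the filter is off by default (a compact
    recruited alveolus thins to a single skeleton voxel, and the
    d_s > d_Ω margin — jitter would have to exceed the local structure
    radius — already suppresses noise seeds).
    Surviving seeds are grown to whole structures by a marker watershed of
    the inverted distance transform inside Ω, competing against the
    deformed baseline skeleton.
    """
    omega = segmented.omega if isinstance(segmented, SegmentedVolume) else \
        np.asarray(segmented, dtype=bool)
    if phase_skeleton.voxels.shape != omega.shape or \
            deformed_baseline.voxels.shape != omega.shape:
        raise ValueError("skeletons and segmentation must share a grid")
    phase = phase_skeleton.phase

    boundary = omega & ~ndimage.binary_erosion(omega, structure=CROSS)
    d_omega = ndimage.distance_transform_edt(~boundary)
    if deformed_baseline.voxels.any():
        d_skel = ndimage.distance_transform_edt(~deformed_baseline.voxels)
    else:
        d_skel = np.full(omega.shape, np.inf)

    sk = phase_skeleton.voxels
    seeds = sk & (d_skel > d_omega)
    # size filter on seed components
    lab, n = ndimage.label(seeds, structure=FULL_CONN)
    if n:
        sizes = np.bincount(lab.ravel())
        drop = np.nonzero(sizes < min_seed_size)[0]
        seeds = seeds & ~np.isin(lab, drop[drop > 0])

    recruited = np.zeros(omega.shape, dtype=np.int32)
    n_comp = 0
    volumes: list[int] = []
    if seeds.any():
        seed_lab, n_comp = ndimage.label(seeds, structure=FULL_CONN)
        markers = np.zeros(omega.shape, dtype=np.int32)
        markers[deformed_baseline.voxels & omega] = 1
        markers[seeds] = seed_lab[seeds] + 1
        edt = ndimage.distance_transform_edt(omega)
        grown = watershed(-edt, markers=markers, mask=omega)
        recruited = np.where(grown >= 2, grown - 1, 0).astype(np.int32)
        # keep only components that actually contain their seed
        volumes = [int(np.sum(recruited == i)) for i in range(1, n_comp + 1)]
    return RecruitmentReport(phase, seeds, recruited, n_comp, volumes)


def detect_series(
    segmentations: list[SegmentedVolume | np.ndarray],
    lagrangian_fields: list[DisplacementField],
    min_seed_size: int = 1,
) -> list[RecruitmentReport]:
    """Run recruitment detection for phases 1..N against the phase-0 baseline.

    ``lagrangian_fields[n-1]`` must map phase 0 to phase n.
    """
    if len(lagrangian_fields) != len(segmentations) - 1:
        raise ValueError("need one Lagrangian field per non-baseline phase")
    baseline = skeletonize(segmentations[0], phase=0)
    out = []
    for n, (seg, lag) in enumerate(zip(segmentations[1:], lagrangian_fields), start=1):
        phase_sk = skeletonize(seg, phase=n)
        deformed = deform_skeleton(baseline, lag)
        out.append(recruitment_detect(phase_sk, deformed, seg, min_seed_size))
    return out
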