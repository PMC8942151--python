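"""File formats: volume series, displacement fields, label maps, VTK export.

Volumes are read and written as multi-page TIFF (one file per phase) or
NIfTI, with a JSON sidecar carrying the voxel size and phase times (the
sidecar is authoritative for timing).  Displacement fields and ground-truth
archives use compressed ``.npz``; strain maps and fields can additionally
be exported as legacy VTK STRUCTURED_POINTS ASCII files that standard
renderers (e.g. ParaView) open directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .core import LABEL_NAMES, DisplacementField, VolumeSeries

# ---------------------------------------------------------------------------
# volume series
# ---------------------------------------------------------------------------


def write_series(series: VolumeSeries, out_dir: str | Path, prefix: str = "phase") -> Path:
    """Write one multi-page TIFF per phase plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in range(series.n_phases):
        tifffile.imwrite(out / f"{prefix}_{t:03d}.tif", np.asarray(series[t], dtype=np.float32))
    sidecar = {
        "voxel_size_um": series.voxel_size,
        "times_s": [float(t) for t in series.times],
        "n_phases": series.n_phases,
        "prefix": prefix,
    }
    (out / f"{prefix}_series.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_series(in_dir: str | Path, prefix: str = "phase") -> VolumeSeries:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / f"{prefix}_series.json").read_text())
    vols = [
        tifffile.imread(in_dir / f"{prefix}_{t:03d}.tif")
        for t in range(sidecar["n_phases"])
    ]
    return VolumeSeries(np.stack(vols), voxel_size=sidecar["voxel_size_um"],
                        times=np.asarray(sidecar["times_s"]))


def write_nifti(volume: np.ndarray, path: str | Path, voxel_size: float) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(abs(img.affine[0, 0]))


# ---------------------------------------------------------------------------
# labels and fields
# ---------------------------------------------------------------------------


def write_labels(labels: np.ndarray, path: str | Path, voxel_size: float = 1.0) -> None:
    """Unsigned-integer label TIFF with a JSON label-map sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8))
    meta = {"voxel_size_um": voxel_size,
            "label_map": {str(k): v for k, v in LABEL_NAMES.items()}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_field(field: DisplacementField, path: str | Path) -> None:
    """Displacement field as a compressed 4-component archive (3 vectors + mask)."""
    np.savez_compressed(
        Path(path),
        vectors=field.vectors.astype(np.float32),
        mask=field.mask,
        kind=field.kind,
        from_step=field.from_step,
        to_step=field.to_step,
        voxel_size=field.voxel_size,
    )


def read_field(path: str | Path) -> DisplacementField:
    with np.load(Path(path), allow_pickle=False) as z:
        return DisplacementField(
            z["vectors"].astype(float),
            kind=str(z["kind"]),
            from_step=int(z["from_step"]),
            to_step=int(z["to_step"]),
            mask=z["mask"].astype(bool),
            voxel_size=float(z["voxel_size"]),
        )


# ---------------------------------------------------------------------------
# legacy VTK STRUCTURED_POINTS (ASCII)
# ---------------------------------------------------------------------------


def export_vtk(
    path: str | Path,
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
    spacing: float | None = None,
) -> Path:
    """Write scalar/vector grids as a legacy VTK STRUCTURED_POINTS file.

    All arrays must share one (Z, Y, X) grid; vectors are (3, Z, Y, X) in
    (z, y, x) component order and are written as (x, y, z) per VTK
    convention.  Values use ``repr`` precision, so float64 data round-trip
    bit-exactly through :func:`read_vtk`.  Masked voxels should be encoded
    as NaN with a companion 0/1 mask scalar array.
    """
    if spacing is None:
        raise ValueError("physical spacing must be set for VTK export")
    scalars = scalars or {}
    vectors = vectors or {}
    arrays = list(scalars.values()) + [v[0] for v in vectors.values()]
    if not arrays:
        raise ValueError("nothing to export")
    shape = arrays[0].shape
    for a in scalars.values():
        if a.shape != shape:
            raise ValueError("all arrays must share a grid")
    for v in vectors.values():
        if v.shape != (3,) + shape:
            raise ValueError("vector arrays must have shape (3, Z, Y, X)")
    nz, ny, nx = shape
    lines = [
        "# vtk DataFile Version 3.0",
        "lungmech export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing!r} {spacing!r} {spacing!r}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr, dtype=float).ravel()  # z-major = VTK x-fastest
        lines.extend(repr(float(v)) for v in flat)
    for name, vec in vectors.items():
        lines.append(f"VECTORS {name} double")
        vx, vy, vz = vec[2].ravel(), vec[1].ravel(), vec[0].ravel()
        lines.extend(f"{float(a)!r} {float(b)!r} {float(c)!r}"
                     for a, b, c in zip(vx, vy, vz))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk(path: str | Path) -> dict:
    """Re-read a file written by :func:`export_vtk` (round-trip identity)."""
    tokens = Path(path).read_text().splitlines()
    i = 0
    dims = None
    spacing = None
    out: dict = {"scalars": {}, "vectors": {}}
    while i < len(tokens):
        line = tokens[i]
        if line.startswith("DIMENSIONS"):
            nx, ny, nz = (int(v) for v in line.split()[1:])
            dims = (nz, ny, nx)
        elif line.startswith("SPACING"):
            spacing = float(line.split()[1])
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            n = dims[0] * dims[1] * dims[2]
            vals = np.array([float(tokens[i + k]) for k in range(n)])
            out["scalars"][name] = vals.reshape(dims)
            i += n - 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            n = dims[0] * dims[1] * dims[2]
            rows = [tokens[i + 1 + k].split() for k in range(n)]
            arr = np.array(rows, dtype=float)  # columns x, y, z
            vec = np.stack([arr[:, 2].reshape(dims), arr[:, 1].reshape(dims),
                            arr[:, 0].reshape(dims)])
            out["vectors"][name] = vec
            i += n
        i += 1
    out["spacing"] = spacing
    return out
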