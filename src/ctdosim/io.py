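"""Readers and writers: DICOM CT / RT Structure Sets and the internal
phantom format.

The DICOM readers are deliberately minimal and read-only: a CT series is
loaded as a HU volume (rescale slope/intercept honored) with its geometry,
and an RT Structure Set yields per-slice closed polygons per ROI. The
internal phantom format is a directory of ``.npy`` volumes (density,
material, one boolean volume per organ) plus a JSON sidecar with spacing,
origin and the organ list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom

from .phantom import BodyContour, OrganMask, VoxelPhantom

__all__ = [
    "read_ct_series",
    "read_rtstruct",
    "save_phantom",
    "load_phantom",
]


def read_ct_series(directory):
    """Read a DICOM CT series into ``(hu, spacing, origin)``.

    The volume is indexed ``[ix, iy, iz]`` with x along DICOM columns,
    y along rows and z along the sorted slice positions; HU values are
    ``pixel * RescaleSlope + RescaleIntercept``.
    """
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)  # row spacing, col spacing
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) \
            - float(first.ImagePositionPatient[2])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    hu = np.stack(
        [ds.pixel_array * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
         for ds in slices], axis=-1)  # (rows=y, cols=x, z)
    hu = np.ascontiguousarray(np.transpose(hu, (1, 0, 2)))
    ipp = [float(v) for v in first.ImagePositionPatient]
    # ImagePositionPatient addresses the first voxel center; internal origin
    # is the grid corner
    origin = (ipp[0] - dx / 2, ipp[1] - dy / 2, ipp[2] - dz / 2)
    return hu, (dx, dy, dz), origin


def read_rtstruct(path, roi_names=None):
    """Read an RT Structure Set into ``{roi_name: [BodyContour, ...]}``.

    Only closed planar contours are returned; ``roi_names`` optionally
    restricts (case-insensitively) which ROIs are loaded.
    """
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    wanted = {n.lower() for n in roi_names} if roi_names else None
    out = {}
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber))
        if name is None or (wanted and name.lower() not in wanted):
            continue
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            if str(getattr(c, "ContourGeometricType", "CLOSED_PLANAR")) \
                    != "CLOSED_PLANAR":
                continue
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours.append(BodyContour(vertices=pts[:, :2], z=float(pts[0, 2])))
        if contours:
            out[name] = contours
    if not out:
        raise ValueError("no matching closed planar contours found")
    return out


def save_phantom(directory, phantom: VoxelPhantom, masks=None):
    """Write a phantom (and optional organ masks) in the internal format."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "density.npy", phantom.density)
    np.save(d / "material.npy", phantom.material)
    masks = masks or {}
    for name, m in masks.items():
        np.save(d / f"mask_{name}.npy", m.mask)
    sidecar = {
        "spacing_mm": list(map(float, phantom.spacing)),
        "origin_mm": list(map(float, phantom.origin)),
        "organs": sorted(masks),
    }
    (d / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(directory):
    """Read back a phantom written by :func:`save_phantom`.

    Returns ``(phantom, masks)``.
    """
    d = Path(directory)
    sidecar = json.loads((d / "phantom.json").read_text())
    phantom = VoxelPhantom(
        density=np.load(d / "density.npy"),
        material=np.load(d / "material.npy"),
        spacing=sidecar["spacing_mm"],
        origin=sidecar["origin_mm"],
    )
    masks = {name: OrganMask(name, np.load(d / f"mask_{name}.npy"))
             for name in sidecar["organs"]}
    return phantom, masks
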