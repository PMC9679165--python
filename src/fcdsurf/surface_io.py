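"""Surface and overlay file I/O (GIFTI and FreeSurfer formats).

Thin wrappers around nibabel: meshes as ``.surf.gii`` or FreeSurfer binary
surfaces, per-vertex scalar overlays as ``.func.gii`` or FreeSurfer "curv"
files, boolean label masks as ``.label.gii``.  The cohort container itself
serializes the template internally; these readers exist for interchange
with standard surface-neuroimaging tools.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib
from nibabel import gifti

from .mesh import SurfaceMesh

__all__ = [
    "read_surface",
    "write_surface",
    "read_overlay",
    "write_overlay",
    "write_label",
    "read_label",
]


def _is_gifti(path) -> bool:
    return str(path).endswith(".gii")


def read_surface(path, cortex_mask=None) -> SurfaceMesh:
    """Read a triangle mesh from GIFTI or FreeSurfer binary format."""
    if _is_gifti(path):
        img = nib.load(str(path))
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    else:
        coords, faces = nib.freesurfer.read_geometry(str(path))
    return SurfaceMesh(np.asarray(coords, float), np.asarray(faces), cortex_mask)


def write_surface(mesh: SurfaceMesh, path) -> None:
    if _is_gifti(path):
        img = gifti.GiftiImage(
            darrays=[
                gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    else:
        nib.freesurfer.write_geometry(str(path), mesh.vertices, mesh.triangles)


def read_overlay(path) -> np.ndarray:
    """Read a per-vertex scalar overlay (.func.gii or FreeSurfer curv)."""
    if _is_gifti(path):
        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=float)
    return np.asarray(nib.freesurfer.read_morph_data(str(path)), dtype=float)


def write_overlay(values: np.ndarray, path) -> None:
    values = np.asarray(values)
    if _is_gifti(path):
        img = gifti.GiftiImage(
            darrays=[
                gifti.GiftiDataArray(
                    values.astype(np.float32), intent="NIFTI_INTENT_NONE"
                )
            ]
        )
        nib.save(img, str(path))
    else:
        nib.freesurfer.write_morph_data(str(path), values.astype(float))


def write_label(mask: np.ndarray, path) -> None:
    """Write a boolean vertex mask as a .label.gii file."""
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                np.asarray(mask, dtype=np.int32), intent="NIFTI_INTENT_LABEL"
            )
        ]
    )
    nib.save(img, str(path))


def read_label(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data) != 0
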