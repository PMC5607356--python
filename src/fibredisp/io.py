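"""Readers and writers for the standard on-disk formats.

DWI volumes travel as NIfTI plus FSL-style ``bvals``/``bvecs`` text files;
PLI stacks and scalar maps as (multipage) TIFF; FODs as ``angle_deg,mass``
CSV (see :mod:`fibredisp.fod`); fit tables as CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile


def read_bvals_bvecs(bvals_path, bvecs_path):
    """Read FSL-format gradient tables.

    ``bvals``: one row of b-values. ``bvecs``: three rows (x, y, z), one
    column per volume. Returns ``(bvals (N,), bvecs (N, 3))``.
    """
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # ambiguous; FSL convention is rows-per-axis
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvals/bvecs sizes disagree")
    return bvals, bvecs


def write_bvals_bvecs(bvals, bvecs, bvals_path, bvecs_path):
    np.savetxt(bvals_path, np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, np.asarray(bvecs).T, fmt="%.8f")


def read_dwi(nifti_path):
    """Load a 4D DWI NIfTI; returns ``(data, affine)``."""
    img = nib.load(str(nifti_path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_nifti(data, path, affine=None):
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float)


def read_pli_stack(path):
    """Read a multipage TIFF PLI stack -> (H, W, n_angles) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 3:
        raise ValueError("expected a multipage TIFF (one page per analyser angle)")
    return np.moveaxis(arr, 0, -1).astype(float)


def write_pli_stack(intensities, path):
    """Write (H, W, n_angles) intensities as a multipage float32 TIFF."""
    tifffile.imwrite(str(path), np.moveaxis(intensities, -1, 0).astype(np.float32))


def write_map_tiff(arr, path):
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32))


def read_map_tiff(path):
    return tifffile.imread(str(path)).astype(float)


def read_mask(path):
    """Boolean mask from NIfTI or PNG/TIFF, by extension."""
    p = Path(path)
    if "".join(p.suffixes).endswith((".nii", ".nii.gz")) or p.suffix == ".nii":
        return read_nifti(p) > 0.5
    from imageio.v3 import imread

    return np.asarray(imread(p)) > 0
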