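"""Masked-volume ingestion, preprocessing contracts, and weight-map export.

Turns sets of 3-D NIfTI volumes (one per subject, one set per condition)
into the n x p matrices sparse CCA consumes: voxels inside a binary mask
become columns in C-order linear-index order of the mask grid (fixed and
documented, since the canonical-vector/image correspondence depends on it).

Preprocessing mirrors the perfusion-study pipeline downstream of spatial
normalization: per-scan mean scaling (subtract each scan's mean, removing
session effects) and per-subject subtraction of the control condition, after
which columns are standardized at ViewMatrix construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ViewMatrix, standardize_columns

__all__ = [
    "MaskedImageSet",
    "read_masked_set",
    "mean_scale",
    "mean_scale_set",
    "condition_contrast",
    "write_weight_map",
    "view_from_set",
    "read_matrix",
    "write_matrix",
]


@dataclass(frozen=True)
class MaskedImageSet:
    """Per-subject volumes reduced to an n_subjects x n_voxels matrix.

    ``voxel_index`` holds the C-order flat indices of in-mask voxels — column
    j of ``data`` is grid voxel ``voxel_index[j]``.  ``global_means`` are the
    whole-volume means recorded at read time, so mean scaling can optionally
    use all voxels instead of only in-mask ones.
    """

    mask: np.ndarray
    affine: np.ndarray
    header: object
    subject_ids: tuple[str, ...]
    data: np.ndarray
    voxel_index: np.ndarray
    global_means: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def read_masked_set(
    image_paths: list[str | Path],
    mask_path: str | Path,
    subject_ids: list[str] | None = None,
) -> MaskedImageSet:
    """Load per-subject volumes and reduce to in-mask columns.

    The mask is binarized at > 0.  Every volume must share the mask's grid
    shape; NaNs inside the mask are an error naming the offending file.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj, dtype=np.float64) > 0
    if mask.ndim != 3:
        raise ValueError(f"mask must be a 3-D volume, got shape {mask.shape}")
    voxel_index = np.flatnonzero(mask.ravel(order="C"))
    if voxel_index.size == 0:
        raise ValueError(f"empty mask: {mask_path}")

    if subject_ids is None:
        subject_ids = [Path(p).name.split(".nii")[0] for p in image_paths]
    if len(subject_ids) != len(image_paths):
        raise ValueError("subject_ids length must match image_paths")

    rows = []
    gmeans = []
    for path in image_paths:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.shape != mask.shape:
            raise ValueError(
                f"grid mismatch: {path} has shape {arr.shape}, mask {mask.shape}"
            )
        flat = arr.ravel(order="C")
        vals = flat[voxel_index]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values inside mask in {path}")
        rows.append(vals)
        finite = flat[np.isfinite(flat)]
        gmeans.append(float(finite.mean()) if finite.size else 0.0)

    return MaskedImageSet(
        mask=mask,
        affine=np.asarray(mask_img.affine),
        header=mask_img.header,
        subject_ids=tuple(subject_ids),
        data=np.asarray(rows),
        voxel_index=voxel_index,
        global_means=np.asarray(gmeans),
    )


def mean_scale(x: np.ndarray) -> np.ndarray:
    """Subtract each scan's (row's) mean, removing per-session offsets."""
    x = np.asarray(x, dtype=np.float64)
    return x - x.mean(axis=-1, keepdims=x.ndim > 1)


def mean_scale_set(mset: MaskedImageSet, use_global: bool = False) -> MaskedImageSet:
    """Mean-scale every subject's scan; by default the in-mask mean is
    subtracted (out-of-mask voxels are background), ``use_global`` uses the
    whole-volume mean recorded at read time instead."""
    if use_global:
        data = mset.data - mset.global_means[:, None]
    else:
        data = mean_scale(mset.data)
    return replace(mset, data=data)


def condition_contrast(
    active: MaskedImageSet,
    placebo: MaskedImageSet,
    *,
    use_global_mean: bool = False,
) -> MaskedImageSet:
    """Per-subject voxelwise difference (active - control) after mean
    scaling each scan; subjects are matched by id, order follows ``active``."""
    if active.mask.shape != placebo.mask.shape or not np.array_equal(
        active.voxel_index, placebo.voxel_index
    ):
        raise ValueError("condition sets must share the same mask")
    missing = [s for s in active.subject_ids if s not in placebo.subject_ids]
    extra = [s for s in placebo.subject_ids if s not in active.subject_ids]
    if missing or extra:
        raise ValueError(
            f"subject-id mismatch: missing from control {missing}, "
            f"unmatched in control {extra}"
        )
    a = mean_scale_set(active, use_global=use_global_mean)
    p = mean_scale_set(placebo, use_global=use_global_mean)
    order = [p.subject_ids.index(s) for s in a.subject_ids]
    diff = a.data - p.data[order]
    return replace(
        a, data=diff, global_means=np.zeros(len(a.subject_ids))
    )


def write_weight_map(u: np.ndarray, mset: MaskedImageSet, path: str | Path) -> Path:
    """Write a weight vector back to voxel space as a NIfTI volume:
    out-of-mask voxels are 0, affine/header come from the mask image.

    ``u`` must have one entry per in-mask voxel (re-inflate dropped columns
    with :func:`scca.core.inflate_weights` first)."""
    u = np.asarray(u, dtype=np.float64)
    if u.shape != (mset.n_voxels,):
        raise ValueError(
            f"weight length {u.shape[0]} != number of in-mask voxels {mset.n_voxels}"
        )
    vol = np.zeros(mset.mask.size)
    vol[mset.voxel_index] = u
    img = nib.Nifti1Image(vol.reshape(mset.mask.shape), mset.affine)
    nib.save(img, str(path))
    return Path(path)


def view_from_set(mset: MaskedImageSet) -> ViewMatrix:
    """Column-standardized view over in-mask voxels; feature ids are the
    voxel linear indices."""
    return standardize_columns(mset.data, feature_ids=mset.voxel_index)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited text matrix (TSV, rows = samples)."""
    return np.loadtxt(str(path), delimiter="\t", ndmin=2)


def write_matrix(X: np.ndarray, path: str | Path) -> Path:
    """Write a matrix as TSV with a stable float format."""
    np.savetxt(str(path), np.asarray(X), delimiter="\t", fmt="%.12g")
    return Path(path)
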