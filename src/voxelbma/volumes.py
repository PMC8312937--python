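"""Volume I/O, the analysis voxel mask, and atlas-region lookup.

The analysis consumes TBSS-style aligned FA volumes (one 3-D NIfTI per
subject or a single 4-D stack), a white-matter label atlas on the same
grid, and its label -> region-name lookup table. Coordinates are 0-based
array indices (i, j, k); spatial interpretation is delegated entirely to
the shared affine, and no resampling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

UNCLASSIFIED = "unclassified"
_AFFINE_TOL = 1e-4


@dataclass
class FAStack:
    """4-D (x, y, z, subject) stack of FA volumes on a common grid."""

    data: np.ndarray
    affine: np.ndarray
    subject_order: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("FA stack must be 4-D (x, y, z, subject)")
        if self.data.shape[3] != len(self.subject_order):
            raise ValueError("subject_order length != 4th-axis length")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("FA stack contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[3]


@dataclass
class AtlasVolume:
    """Integer label volume (0 = unlabeled) with a label -> name lookup."""

    labels: np.ndarray
    lookup: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"atlas labels missing from lookup: {sorted(missing)}")

    def region_names(self) -> list[str]:
        """All lookup names in ascending label order, then 'unclassified'."""
        names = [self.lookup[lab] for lab in sorted(self.lookup)]
        return names + [UNCLASSIFIED]


def load_fa_stack(
    source: Sequence[str | Path] | str | Path,
    covariates: pd.DataFrame | Sequence[str],
    subject_order: Sequence[str] | None = None,
) -> FAStack:
    """Load an FA stack, ordered exactly as the covariate table.

    ``source`` is either a list of single-subject 3-D volumes (one per
    covariate row, in table order) or one 4-D file accompanied by a
    ``subject_order`` sidecar list. Grids and affines must agree within
    1e-4; mismatches are rejected naming the offending file.
    """
    if isinstance(covariates, pd.DataFrame):
        expected_ids = [str(s) for s in covariates["subject_id"]]
    else:
        expected_ids = [str(s) for s in covariates]
    if len(set(expected_ids)) != len(expected_ids):
        raise ValueError("duplicate subject ids in covariate table")

    if isinstance(source, (str, Path)):
        img = nib.load(str(source))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{source}: expected a 4-D volume, got {data.ndim}-D")
        if subject_order is None:
            raise ValueError("a 4-D stack requires a subject_order sidecar")
        order = [str(s) for s in subject_order]
        if sorted(order) != sorted(expected_ids):
            raise ValueError("subject_order does not match the covariate table ids")
        if data.shape[3] != len(order):
            raise ValueError(
                f"{source}: 4th axis has {data.shape[3]} volumes, "
                f"subject_order lists {len(order)}"
            )
        # reorder the 4th axis into covariate-table order
        pos = {sid: i for i, sid in enumerate(order)}
        idx = [pos[sid] for sid in expected_ids]
        return FAStack(data=data[..., idx], affine=img.affine, subject_order=expected_ids)

    paths = [Path(p) for p in source]
    if len(paths) != len(expected_ids):
        raise ValueError(
            f"{len(paths)} volumes for {len(expected_ids)} covariate rows"
        )
    volumes, affine, shape = [], None, None
    for path, sid in zip(paths, expected_ids):
        img = nib.load(str(path))
        vol = np.asarray(img.get_fdata(), dtype=float)
        if vol.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D volume, got {vol.ndim}-D")
        if affine is None:
            affine, shape = img.affine, vol.shape
        else:
            if vol.shape != shape:
                raise ValueError(f"{path}: grid {vol.shape} != expected {shape}")
            if np.max(np.abs(img.affine - affine)) > _AFFINE_TOL:
                raise ValueError(f"{path}: affine differs beyond tolerance {_AFFINE_TOL}")
        volumes.append(vol)
    return FAStack(
        data=np.stack(volumes, axis=-1), affine=affine, subject_order=expected_ids
    )


def build_mask(
    stack: FAStack, fa_threshold: float = 0.2, black_rule: str = "any"
) -> tuple[np.ndarray, int]:
    """Analysis mask: drop black voxels and low-mean-FA voxels.

    A voxel is kept iff (a) no subject has FA exactly 0 there (black
    voxel removal) and (b) the across-subject mean FA is >= the
    threshold (default 0.2, below which there is little white matter).
    ``black_rule='all'`` switches (a) to the weaker reading that only
    voxels that are 0 in *every* subject are black.

    Returns ``(mask, n_retained)``.
    """
    if not 0 < fa_threshold < 1:
        raise ValueError(f"fa_threshold must be in (0, 1), got {fa_threshold}")
    if black_rule not in ("any", "all"):
        raise ValueError("black_rule must be 'any' or 'all'")
    zero = stack.data == 0
    black = zero.any(axis=3) if black_rule == "any" else zero.all(axis=3)
    mean_fa = stack.data.mean(axis=3)
    mask = (~black) & (mean_fa >= fa_threshold)
    return mask, int(mask.sum())


def voxels_to_regions(
    voxel_indices: Iterable[tuple[int, int, int]], atlas: AtlasVolume
) -> list[str]:
    """Map 0-based (i, j, k) voxel indices to atlas region names.

    Label 0 maps to the reserved name ``'unclassified'``.
    """
    names = []
    shape = atlas.labels.shape
    for ijk in voxel_indices:
        i, j, k = (int(c) for c in ijk)
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            raise IndexError(f"voxel {ijk} outside grid {shape}")
        lab = int(atlas.labels[i, j, k])
        if lab == 0:
            names.append(UNCLASSIFIED)
        else:
            try:
                names.append(atlas.lookup[lab])
            except KeyError:
                raise ValueError(f"atlas label {lab} missing from lookup") from None
    return names


# -- file round-trips ---------------------------------------------------------


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3-D or 4-D array as NIfTI-1; booleans are stored as uint8."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def load_atlas(
    labels_path: str | Path, lookup_path: str | Path
) -> tuple[AtlasVolume, np.ndarray]:
    """Load an atlas label volume plus its TSV lookup (columns label, region_name)."""
    img = nib.load(str(labels_path))
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    lookup = read_atlas_lookup(lookup_path)
    return AtlasVolume(labels=labels, lookup=lookup), img.affine


def read_atlas_lookup(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"label", "region_name"}.issubset(df.columns):
        raise ValueError(f"atlas lookup {path} needs columns label, region_name")
    lookup = dict(zip(df["label"].astype(int), df["region_name"].astype(str)))
    if len(lookup) != len(df):
        raise ValueError("duplicate labels in atlas lookup")
    if 0 in lookup:
        raise ValueError("label 0 is reserved for unlabeled voxels")
    return lookup


def write_atlas_lookup(lookup: dict[int, str], path: str | Path) -> None:
    pd.DataFrame(
        {"label": sorted(lookup), "region_name": [lookup[k] for k in sorted(lookup)]}
    ).to_csv(path, sep="\t", index=False)
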