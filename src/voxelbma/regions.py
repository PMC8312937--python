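"""Region x covariate summaries of significant voxels and coefficient signs.

Aggregates the per-covariate FDR-significant voxel sets onto the atlas:
counts per region (off-atlas voxels get their own 'unclassified' row so
column sums remain the covariate's xi), and the proportions of positive
and negative model-averaged coefficients among the significant voxels
of each region.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .fdr import FDRResult
from .volumes import UNCLASSIFIED, AtlasVolume, voxels_to_regions


def _region_index(atlas: AtlasVolume) -> list[str]:
    return atlas.region_names()


def count_significant_by_region(
    fdr_results: Sequence[FDRResult],
    atlas: AtlasVolume,
    voxel_coords: Sequence[Sequence[tuple[int, int, int]]],
) -> pd.DataFrame:
    """Counts of significant voxels per (region, covariate).

    ``voxel_coords[c]`` gives the (i, j, k) coordinate of each entry of
    ``fdr_results[c].significant_voxels``, aligned one-to-one. Returns a
    DataFrame indexed by region name (atlas order, then 'unclassified')
    with one integer column per covariate; ``df.attrs['value_kind']`` is
    ``'count'``. Column sums equal each covariate's xi.
    """
    if len(fdr_results) != len(voxel_coords):
        raise ValueError("one coordinate list per FDR result required")
    regions = _region_index(atlas)
    table = pd.DataFrame(
        0, index=pd.Index(regions, name="region"),
        columns=[r.covariate_name for r in fdr_results], dtype=int,
    )
    for res, coords in zip(fdr_results, voxel_coords):
        if len(coords) != res.xi:
            raise ValueError(
                f"{res.covariate_name}: {len(coords)} coordinates for xi={res.xi}"
            )
        for name in voxels_to_regions(coords, atlas):
            table.loc[name, res.covariate_name] += 1
    table.attrs["value_kind"] = "count"
    return table


def coefficient_sign_proportions(
    fdr_results: Sequence[FDRResult],
    coefficient_maps: np.ndarray,
    atlas: AtlasVolume,
    voxel_coords: Sequence[Sequence[tuple[int, int, int]]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractions of positive / negative averaged coefficients per cell.

    ``coefficient_maps`` is a 4-D (x, y, z, covariate) array of
    model-averaged coefficient means. Among the covariate-c significant
    voxels falling in region r, the positive (negative) table holds the
    fraction with coefficient > 0 (< 0); exact zeros count in neither,
    and cells with no significant voxels are NaN (absent). Returns
    ``(positive, negative)`` with ``attrs['value_kind'] = 'proportion'``.
    """
    coefficient_maps = np.asarray(coefficient_maps, dtype=float)
    if coefficient_maps.ndim != 4:
        raise ValueError("coefficient_maps must be (x, y, z, covariate)")
    if coefficient_maps.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"coefficient grid {coefficient_maps.shape[:3]} != "
            f"atlas grid {atlas.labels.shape}"
        )
    regions = _region_index(atlas)
    cols = [r.covariate_name for r in fdr_results]
    pos = pd.DataFrame(np.nan, index=pd.Index(regions, name="region"), columns=cols)
    neg = pos.copy()

    for c, (res, coords) in enumerate(zip(fdr_results, voxel_coords)):
        if len(coords) != res.xi:
            raise ValueError(
                f"{res.covariate_name}: {len(coords)} coordinates for xi={res.xi}"
            )
        names = voxels_to_regions(coords, atlas)
        by_region: dict[str, list[float]] = {}
        for (i, j, k), name in zip(coords, names):
            by_region.setdefault(name, []).append(coefficient_maps[i, j, k, c])
        for name, vals in by_region.items():
            vals_arr = np.asarray(vals)
            pos.loc[name, res.covariate_name] = float(np.mean(vals_arr > 0))
            neg.loc[name, res.covariate_name] = float(np.mean(vals_arr < 0))
    pos.attrs["value_kind"] = "proportion"
    neg.attrs["value_kind"] = "proportion"
    return pos, neg


def to_long_format(
    counts: pd.DataFrame, positive: pd.DataFrame, negative: pd.DataFrame
) -> pd.DataFrame:
    """Long-format (region, covariate, count, prop_pos, prop_neg) table."""
    long = counts.stack().rename("count").reset_index()
    long.columns = ["region", "covariate", "count"]
    long["prop_pos"] = [
        positive.loc[r, c] for r, c in zip(long["region"], long["covariate"])
    ]
    long["prop_neg"] = [
        negative.loc[r, c] for r, c in zip(long["region"], long["covariate"])
    ]
    return long
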