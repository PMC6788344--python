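"""Group-level relevance accumulation and atlas-based aggregation.

Two quantities drive the regional interpretation of the network:

* ``M_N(v)``: the sum over all test-set subjects, and over both sessions,
  of the absolute per-voxel relevance at voxel ``v``.
* ``M_r``: the sum of ``M_N`` over the voxels of atlas region ``r``,
  normalized by the region's voxel volume ``V_r``, removing the size bias
  that large regions would otherwise enjoy.

Regions are reported sorted by ``M_r`` descending; volume normalization
means a uniform relevance field scores every region identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import InputError
from .lrp import RelevanceMap
from .phantom import ToyAtlas
from .volume import Volume

__all__ = [
    "GroupRelevance",
    "RegionRelevanceTable",
    "accumulate",
    "aggregate_by_region",
    "top_regions",
]


@dataclass
class GroupRelevance:
    """Accumulated absolute relevance over subjects and sessions."""

    M_N: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        if np.any(self.M_N < 0):
            raise InputError("accumulated relevance must be non-negative")


@dataclass
class RegionRelevanceTable:
    """Per-region summed relevance, volume, normalized score, and rank."""

    table: pd.DataFrame  # columns: region_id, name, group, V_r, summed_relevance, M_r, M_r_scaled, rank

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(t["M_r"] * t["V_r"], t["summed_relevance"]):
            raise InputError("M_r * V_r must equal summed_relevance")
        if sorted(t["rank"]) != list(range(1, len(t) + 1)):
            raise InputError("ranks must be a permutation of 1..R")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def accumulate(maps: Sequence[RelevanceMap]) -> GroupRelevance:
    """M_N(v) = sum over subjects of |relevance_s1(v)| + |relevance_s2(v)|.

    Callers are responsible for passing test-set maps only.
    """
    maps = list(maps)
    if not maps:
        raise InputError("cannot accumulate an empty list of relevance maps")
    shape = maps[0].session1_relevance.shape
    M = np.zeros(shape, dtype=np.float64)
    for m in maps:
        if m.session1_relevance.shape != shape:
            raise InputError("all relevance maps must share one grid")
        M += np.abs(m.session1_relevance) + np.abs(m.session2_relevance)
    return GroupRelevance(M_N=M, n_subjects=len(maps))


def aggregate_by_region(
    group: GroupRelevance,
    atlas: ToyAtlas | Volume | np.ndarray,
    region_names: dict[int, str] | None = None,
    region_groups: dict[int, str] | None = None,
) -> RegionRelevanceTable:
    """Sum M_N within each atlas region and normalize by region volume V_r.

    Accepts a ToyAtlas, an integer-label Volume, or a raw label array
    (background label 0 excluded).  Regions with zero volume are excluded
    with a warning.  Rows are sorted by M_r descending, ties broken by
    region id ascending.
    """
    if isinstance(atlas, ToyAtlas):
        labels = np.asarray(atlas.labels.data)
        region_names = region_names or atlas.region_names
        region_groups = region_groups or atlas.region_groups
    elif isinstance(atlas, Volume):
        labels = np.asarray(atlas.data)
    else:
        labels = np.asarray(atlas)
    labels = np.rint(labels).astype(int)
    if labels.shape != group.M_N.shape:
        raise InputError(
            f"atlas grid {labels.shape} does not match relevance grid {group.M_N.shape}"
        )
    region_names = region_names or {}
    region_groups = region_groups or {}
    ids = sorted(set(np.unique(labels)) - {0})
    rows = []
    for r in ids:
        sel = labels == r
        v_r = int(sel.sum())
        if v_r == 0:  # can only happen with an explicit but absent id
            warnings.warn(f"region {r} has zero volume; excluded", stacklevel=2)
            continue
        summed = float(group.M_N[sel].sum())
        rows.append(
            {
                "region_id": int(r),
                "name": region_names.get(r, f"region-{r:02d}"),
                "group": region_groups.get(r, ""),
                "V_r": v_r,
                "summed_relevance": summed,
                "M_r": summed / v_r,
            }
        )
    if not rows:
        raise InputError("atlas labels contain no non-background regions")
    df = pd.DataFrame(rows)
    df = df.sort_values(["M_r", "region_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    peak = df["M_r"].max()
    df["M_r_scaled"] = df["M_r"] / peak if peak > 0 else 0.0
    return RegionRelevanceTable(df.reset_index(drop=True))


def top_regions(table: RegionRelevanceTable, k: int) -> pd.DataFrame:
    """First k rows by M_r descending (ties by region id ascending)."""
    if k > len(table):
        raise InputError(f"k={k} exceeds the {len(table)} available regions")
    return table.table.head(k).copy()
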