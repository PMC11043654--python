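"""Stepwise functional connectivity: seed partition, walk-count maps, argmax.

Stepwise functional connectivity (SFC) of node j at link-step k is the number
of length-k *walks* from any seed node to j in the binary functional graph,
i.e. ``sum_{s in seed} (A^k)_{sj}``.  Walks -- not simple paths -- are the
operative definition in the stepwise-connectivity literature; they are what
makes the computation tractable (iterated vector-matrix products, never
materializing A^k).  Step 1 is direct connectivity; steps 2-4 are indirect
routes.  Maps are computed up to four steps, where SFC topography stabilizes.

Because raw counts grow combinatorially with k, maps are z-scored per step
over the analysis mask (seed nodes excluded) before any cross-step comparison
or group statistics; raw counts are retained for exact oracle checks.

The caudate seed is bilateral (left + right pooled).  Its medial component is
the set of caudate voxels face-adjacent (6-connectivity by default, the
strictest reading of adjacency) to the ventricle mask -- the wall facing the
subventricular zone -- and the lateral component is the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import BinaryGraph
from .io import CAUDATE_CLASSES, LabelVolume, NodeTable, build_node_table

__all__ = [
    "SeedSet",
    "SFCMapSet",
    "partition_caudate",
    "whole_caudate_seed",
    "sfc_maps",
    "zscore_maps",
    "average_maps",
    "combined_map",
    "region_reduce",
    "NEIGHBOR_OFFSETS",
]


def _offsets(connectivity: int) -> np.ndarray:
    """Voxel neighbourhood offsets for 6-, 18- or 26-connectivity."""
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs)


NEIGHBOR_OFFSETS = {c: _offsets(c) for c in (6, 18, 26)}


@dataclass(frozen=True)
class SeedSet:
    """A named, nonempty set of graph node indices used as the SFC seed."""

    nodes: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=int)
        if nodes.ndim != 1 or nodes.size == 0:
            raise ValueError(f"seed {self.name!r} must be a nonempty 1D index set")
        if len(np.unique(nodes)) != nodes.size:
            raise ValueError(f"seed {self.name!r} has duplicate node indices")
        object.__setattr__(self, "nodes", nodes)

    def __len__(self) -> int:
        return self.nodes.size


@dataclass
class SFCMapSet:
    """Per-node SFC values at steps 1..max_step for one graph and one seed.

    ``normalization`` is "raw_counts" (non-negative integers) or "zscore"
    (per-step mean 0 / sd 1 over the analysis mask, seed entries NaN).
    """

    steps: dict[int, np.ndarray]
    seed: SeedSet
    normalization: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.normalization not in ("raw_counts", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        ks = sorted(self.steps)
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError(f"steps must be contiguous from 1, got {ks}")

    @property
    def max_step(self) -> int:
        return max(self.steps)

    @property
    def n_nodes(self) -> int:
        return len(next(iter(self.steps.values())))

    def as_matrix(self) -> np.ndarray:
        """(max_step, n_nodes) array of the per-step maps."""
        return np.stack([self.steps[k] for k in range(1, self.max_step + 1)])


def partition_caudate(
    atlas: LabelVolume,
    connectivity: int = 6,
    node_table: NodeTable | None = None,
) -> tuple[SeedSet, SeedSet]:
    """Split the bilateral caudate into medial (ventricle-adjacent) and lateral seeds.

    A caudate voxel is medial iff at least one neighbour under the chosen
    connectivity is labelled ventricle; both hemispheres are pooled.  Returns
    (medial, lateral) as node-index sets over ``node_table`` (built from the
    atlas when not supplied).
    """
    offsets = NEIGHBOR_OFFSETS[connectivity] if connectivity in NEIGHBOR_OFFSETS else _offsets(connectivity)
    if node_table is None:
        node_table = build_node_table(atlas)
    caud_mask = atlas.mask_of_class(*CAUDATE_CLASSES)
    vent_mask = atlas.mask_of_class("ventricle")
    if not caud_mask.any():
        raise ValueError("atlas contains no caudate voxels")
    if not vent_mask.any():
        raise ValueError("atlas contains no ventricle voxels")
    shape = atlas.labels.shape
    coords = np.argwhere(caud_mask)
    medial_vox = np.zeros(len(coords), dtype=bool)
    for off in offsets:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        hit = np.zeros(len(coords), dtype=bool)
        hit[ok] = vent_mask[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
        medial_vox |= hit
    vox_index = node_table.index_of_voxel()
    caud_nodes = np.array([vox_index[tuple(c)] for c in coords])
    medial = caud_nodes[medial_vox]
    lateral = caud_nodes[~medial_vox]
    if medial.size == 0:
        raise ValueError("degenerate geometry: no caudate voxel is adjacent to the ventricles")
    if lateral.size == 0:
        raise ValueError("degenerate geometry: every caudate voxel is adjacent to the ventricles")
    return (
        SeedSet(np.sort(medial), "medial_caudate"),
        SeedSet(np.sort(lateral), "lateral_caudate"),
    )


def whole_caudate_seed(atlas: LabelVolume, node_table: NodeTable | None = None) -> SeedSet:
    if node_table is None:
        node_table = build_node_table(atlas)
    nodes = node_table.nodes_of_class(*CAUDATE_CLASSES)
    return SeedSet(nodes, "whole_caudate")


def sfc_maps(graph: BinaryGraph, seed: SeedSet, max_step: int = 4) -> SFCMapSet:
    """Raw walk-count SFC maps at steps 1..max_step.

    step-k value of node j = number of length-k walks from any seed node to j,
    computed by iterated vector-matrix products (A^k is never formed).
    """
    if max_step < 1:
        raise ValueError(f"max_step must be >= 1, got {max_step}")
    n = graph.n_nodes
    if seed.nodes.min() < 0 or seed.nodes.max() >= n:
        raise ValueError(f"seed {seed.name!r} has node indices outside 0..{n - 1}")
    v = np.zeros(n)
    v[seed.nodes] = 1.0
    steps: dict[int, np.ndarray] = {}
    for k in range(1, max_step + 1):
        v = v @ graph.adjacency
        steps[k] = v.copy()
    return SFCMapSet(steps, seed, "raw_counts")


def zscore_maps(maps: SFCMapSet, mask: np.ndarray | None = None) -> SFCMapSet:
    """Z-score each step map over the analysis mask, excluding seed nodes.

    Seed entries are set to NaN: their values are dominated by local degree
    and are excluded from normalization and from all group statistics.  A
    step whose masked values are constant z-scores to all-zero.
    """
    if maps.normalization == "zscore":
        return maps
    n = maps.n_nodes
    m = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).copy()
    m[maps.seed.nodes] = False
    if not m.any():
        raise ValueError("empty analysis mask after excluding seed nodes")
    out: dict[int, np.ndarray] = {}
    for k, vals in maps.steps.items():
        mu = vals[m].mean()
        sd = vals[m].std()
        z = np.full(n, np.nan)
        z[m] = 0.0 if sd == 0 else (vals[m] - mu) / sd
        out[k] = z
    return SFCMapSet(out, maps.seed, "zscore")


def average_maps(maps: list[SFCMapSet]) -> SFCMapSet:
    """Element-wise mean of same-shaped map sets (e.g. the young-group average)."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.normalization != first.normalization:
            raise ValueError("cannot average maps with mixed normalizations")
        if m.seed.name != first.seed.name:
            raise ValueError("cannot average maps with different seeds")
        if m.n_nodes != first.n_nodes or m.max_step != first.max_step:
            raise ValueError("maps do not share a node space / step range")
    out = {
        k: np.mean([m.steps[k] for m in maps], axis=0) for k in range(1, first.max_step + 1)
    }
    return SFCMapSet(out, first.seed, first.normalization)


def combined_map(maps: SFCMapSet) -> np.ndarray:
    """Per-node step index (1-4) at which SFC is maximal; the combined SFC map.

    1 = functionally closest to the seed, 4 = most distant.  Ties break to the
    smallest step; nodes with all-zero SFC across steps (or NaN seed entries)
    get the 0 sentinel.
    """
    if maps.max_step < 4:
        raise ValueError("combined map requires steps 1-4")
    stacked = maps.as_matrix()
    with np.errstate(invalid="ignore"):
        arg = np.nanargmax(np.nan_to_num(stacked, nan=-np.inf), axis=0) + 1
    degenerate = np.all((stacked == 0) | np.isnan(stacked), axis=0)
    arg[degenerate] = 0
    return arg.astype(np.int32)


def region_reduce(
    values: np.ndarray,
    node_table: NodeTable,
    region_labels: list[int] | None = None,
) -> "pd.Series":
    """Mean per-node value within each atlas region (voxel -> region reduction).

    NaN node values (seed exclusions) are dropped from the mean; a region that
    is empty or all-NaN raises.  The returned Series is keyed by region name in
    atlas label order, matching RegionalTable region order for downstream joins.
    """
    import pandas as pd

    values = np.asarray(values, dtype=float)
    if region_labels is None:
        region_labels = node_table.atlas.labels_of_class("cortical_parcel", "subcortical_parcel")
    names, means = [], []
    for label in region_labels:
        nodes = node_table.nodes_with_label(label)
        name = node_table.atlas.dictionary[label].name
        if nodes.size == 0:
            raise ValueError(f"region {name!r} has no voxels in the atlas")
        vals = values[nodes]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"region {name!r} has no finite node values to reduce")
        names.append(name)
        means.append(vals.mean())
    return pd.Series(means, index=names, name="regional_value")
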