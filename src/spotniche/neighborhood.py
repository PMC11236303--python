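"""Hex-lattice spot adjacency and the four-way nearby classification.

Non-tumor spots are classed by which tumor marker-groups they touch:
nearby_pos (adjacent to marker-positive tumor only), nearby_neg (negative
only), nearby_both, or nearby_none. "Other" tumor spots (necrotic) never
confer nearby status, consistent with their exclusion from group statistics.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import SpotTable
from .spot_annotation import AnnotationError, SpotAnnotation

# ring-1 neighborhood on the even-parity offset hex lattice
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class AdjacencyGraph:
    """Undirected spot adjacency; symmetric, no self-edges."""

    neighbors: dict[str, set[str]]
    mode: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, nbrs in self.neighbors.items():
            if a in nbrs:
                raise ValueError(f"self-edge at {a!r}")
            for b in nbrs:
                if a not in self.neighbors.get(b, set()):
                    raise ValueError(f"asymmetric edge {a!r} -> {b!r}")

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, nbrs in self.neighbors.items() for b in nbrs}

    def edge_records(self):
        pairs = sorted(tuple(sorted(e)) for e in self.edge_set())
        return [{"spot_a": a, "spot_b": b} for a, b in pairs]

    def degree(self, spot: str) -> int:
        return len(self.neighbors[spot])


def build_adjacency(
    spot_table: SpotTable,
    mode: str = "array_hex",
    ring: int = 1,
    distance_factor: float = 1.3,
) -> AdjacencyGraph:
    """Build the spot adjacency graph.

    array_hex: ring-1 neighbors of (r, c) are {(r, c±2), (r±1, c±1)}; ring k
    is the k-fold closure (graph distance <= k on the ring-1 graph).
    pixel_distance: spots closer than distance_factor x the median
    nearest-neighbor pixel distance are adjacent.
    """
    f = spot_table.frame
    ids = f["spot_id"].tolist()
    if mode == "array_hex":
        if ring < 1:
            raise ValueError("ring must be >= 1")
        coord_of = {}
        for sid, r, c in zip(ids, f["array_row"], f["array_col"]):
            key = (int(r), int(c))
            if key in coord_of:
                raise ValueError(f"duplicate array coordinate {key}")
            coord_of[key] = sid
        ring1: dict[str, set[str]] = {sid: set() for sid in ids}
        for (r, c), sid in coord_of.items():
            for dr, dc in HEX_OFFSETS:
                other = coord_of.get((r + dr, c + dc))
                if other is not None:
                    ring1[sid].add(other)
        if ring == 1:
            neighbors = ring1
        else:
            neighbors = {sid: _within_k(ring1, sid, ring) for sid in ids}
        params = {"ring": ring}
    elif mode == "pixel_distance":
        xy = f[["pixel_x", "pixel_y"]].to_numpy(float)
        neighbors = {sid: set() for sid in ids}
        if len(ids) > 1:
            tree = cKDTree(xy)
            nn_dist, _ = tree.query(xy, k=2)
            cutoff = distance_factor * float(np.median(nn_dist[:, 1]))
            for i, j in tree.query_pairs(cutoff):
                if np.hypot(*(xy[i] - xy[j])) < cutoff:
                    neighbors[ids[i]].add(ids[j])
                    neighbors[ids[j]].add(ids[i])
        params = {"distance_factor": distance_factor}
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    return AdjacencyGraph(neighbors, mode, params)


def _within_k(ring1: dict[str, set[str]], start: str, k: int) -> set[str]:
    seen = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if seen[node] == k:
            continue
        for nbr in ring1[node]:
            if nbr not in seen:
                seen[nbr] = seen[node] + 1
                queue.append(nbr)
    seen.pop(start)
    return set(seen)


def classify_nearby(annotation: SpotAnnotation, graph: AdjacencyGraph) -> SpotAnnotation:
    """Fill nearby_group for every non-tumor spot from adjacent tumor groups.

    Let P / N be the counts of adjacent tumor spots called pos / neg ('other'
    tumor spots are ignored). P>0,N=0 -> nearby_pos; P=0,N>0 -> nearby_neg;
    P>0,N>0 -> nearby_both; P=0,N=0 -> nearby_none.
    """
    t = annotation.table
    missing = [s for s in t.index if s not in graph.neighbors]
    if missing:
        raise AnnotationError(f"graph does not cover spot(s) {missing[:5]}")
    unresolved = t[(t["region"] == "tumor") & ~t["tumor_group"].isin({"pos", "neg", "other"})]
    if len(unresolved):
        raise AnnotationError(
            f"unresolved tumor_group for tumor spot(s) {list(unresolved.index[:5])}"
        )
    table = t.copy()
    tumor_group = t["tumor_group"]
    is_tumor = t["region"] == "tumor"
    for sid in t.index:
        if is_tumor[sid]:
            table.at[sid, "nearby_group"] = "not_applicable"
            continue
        p = n = 0
        for nbr in graph.neighbors[sid]:
            if nbr in tumor_group.index and is_tumor[nbr]:
                g = tumor_group[nbr]
                if g == "pos":
                    p += 1
                elif g == "neg":
                    n += 1
        if p and n:
            label = "nearby_both"
        elif p:
            label = "nearby_pos"
        elif n:
            label = "nearby_neg"
        else:
            label = "nearby_none"
        table.at[sid, "nearby_group"] = label
    return SpotAnnotation(table)


NEARBY_CENSUS_CATEGORIES = (
    "nearby_pos",
    "nearby_neg",
    "nearby_both",
    "nearby_none",
    "not_applicable",
)


def nearby_census(annotation: SpotAnnotation) -> dict[str, int]:
    """Counts per nearby category (tumor spots fall under not_applicable)."""
    counts = {c: 0 for c in NEARBY_CENSUS_CATEGORIES}
    for v in annotation.table["nearby_group"]:
        if v == "unclassified":
            raise AnnotationError("census before classify_nearby")
        counts[v] += 1
    return counts
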