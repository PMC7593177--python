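"""Zone delineation from a trained map: cluster codebooks, pick k, map cells.

The node codebook vectors are clustered by complete-linkage agglomeration on
Euclidean distances; the number of zones is the k in [k_min, k_max] that
maximizes the mean silhouette of the node partition.  Cells inherit the
cluster of their best-matching node, then the zone map is spatially cleaned:
unsurveyed cells take the modal label of their eight neighbors (iterated,
synchronous), and designated island groups are homogenized to their own
modal observed label.  All tie-breaks resolve to the smallest label or index
so every step is deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .grid import GridSpec, PresenceAbsenceMatrix
from .som import SOMFit, SOMModel

log = logging.getLogger(__name__)

PROV_UNASSIGNED = "unassigned"
PROV_OBSERVED = "observed"
PROV_IMPUTED = "imputed"
PROV_ISLAND = "island-rule"

#: Zone label of unassigned cells.
UNASSIGNED = 0


@dataclass
class MergeTree:
    """Agglomeration history: (left_id, right_id, height, size) per merge.

    Ids 0..n-1 are leaves; merge ``m`` creates id ``n + m``.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]


@dataclass
class KSelection:
    """Mean silhouette per candidate k and the selected k (smallest maximizer)."""

    ks: list[int]
    silhouettes: list[float]
    k_star: int


@dataclass
class ZoneMap:
    """Per-cell zone label (0 = unassigned) with provenance."""

    labels: np.ndarray
    provenance: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != UNASSIGNED

    @property
    def zones(self) -> list[int]:
        return sorted(int(z) for z in np.unique(self.labels[self.assigned]))

    def copy(self) -> "ZoneMap":
        return ZoneMap(self.labels.copy(), self.provenance.copy(), self.grid)


def codebook_distances(model: SOMModel) -> np.ndarray:
    """Condensed (i<j ordered) Euclidean distances between codebook vectors."""
    return pdist(model.codebook, metric="euclidean")


def complete_linkage(dist: np.ndarray) -> MergeTree:
    """Naive agglomerative clustering with complete (maximum) linkage.

    At each step the pair of active clusters at minimal complete-linkage
    distance merges; ties break to the smallest (left_id, right_id).  The
    O(n^3) formulation is exact and fine for codebooks of <=100 nodes.
    """
    dist = np.asarray(dist, dtype=float)
    m = dist.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n < 2 or n * (n - 1) // 2 != m:
        raise ValueError("need condensed distances for >=2 items")
    D = {}  # (a, b) with a < b -> complete-linkage distance
    sq = squareform(dist)
    for a in range(n):
        for b in range(a + 1, n):
            D[(a, b)] = float(sq[a, b])
    active = {i: 1 for i in range(n)}  # id -> cluster size
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        (a, b) = min(D, key=lambda p: (D[p], p))
        h = D[(a, b)]
        size = active[a] + active[b]
        merges.append((a, b, h, size))
        del active[a], active[b]
        new_D = {}
        for (p, q), d in D.items():
            if a in (p, q) or b in (p, q):
                continue
            new_D[(p, q)] = d
        for o in active:
            da = D[(min(a, o), max(a, o))]
            db = D[(min(b, o), max(b, o))]
            new_D[(min(o, next_id), max(o, next_id))] = max(da, db)
        active[next_id] = size
        D = new_D
        next_id += 1
    return MergeTree(n_leaves=n, merges=merges)


def cut_tree(tree: MergeTree, k: int) -> np.ndarray:
    """Labels 1..k after undoing the last k-1 merges.

    Clusters are numbered by the order their first member appears when
    scanning items 0..n-1.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b, _h, _s) in enumerate(tree.merges[: n - k]):
        new = n + m
        parent[find(a)] = new
        parent[find(b)] = new

    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in mapping:
            mapping[root] = len(mapping) + 1
        labels[i] = mapping[root]
    return labels


def silhouette_mean(dist: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette width of a partition, from condensed distances.

    For item i, a(i) is its mean distance to its own cluster (excluding
    itself) and b(i) the smallest mean distance to any other cluster;
    s(i) = (b - a) / max(a, b).  Singleton clusters contribute s(i) = 0.
    """
    labels = np.asarray(labels)
    sq = squareform(np.asarray(dist, dtype=float))
    n = sq.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels length inconsistent with distances")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = np.zeros(n)
    members = {u: np.flatnonzero(labels == u) for u in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0
            continue
        a = sq[i, own].sum() / (own.size - 1)
        b = min(sq[i, members[u]].mean() for u in uniq if u != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def select_k(
    tree: MergeTree, dist: np.ndarray, k_min: int = 2, k_max: int = 15
) -> KSelection:
    """Silhouette scan over the tree's partitions; smallest maximizer wins."""
    if not (2 <= k_min <= k_max <= tree.n_leaves):
        raise ValueError("invalid k range")
    ks = list(range(k_min, k_max + 1))
    sils = [silhouette_mean(dist, cut_tree(tree, k)) for k in ks]
    k_star = ks[int(np.argmax(sils))]  # argmax returns first = smallest k
    return KSelection(ks=ks, silhouettes=sils, k_star=k_star)


def cells_to_zones(
    fit: SOMFit, node_labels: Sequence[int], pa: PresenceAbsenceMatrix
) -> ZoneMap:
    """Each surveyed cell inherits the cluster label of its BMU node."""
    node_labels = np.asarray(node_labels, dtype=int)
    if node_labels.shape != (fit.model.n_nodes,):
        raise ValueError("node_labels must cover every node")
    labels = np.full(pa.grid.n_cells, UNASSIGNED, dtype=int)
    prov = np.full(pa.grid.n_cells, PROV_UNASSIGNED, dtype=object)
    surveyed = np.flatnonzero(pa.surveyed)
    labels[surveyed] = node_labels[fit.cell_to_node[surveyed]]
    prov[surveyed] = PROV_OBSERVED
    return ZoneMap(labels=labels, provenance=prov, grid=pa.grid)


def _moore_neighbors(cell: int, grid: GridSpec) -> list[int]:
    r, c = grid.cell_rowcol(cell)
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                out.append(rr * grid.n_cols + cc)
    return out


def impute_empty_cells(zm: ZoneMap) -> ZoneMap:
    """Fill unassigned cells from their eight neighbors' modal label.

    Passes are synchronous (all fills in a pass read the pass-start state)
    and repeat until a fixed point; ties go to the smallest label.  Cells
    with no assigned neighbor in any reachable pass stay unassigned.
    """
    if not zm.assigned.any():
        raise ValueError("zone map has no assigned cells")
    out = zm.copy()
    while True:
        labels0 = out.labels.copy()
        changed = False
        for cell in np.flatnonzero(labels0 == UNASSIGNED):
            neigh = [labels0[nb] for nb in _moore_neighbors(cell, zm.grid)]
            neigh = [l for l in neigh if l != UNASSIGNED]
            if not neigh:
                continue
            counts: dict[int, int] = {}
            for l in neigh:
                counts[l] = counts.get(l, 0) + 1
            best = min(counts, key=lambda l: (-counts[l], l))
            out.labels[cell] = best
            out.provenance[cell] = PROV_IMPUTED
            changed = True
        if not changed:
            return out


def apply_island_rule(
    zm: ZoneMap, island_cells: Mapping[str, Sequence[int]]
) -> ZoneMap:
    """Homogenize each named island group to its own modal observed label.

    Islands far from the mainland grid can pick up unstable labels; within
    each group every member cell is reassigned to the most frequent label
    among the group's own observed (surveyed) cells, ties to the smallest
    label.  Groups with no observed member are left untouched with a
    warning.  Cells outside the groups are never altered.
    """
    out = zm.copy()
    seen: set[int] = set()
    for name, cells in island_cells.items():
        cells = [int(c) for c in cells]
        if seen.intersection(cells):
            raise ValueError(f"island group {name!r} overlaps another group")
        seen.update(cells)
        observed = [
            zm.labels[c]
            for c in cells
            if zm.provenance[c] == PROV_OBSERVED and zm.labels[c] != UNASSIGNED
        ]
        if not observed:
            log.warning("island group %r has no surveyed cells; left untouched", name)
            continue
        counts: dict[int, int] = {}
        for l in observed:
            counts[int(l)] = counts.get(int(l), 0) + 1
        mode = min(counts, key=lambda l: (-counts[l], l))
        for c in cells:
            out.labels[c] = mode
            out.provenance[c] = PROV_ISLAND
    return out


def relabel_by_area(zm: ZoneMap) -> ZoneMap:
    """Renumber zones 1..k by descending assigned cell count (ties: old label)."""
    out = zm.copy()
    zones = zm.zones
    counts = {z: int((zm.labels == z).sum()) for z in zones}
    order = sorted(zones, key=lambda z: (-counts[z], z))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    for old, new in mapping.items():
        out.labels[zm.labels == old] = new
    return out


# -- exports ---------------------------------------------------------------


def zone_map_to_csv(zm: ZoneMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "row", "col", "label", "provenance"])
        for cell in range(zm.grid.n_cells):
            r, c = zm.grid.cell_rowcol(cell)
            w.writerow([cell, r, c, int(zm.labels[cell]), zm.provenance[cell]])


def zone_map_from_csv(path: str | Path, grid: GridSpec) -> ZoneMap:
    labels = np.full(grid.n_cells, UNASSIGNED, dtype=int)
    prov = np.full(grid.n_cells, PROV_UNASSIGNED, dtype=object)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cell = int(row["cell_id"])
            labels[cell] = int(row["label"])
            prov[cell] = row["provenance"]
    return ZoneMap(labels=labels, provenance=prov, grid=grid)


def merge_tree_to_csv(tree: MergeTree, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "left_id", "right_id", "height", "size"])
        for i, (a, b, h, s) in enumerate(tree.merges):
            w.writerow([i, a, b, repr(h), s])


def selection_to_csv(sel: KSelection, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["k", "mean_silhouette", "selected"])
        for k, s in zip(sel.ks, sel.silhouettes):
            w.writerow([k, repr(s), int(k == sel.k_star)])
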