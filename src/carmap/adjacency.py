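"""Queen-contiguity spatial neighbour structures and GAL file interchange.

Two regions are Queen neighbours when their boundaries share at least one
point — an edge or a single corner. All neighbour pairs carry equal weight,
matching the convention of first-order contiguity disease-mapping models.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape
from shapely.strtree import STRtree

#: Coordinates are snapped to this grid before contiguity testing, so
#: boundaries that agree to well below any meaningful map precision register
#: as shared.
SNAP = 1e-9


@dataclass
class NeighborStructure:
    """Symmetric adjacency lists over an ordered set of regions.

    ``neighbors[i]`` holds the integer indices of the neighbours of region
    ``region_ids[i]``; every pair carries weight 1.
    """

    region_ids: list[str]
    neighbors: list[np.ndarray]

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(sorted(n), dtype=np.int64) for n in self.neighbors]

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    def validate(self) -> None:
        """Raise ValueError on self-loops or asymmetric pairs."""
        if len(self.neighbors) != self.n:
            raise ValueError("neighbors length does not match region_ids")
        sets = [set(nb.tolist()) for nb in self.neighbors]
        for i, nbrs in enumerate(sets):
            if i in nbrs:
                raise ValueError(f"region {self.region_ids[i]} lists itself as neighbour")
            for j in nbrs:
                if not (0 <= j < self.n):
                    raise ValueError(f"neighbour index {j} out of range")
                if i not in sets[j]:
                    raise ValueError(
                        "asymmetric adjacency: "
                        f"{self.region_ids[i]} -> {self.region_ids[j]} has no reverse"
                    )

    def component_labels(self) -> np.ndarray:
        """Connected-component label per region (BFS)."""
        labels = np.full(self.n, -1, dtype=np.int64)
        comp = 0
        for start in range(self.n):
            if labels[start] >= 0:
                continue
            queue = deque([start])
            labels[start] = comp
            while queue:
                i = queue.popleft()
                for j in self.neighbors[i]:
                    if labels[j] < 0:
                        labels[j] = comp
                        queue.append(j)
            comp += 1
        return labels

    def n_components(self) -> int:
        return int(self.component_labels().max()) + 1

    def to_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) flattened adjacency, for numeric kernels."""
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(self.degrees())
        indices = (
            np.concatenate(self.neighbors)
            if self.n and indptr[-1] > 0
            else np.zeros(0, dtype=np.int64)
        )
        return indptr, indices.astype(np.int64)

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (the ICAR precision scaffold)."""
        lap = np.zeros((self.n, self.n))
        for i, nbrs in enumerate(self.neighbors):
            lap[i, i] = len(nbrs)
            lap[i, nbrs] = -1.0
        return lap

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeighborStructure):
            return NotImplemented
        return self.region_ids == other.region_ids and all(
            np.array_equal(a, b) for a, b in zip(self.neighbors, other.neighbors)
        )


def _snap(geom, grid: float = SNAP):
    return shapely.transform(geom, lambda c: np.round(c / grid) * grid)


def queen_adjacency(region_ids: list[str], polygons: list) -> NeighborStructure:
    """Queen-contiguity structure from region polygons.

    Boundaries sharing at least one point (after snapping coordinates to a
    1e-9 grid) make two regions neighbours. Polygons are assumed to tile the
    plane without overlapping interiors.
    """
    if len(set(region_ids)) != len(region_ids):
        dupes = sorted({r for r in region_ids if region_ids.count(r) > 1})
        raise ValueError(f"duplicate region ids: {dupes}")
    if len(region_ids) != len(polygons):
        raise ValueError("region_ids and polygons differ in length")
    geoms = [_snap(shape(g) if isinstance(g, dict) else g) for g in polygons]
    for rid, g in zip(region_ids, geoms):
        if not g.is_valid:
            raise ValueError(f"invalid polygon for region {rid}")
    tree = STRtree(geoms)
    left, right = tree.query(np.array(geoms, dtype=object), predicate="intersects")
    nbrs: list[set[int]] = [set() for _ in region_ids]
    for i, j in zip(left, right):
        if i != j:
            nbrs[int(i)].add(int(j))
            nbrs[int(j)].add(int(i))
    return NeighborStructure(list(region_ids), [np.array(sorted(s)) for s in nbrs])


def queen_from_geojson(path: str | Path) -> NeighborStructure:
    """Queen adjacency from a GeoJSON FeatureCollection with region_id props."""
    with open(path) as fh:
        fc = json.load(fh)
    ids = [f["properties"]["region_id"] for f in fc["features"]]
    geoms = [f["geometry"] for f in fc["features"]]
    return queen_adjacency(ids, geoms)


def write_gal(ns: NeighborStructure, path: str | Path) -> None:
    """Write the GeoDa GAL dialect: count header, then id/degree + neighbour lines."""
    ns.validate()
    lines = [str(ns.n)]
    for i, rid in enumerate(ns.region_ids):
        nbrs = ns.neighbors[i]
        lines.append(f"{rid} {len(nbrs)}")
        lines.append(" ".join(ns.region_ids[j] for j in nbrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path: str | Path) -> NeighborStructure:
    """Parse a GAL file; malformed content raises ValueError naming the line."""
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ValueError(f"{path}: empty GAL file")
    header = raw[0].split()
    # GeoDa also writes a 4-token "0 n shapefile key" header; the count is
    # then the second token.
    try:
        n = int(header[0]) if len(header) == 1 else int(header[1])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: malformed header {raw[0]!r}") from None
    ids: list[str] = []
    nbr_names: list[list[str]] = []
    ln = 1
    for _ in range(n):
        if ln >= len(raw):
            raise ValueError(f"{path}: truncated after line {ln}")
        head = raw[ln].split()
        if len(head) != 2:
            raise ValueError(f"{path}: line {ln + 1}: expected 'id degree', got {raw[ln]!r}")
        rid, deg_s = head
        try:
            deg = int(deg_s)
        except ValueError:
            raise ValueError(f"{path}: line {ln + 1}: bad degree {deg_s!r}") from None
        ln += 1
        if deg > 0:
            if ln >= len(raw):
                raise ValueError(f"{path}: truncated neighbour line for {rid}")
            names = raw[ln].split()
            ln += 1
        else:
            names = []
            # tolerate an explicit empty line for degree-0 regions
            if ln < len(raw) and raw[ln].strip() == "":
                ln += 1
        if len(names) != deg:
            raise ValueError(
                f"{path}: line {ln}: region {rid} declares {deg} neighbours, lists {len(names)}"
            )
        ids.append(rid)
        nbr_names.append(names)
    if len(ids) != n:
        raise ValueError(f"{path}: header declares {n} regions, found {len(ids)}")
    index = {rid: i for i, rid in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError(f"{path}: duplicate region ids")
    neighbors = []
    for rid, names in zip(ids, nbr_names):
        try:
            neighbors.append(np.array(sorted(index[nm] for nm in names), dtype=np.int64))
        except KeyError as exc:
            raise ValueError(f"{path}: region {rid} lists unknown neighbour {exc}") from None
    ns = NeighborStructure(ids, neighbors)
    ns.validate()  # raises on asymmetric file content, naming the pair
    return ns


@dataclass(frozen=True)
class NeighborSummary:
    median_degree: float
    min_degree: int
    max_degree: int
    n_components: int


def neighbor_summary(ns: NeighborStructure) -> NeighborSummary:
    """Degree order statistics and connected-component count."""
    if ns.n == 0:
        raise ValueError("empty neighbour structure")
    deg = ns.degrees()
    return NeighborSummary(
        median_degree=float(np.median(deg)),
        min_degree=int(deg.min()),
        max_degree=int(deg.max()),
        n_components=ns.n_components(),
    )
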