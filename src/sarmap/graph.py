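"""Tract adjacency structures.

The spatial unit of the analysis is the census tract; everything spatial
(the intrinsic CAR prior, Moran statistics, LISA) is driven by a symmetric
neighbour graph over tracts.  :class:`AdjacencyGraph` wraps that graph with
a fixed tract ordering, supports regular lattices (rook/queen contiguity),
the plain-text GAL spatial-weights exchange format, and queen/rook
contiguity derived from GeoJSON polygons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp


class IsolatedTractError(ValueError):
    """Raised when an operation requires every tract to have a neighbour."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbour structure over census tracts.

    Parameters
    ----------
    tract_ids : tuple of str
        Ordered tract identifiers; all vector quantities downstream follow
        this order.
    edges : frozenset of frozenset
        Unordered id pairs; no self-loops.
    """

    tract_ids: tuple[str, ...]
    edges: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = set(self.tract_ids)
        if len(ids) != len(self.tract_ids):
            raise ValueError("duplicate tract ids")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= ids:
                raise ValueError(f"edge endpoint not a known tract: {set(e)}")

    @property
    def n(self) -> int:
        return len(self.tract_ids)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tract_ids)}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.tract_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix W in tract order."""
        idx = self.index
        rows, cols = [], []
        for e in self.edges:
            a, b = tuple(e)
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency_matrix().sum(axis=1)).ravel()

    def neighbors(self, tract_id: str) -> list[str]:
        out = []
        for e in self.edges:
            if tract_id in e:
                (other,) = e - {tract_id}
                out.append(other)
        return sorted(out)

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    def component_labels(self) -> np.ndarray:
        """Integer component label per tract, in tract order."""
        labels = np.empty(self.n, dtype=int)
        idx = self.index
        for k, comp in enumerate(self.components()):
            for t in comp:
                labels[idx[t]] = k
        return labels

    def is_connected(self) -> bool:
        return len(self.components()) == 1

    def isolated_tracts(self) -> list[str]:
        deg = self.degrees()
        return [t for t, d in zip(self.tract_ids, deg) if d == 0]

    # ------------------------------------------------------------------ I/O

    def to_gal(self, path: str, name: str = "tracts") -> None:
        """Write the graph as a GAL spatial-weights file."""
        g = self.to_networkx()
        lines = [f"0 {self.n} {name} tract_id"]
        for t in self.tract_ids:
            nbrs = sorted(g.neighbors(t))
            lines.append(f"{t} {len(nbrs)}")
            lines.append(" ".join(nbrs))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_gal(cls, path: str) -> "AdjacencyGraph":
        """Read a GAL spatial-weights file (symmetrises if needed)."""
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        header = lines[0].split()
        n = int(header[1]) if len(header) > 1 else int(header[0])
        ids: list[str] = []
        edges: set[frozenset[str]] = set()
        pos = 1
        while pos < len(lines):
            tract, k = lines[pos].split()[:2]
            ids.append(tract)
            k = int(k)
            pos += 1
            if k > 0:
                nbrs = lines[pos].split()
                pos += 1
                for nb in nbrs:
                    edges.add(frozenset((tract, nb)))
        if len(ids) != n:
            raise ValueError(f"GAL header announces {n} tracts, found {len(ids)}")
        return cls(tuple(ids), frozenset(edges))


def make_lattice(n_rows: int, n_cols: int, contiguity: str = "queen") -> AdjacencyGraph:
    """Regular grid of tracts with rook or queen contiguity.

    Tract ids are deterministic: ``"r{row}c{col}"``, row-major order.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    tid = lambda r, c: f"r{r}c{c}"  # noqa: E731
    ids = tuple(tid(r, c) for r in range(n_rows) for c in range(n_cols))
    offsets = [(0, 1), (1, 0)]
    if contiguity == "queen":
        offsets += [(1, 1), (1, -1)]
    edges = set()
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    edges.add(frozenset((tid(r, c), tid(rr, cc))))
    return AdjacencyGraph(ids, frozenset(edges))


def lattice_geojson(n_rows: int, n_cols: int, cell_size: float = 0.01,
                    origin: tuple[float, float] = (-5.95, 43.35)) -> dict:
    """GeoJSON FeatureCollection of unit-square tract polygons for a lattice.

    Coordinates are synthetic WGS84 squares; the `tract_id` property matches
    :func:`make_lattice` ids.
    """
    from shapely.geometry import box, mapping

    x0, y0 = origin
    features = []
    for r in range(n_rows):
        for c in range(n_cols):
            poly = box(x0 + c * cell_size, y0 - (r + 1) * cell_size,
                       x0 + (c + 1) * cell_size, y0 - r * cell_size)
            features.append({
                "type": "Feature",
                "properties": {"tract_id": f"r{r}c{c}"},
                "geometry": mapping(poly),
            })
    return {"type": "FeatureCollection", "features": features}


def graph_from_geojson(geojson: dict | str, contiguity: str = "queen") -> AdjacencyGraph:
    """Derive tract contiguity from a GeoJSON FeatureCollection of polygons.

    Queen contiguity joins polygons sharing at least a boundary point; rook
    requires a shared boundary segment of positive length.
    """
    from shapely.geometry import shape
    from shapely.strtree import STRtree

    if isinstance(geojson, str):
        with open(geojson) as fh:
            geojson = json.load(fh)
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    ids = [f["properties"]["tract_id"] for f in geojson["features"]]
    geoms = [shape(f["geometry"]) for f in geojson["features"]]
    tree = STRtree(geoms)
    edges: set[frozenset[str]] = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="touches"):
            j = int(j)
            if j == i:
                continue
            if contiguity == "rook":
                shared = g.boundary.intersection(geoms[j].boundary)
                if shared.length == 0:
                    continue
            edges.add(frozenset((ids[i], ids[j])))
    return AdjacencyGraph(tuple(ids), frozenset(edges))


def greedy_coloring(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Partition tracts into independent sets (no two neighbours share a set).

    Used to vectorise single-site MCMC updates: within a colour class the
    full conditionals are mutually independent given the rest of the field.
    Deterministic for a given graph.
    """
    coloring = nx.greedy_color(graph.to_networkx(), strategy="largest_first")
    idx = graph.index
    n_colors = max(coloring.values()) + 1 if coloring else 0
    groups = [[] for _ in range(n_colors)]
    for t in graph.tract_ids:
        groups[coloring[t]].append(idx[t])
    return [np.array(sorted(g), dtype=int) for g in groups]
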