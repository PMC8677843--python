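"""Spatial neighbor/weight structures (contiguity, distance band, GAL I/O).

The weights matrix w_ij drives the Getis-Ord Gi* statistic, the bivariate
local Moran's I and the spatial lag/error regressions.  Conventions follow
standard practice: Gi* wants binary weights *with* each unit included in its
own neighborhood (the "star"), local Moran wants row-standardized weights
*without* self; both are explicit flags here rather than baked in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "contiguity_weights",
    "distance_band_weights",
    "read_gal",
    "write_gal",
]


@dataclass
class SpatialWeights:
    """Sparse neighbor/weight structure over an ordered set of unit ids."""

    ids: list[str]
    neighbors: dict[str, list[str]]
    weights: dict[str, list[float]]
    include_self: bool = False
    standardization: str = "binary"  # "binary" | "row"
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {u: i for i, u in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate unit ids in weights")
        for u in self.ids:
            self.neighbors.setdefault(u, [])
            self.weights.setdefault(u, [1.0] * len(self.neighbors[u]))
            if len(self.neighbors[u]) != len(self.weights[u]):
                raise ValueError(f"neighbor/weight length mismatch for {u!r}")
            for v in self.neighbors[u]:
                if v not in self._index:
                    raise ValueError(f"unknown neighbor id {v!r} for unit {u!r}")
            if not self.include_self and u in self.neighbors[u]:
                raise ValueError(f"unit {u!r} neighbors itself but include_self is False")

    @property
    def n(self) -> int:
        return len(self.ids)

    def cardinalities(self) -> dict[str, int]:
        return {u: len(self.neighbors[u]) for u in self.ids}

    def isolates(self) -> list[str]:
        return [u for u in self.ids if not self.neighbors[u]]

    def sparse(self) -> sparse.csr_matrix:
        """Weights as an n x n CSR matrix in the order of ``ids``."""
        rows, cols, data = [], [], []
        for u in self.ids:
            i = self._index[u]
            for v, w in zip(self.neighbors[u], self.weights[u]):
                rows.append(i)
                cols.append(self._index[v])
                data.append(w)
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def row_standardized(self) -> "SpatialWeights":
        """Rescale each unit's weights to sum to one (isolates untouched)."""
        weights = {}
        for u in self.ids:
            total = sum(self.weights[u])
            if total > 0:
                weights[u] = [w / total for w in self.weights[u]]
            else:
                weights[u] = []
        return SpatialWeights(
            ids=list(self.ids),
            neighbors={u: list(v) for u, v in self.neighbors.items()},
            weights=weights,
            include_self=self.include_self,
            standardization="row",
        )

    def same_structure(self, other: "SpatialWeights") -> bool:
        return self.ids == other.ids and all(
            sorted(self.neighbors[u]) == sorted(other.neighbors[u]) for u in self.ids
        )


def _lattice_neighbors(rule: str) -> list[tuple[int, int]]:
    rook = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if rule == "rook":
        return rook
    if rule == "queen":
        return rook + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    raise ValueError(f"unknown contiguity rule {rule!r}")


def contiguity_weights(
    table: pd.DataFrame, rule: str = "queen", include_self: bool = False
) -> SpatialWeights:
    """Rook/queen contiguity on a lattice table (binary, symmetric)."""
    if "row" not in table.columns or "col" not in table.columns:
        raise ValueError("table needs integer 'row' and 'col' lattice indices")
    offsets = _lattice_neighbors(rule)
    cell_of = {
        (int(r), int(c)): u
        for r, c, u in zip(table["row"], table["col"], table["unit_id"])
    }
    ids = list(table["unit_id"])
    neighbors: dict[str, list[str]] = {}
    for (r, c), u in cell_of.items():
        nbrs = [u] if include_self else []
        for dr, dc in offsets:
            v = cell_of.get((r + dr, c + dc))
            if v is not None:
                nbrs.append(v)
        neighbors[u] = nbrs
    weights = {u: [1.0] * len(v) for u, v in neighbors.items()}
    w = SpatialWeights(ids, neighbors, weights, include_self=include_self)
    if w.isolates():
        warnings.warn(f"{len(w.isolates())} unit(s) have no neighbors", stacklevel=2)
    return w


def distance_band_weights(
    table: pd.DataFrame, band: float, include_self: bool = False
) -> SpatialWeights:
    """Binary weights: w_ij = 1 iff centroid distance <= band."""
    if band <= 0:
        raise ValueError("band must be positive")
    coords = table[["x", "y"]].to_numpy(dtype=float)
    ids = list(table["unit_id"])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(band, output_type="ndarray")
    neighbors: dict[str, list[str]] = {u: ([u] if include_self else []) for u in ids}
    for i, j in pairs:
        neighbors[ids[i]].append(ids[j])
        neighbors[ids[j]].append(ids[i])
    weights = {u: [1.0] * len(v) for u, v in neighbors.items()}
    w = SpatialWeights(ids, neighbors, weights, include_self=include_self)
    isolates = [u for u in w.ids if len(w.neighbors[u]) <= (1 if include_self else 0)]
    if isolates:
        warnings.warn(
            f"distance band {band} leaves {len(isolates)} unit(s) without "
            "neighbors (band below minimum nearest-neighbor distance?)",
            stacklevel=2,
        )
    return w


def write_gal(w: SpatialWeights, path) -> None:
    """Write a plain-text GAL file: 'n' header, then 'id k' + neighbor line."""
    with open(path, "w") as fh:
        fh.write(f"{w.n}\n")
        for u in w.ids:
            nbrs = w.neighbors[u]
            fh.write(f"{u} {len(nbrs)}\n")
            fh.write(" ".join(nbrs) + "\n")


def read_gal(path, include_self: bool = False) -> SpatialWeights:
    """Read a GAL file written by :func:`write_gal` (binary weights)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty GAL file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed GAL header {lines[0]!r}") from exc
    ids: list[str] = []
    neighbors: dict[str, list[str]] = {}
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise ValueError("GAL file truncated")
        parts = lines[pos].split()
        if len(parts) != 2:
            raise ValueError(f"malformed GAL unit line {lines[pos]!r}")
        uid, k = parts[0], int(parts[1])
        nbr_line = lines[pos + 1].split() if pos + 1 < len(lines) else []
        if len(nbr_line) != k:
            raise ValueError(
                f"unit {uid!r} declares {k} neighbors but lists {len(nbr_line)}"
            )
        ids.append(uid)
        neighbors[uid] = nbr_line
        pos += 2
    known = set(ids)
    for uid, nbrs in neighbors.items():
        for v in nbrs:
            if v not in known:
                raise ValueError(f"GAL neighbor id {v!r} (of {uid!r}) is unknown")
    weights = {u: [1.0] * len(v) for u, v in neighbors.items()}
    inferred_self = any(u in neighbors[u] for u in ids)
    return SpatialWeights(
        ids, neighbors, weights, include_self=include_self or inferred_self
    )
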