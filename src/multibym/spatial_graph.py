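"""District adjacency graphs and the scaled ICAR precision structure.

The spatially structured component of a BYM2 random effect lives on the
district contiguity graph. Its precision matrix ``Q`` is the graph
Laplacian: ``Q_ii`` is the number of neighbours of district *i* and
``Q_ij = -1`` when *i* and *j* are neighbours. ``Q`` is rank deficient
(one null direction per connected component), so the structured effect is
identified by a sum-to-zero constraint per component, and its generalized
inverse covariance ``Q^-`` is computed on the orthogonal complement of the
null space.

Following the BYM2 convention, the ICAR precision is rescaled by a factor
``kappa`` chosen so the structured effect has unit *typical* marginal
variance: ``kappa = exp(mean_i log [Q^-]_ii)`` over non-island districts,
which makes the geometric mean of the diagonal of ``(kappa Q)^-`` exactly 1.
Islands (degree-0 districts) carry no structured effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "DistrictGraph",
    "build_adjacency",
    "adjacency_from_pairs",
    "scale_icar",
    "sample_structured",
    "read_geojson_districts",
    "read_adjacency_pairs",
    "write_adjacency_pairs",
]


@dataclass
class DistrictGraph:
    """Contiguity graph of ``m`` districts with its ICAR precision.

    Attributes
    ----------
    n_districts : int
        Number of districts ``m``.
    neighbor_lists : list[list[int]]
        Sorted 0-based neighbour indices per district.
    Q : ndarray of shape (m, m)
        Integer-valued ICAR precision (graph Laplacian).
    scaling_factor : float or None
        The BYM2 variance-scaling constant ``kappa``; set by
        :func:`scale_icar`.
    components : list[ndarray]
        District indices per connected component (islands are singleton
        components).
    island_ids : ndarray
        Indices of districts with zero neighbours.
    district_ids : list[str] or None
        Optional external identifiers, parallel to internal indices.
    """

    n_districts: int
    neighbor_lists: list
    Q: np.ndarray
    scaling_factor: float | None = None
    components: list = field(default_factory=list)
    island_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    district_ids: list | None = None
    # cached eigenstructure of the scaled precision, filled by scale_icar
    _eigvals: np.ndarray | None = None
    _eigvecs: np.ndarray | None = None
    _marginal_var: np.ndarray | None = None

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbor_lists], dtype=int)

    def structured_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(W, gamma)`` where columns of ``W`` span the constrained
        structured effect: ``u = W @ z`` with ``z ~ N(0, I)`` has covariance
        equal to the generalized inverse of ``kappa Q``, and ``gamma`` are the
        eigenvalues of that covariance in the spanned directions.
        """
        if self.scaling_factor is None:
            raise ValueError("graph not scaled; call scale_icar first")
        pos = self._eigvals > 0
        gamma = 1.0 / (self.scaling_factor * self._eigvals[pos])
        W = self._eigvecs[:, pos] * np.sqrt(gamma)
        return W, gamma

    def centered_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Full orthonormal eigenbasis ``(E, gamma)`` of the scaled
        structured covariance over all m districts: ``b = E w`` has BYM2
        prior ``w_i ~ N(0, sigma^2 (1 - phi + phi gamma_i))`` with
        ``gamma_i = 0`` on the sum-to-zero null directions and on islands
        (indicator columns)."""
        if self.scaling_factor is None:
            raise ValueError("graph not scaled; call scale_icar first")
        pos = self._eigvals > 0
        gamma = np.where(pos, 1.0 / (self.scaling_factor * np.where(pos, self._eigvals, 1.0)), 0.0)
        return self._eigvecs, gamma

    def covariance_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the scaled structured covariance ``(kappa Q)^-``
        restricted to non-island districts (zeros for the per-component
        sum-to-zero null directions included)."""
        if self.scaling_factor is None:
            raise ValueError("graph not scaled; call scale_icar first")
        non_island = self.n_districts - self.island_ids.size
        pos = self._eigvals > 0
        gamma = np.zeros(non_island)
        gamma[: pos.sum()] = 1.0 / (self.scaling_factor * self._eigvals[pos])
        return gamma


def _graph_from_neighbor_lists(neighbor_lists, district_ids=None) -> DistrictGraph:
    m = len(neighbor_lists)
    Q = np.zeros((m, m))
    for i, nbs in enumerate(neighbor_lists):
        Q[i, i] = len(nbs)
        for j in nbs:
            Q[i, j] = -1.0
    deg = np.array([len(nb) for nb in neighbor_lists])
    rows = [i for i, nbs in enumerate(neighbor_lists) for _ in nbs]
    cols = [j for nbs in neighbor_lists for j in nbs]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, labels = connected_components(adj, directed=False)
    components = [np.flatnonzero(labels == c) for c in range(n_comp)]
    return DistrictGraph(
        n_districts=m,
        neighbor_lists=[sorted(nbs) for nbs in neighbor_lists],
        Q=Q,
        components=components,
        island_ids=np.flatnonzero(deg == 0),
        district_ids=district_ids,
    )


def build_adjacency(geometries, rule: str = "queen", district_ids=None) -> DistrictGraph:
    """Build the contiguity graph from district polygons.

    Two districts are neighbours when their polygons share at least one
    boundary point (``rule="queen"``, the default: a corner touch counts) or
    share a boundary segment of positive length (``rule="rook"``).

    Parameters
    ----------
    geometries : sequence of shapely (Multi)Polygons
    rule : {"queen", "rook"}
    district_ids : optional sequence of unique identifiers
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    m = len(geometries)
    if district_ids is not None:
        if len(set(district_ids)) != m:
            raise ValueError("duplicate district identifiers")
        district_ids = [str(d) for d in district_ids]
    geoms = []
    for idx, g in enumerate(geometries):
        label = district_ids[idx] if district_ids is not None else str(idx)
        if g is None or not isinstance(g, BaseGeometry) or g.is_empty:
            raise ValueError(f"district {label}: empty or missing geometry")
        if not g.is_valid:
            raise ValueError(f"district {label}: invalid geometry")
        geoms.append(g)

    from shapely.strtree import STRtree

    tree = STRtree(geoms)
    neighbor_lists = [set() for _ in range(m)]
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "rook" and inter.length == 0:
                continue  # point contact only
            neighbor_lists[i].add(j)
            neighbor_lists[j].add(i)
    return _graph_from_neighbor_lists(
        [sorted(s) for s in neighbor_lists], district_ids=district_ids
    )


def adjacency_from_pairs(pairs, m: int, district_ids=None) -> DistrictGraph:
    """Build the graph from 1-based neighbour pairs.

    Pair orientation is irrelevant and duplicates collapse; self-pairs and
    out-of-range indices are rejected.
    """
    if m < 1:
        raise ValueError("m must be positive")
    neighbor_lists = [set() for _ in range(m)]
    for a, b in pairs:
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"self-pair ({a},{b}) not allowed")
        if not (1 <= a <= m and 1 <= b <= m):
            raise ValueError(f"pair ({a},{b}) out of range 1..{m}")
        neighbor_lists[a - 1].add(b - 1)
        neighbor_lists[b - 1].add(a - 1)
    return _graph_from_neighbor_lists(
        [sorted(s) for s in neighbor_lists], district_ids=district_ids
    )


def scale_icar(graph: DistrictGraph) -> DistrictGraph:
    """Compute the BYM2 scaling factor ``kappa`` and cache the eigenstructure.

    The generalized inverse of ``Q`` under the per-component sum-to-zero
    constraint is the Moore-Penrose pseudo-inverse (the null space of the
    ICAR precision is exactly the per-component constant vectors).
    ``kappa`` is the geometric mean of its marginal variances over
    non-island districts, so the scaled covariance ``(kappa Q)^-`` has
    geometric-mean diagonal 1.
    """
    non_island = np.setdiff1d(np.arange(graph.n_districts), graph.island_ids)
    if non_island.size == 0:
        raise ValueError("all districts are islands: no structured component exists")

    # eigendecompose per component (block-diagonal structure) for stability
    eigvals = np.zeros(graph.n_districts)
    eigvecs = np.zeros((graph.n_districts, graph.n_districts))
    marg = np.zeros(graph.n_districts)
    col = 0
    for comp in graph.components:
        if comp.size == 1:
            # island: no structured effect; indicator basis column, gamma = 0
            eigvecs[comp[0], col] = 1.0
            col += 1
            continue
        Qc = graph.Q[np.ix_(comp, comp)]
        w, V = np.linalg.eigh(Qc)
        # smallest eigenvalue is the constant null direction; clamp to 0
        w[np.abs(w) < 1e-9 * max(w.max(), 1.0)] = 0.0
        pos = w > 0
        varc = (V[:, pos] ** 2 / w[pos]).sum(axis=1)
        marg[comp] = varc
        for k in range(comp.size):
            eigvals[col] = w[k]
            eigvecs[comp, col] = V[:, k]
            col += 1
    kappa = float(np.exp(np.mean(np.log(marg[non_island]))))
    graph.scaling_factor = kappa
    graph._eigvals = eigvals
    graph._eigvecs = eigvecs
    graph._marginal_var = marg / kappa  # diagonal of (kappa Q)^-
    return graph


def sample_structured(graph: DistrictGraph, rng) -> np.ndarray:
    """Draw ``u* ~ N(0, (kappa Q)^-)`` with per-component sum-to-zero.

    Islands receive exactly 0. ``rng`` is a ``numpy.random.Generator`` or a
    seed acceptable to ``numpy.random.default_rng``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    W, _ = graph.structured_basis()
    z = rng.standard_normal(W.shape[1])
    return W @ z


# ---------------------------------------------------------------------------
# file I/O


def read_geojson_districts(path, id_property: str = "id"):
    """Read district polygons from a GeoJSON FeatureCollection.

    Returns ``(geometries, district_ids)``; the identifier is taken from the
    feature property named ``id_property`` (falling back to the feature-level
    ``id`` member, then the feature index).
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    geometries, ids = [], []
    for k, feat in enumerate(gj["features"]):
        geometries.append(_shapely_shape(feat["geometry"]))
        props = feat.get("properties") or {}
        ids.append(str(props.get(id_property, feat.get("id", k))))
    return geometries, ids


def read_adjacency_pairs(path):
    """Read a two-column delimited pair list (1-based indices).

    Accepts whitespace- or comma-separated columns; lines starting with ``#``
    are ignored. Returns a list of ``(i, j)`` integer tuples.
    """
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"malformed adjacency line: {line!r}")
            pairs.append((int(parts[0]), int(parts[1])))
    return pairs


def write_adjacency_pairs(graph: DistrictGraph, path, metadata_path=None):
    """Write the edge list (1-based, each edge once) and optional metadata
    (m, kappa, islands) as JSON."""
    with open(path, "w") as fh:
        fh.write("# district_i district_j (1-based)\n")
        for i, nbs in enumerate(graph.neighbor_lists):
            for j in nbs:
                if j > i:
                    fh.write(f"{i + 1} {j + 1}\n")
    if metadata_path is not None:
        meta = {
            "n_districts": graph.n_districts,
            "scaling_factor": graph.scaling_factor,
            "n_islands": int(graph.island_ids.size),
            "n_components": len(graph.components),
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))
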