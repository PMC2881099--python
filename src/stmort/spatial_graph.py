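"""Municipality adjacency structure and intrinsic-CAR quadratic forms.

The spatial backbone of the mortality models is an undirected neighborhood
graph over small areas (municipalities).  The spatially structured random
effects carry an intrinsic conditional-autoregressive (ICAR) prior whose
log density, up to an additive constant, is

    ((n - c)/2) * log(tau) - (tau/2) * sum_{i~j} (phi_i - phi_j)^2

where ``n`` is the number of areas, ``c`` the number of connected components
of the graph (the rank deficiency of the graph Laplacian), ``tau`` the
precision, and the sum runs over unordered neighbor pairs.  The prior is
improper: it is flat along the constant direction of each component, which
is why samplers re-center the field per component every sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "NeighborFormatError",
    "read_neighbors",
    "build_lattice",
    "car_pairwise_quadratic",
    "car_log_kernel",
    "write_edge_list",
]


class NeighborFormatError(ValueError):
    """Raised when a neighbor file is malformed."""


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected area adjacency with derived degree and component structure.

    Parameters
    ----------
    n_areas
        Number of areas (graph nodes), indexed ``0..n_areas-1``.
    edges
        Unordered distinct pairs of area indices.  Self-pairs are rejected.
    labels
        Optional external area identifiers, one per index.  Internal code
        is always 0-based; external files keep their own labels through
        this map.

    Notes
    -----
    Isolated areas (degree 0) are permitted; each counts as its own
    connected component and contributes nothing to the CAR quadratic form.
    """

    n_areas: int
    edges: frozenset = field(default_factory=frozenset)
    labels: tuple = None

    def __post_init__(self):
        if self.n_areas < 1:
            raise ValueError("n_areas must be a positive integer")
        norm = set()
        for (i, j) in self.edges:
            if i == j:
                raise ValueError(f"self-pair ({i},{i}) not allowed")
            if not (0 <= i < self.n_areas and 0 <= j < self.n_areas):
                raise ValueError(f"edge ({i},{j}) outside area range")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(norm))
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(range(self.n_areas)))
        elif len(self.labels) != self.n_areas:
            raise ValueError("labels length must equal n_areas")
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

        es = sorted(self.edges)
        ei = np.fromiter((e[0] for e in es), dtype=np.intp, count=len(es))
        ej = np.fromiter((e[1] for e in es), dtype=np.intp, count=len(es))
        object.__setattr__(self, "_ei", ei)
        object.__setattr__(self, "_ej", ej)
        deg = np.zeros(self.n_areas, dtype=np.intp)
        np.add.at(deg, ei, 1)
        np.add.at(deg, ej, 1)
        object.__setattr__(self, "degree", deg)

        uf = _UnionFind(self.n_areas)
        for a, b in zip(ei, ej):
            uf.union(a, b)
        roots = [uf.find(i) for i in range(self.n_areas)]
        uniq = {}
        comp = np.empty(self.n_areas, dtype=np.intp)
        for i, r in enumerate(roots):
            comp[i] = uniq.setdefault(r, len(uniq))
        object.__setattr__(self, "component_labels", comp)
        object.__setattr__(self, "n_components", len(uniq))

    # -- derived structure -------------------------------------------------

    @property
    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two aligned index arrays (for vectorized sums)."""
        return self._ei, self._ej

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix."""
        n = self.n_areas
        ei, ej = self._ei, self._ej
        data = np.ones(2 * len(ei))
        rows = np.concatenate([ei, ej])
        cols = np.concatenate([ej, ei])
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - A (the ICAR precision pattern)."""
        L = -self.adjacency_matrix().toarray()
        np.fill_diagonal(L, self.degree)
        return L

    def component_means(self, x: np.ndarray) -> np.ndarray:
        """Mean of ``x`` within each connected component (length n_components)."""
        x = np.asarray(x, dtype=float)
        sums = np.bincount(self.component_labels, weights=x, minlength=self.n_components)
        counts = np.bincount(self.component_labels, minlength=self.n_components)
        return sums / counts

    def center_by_component(self, x: np.ndarray) -> np.ndarray:
        """Subtract the per-component mean from ``x``."""
        return np.asarray(x, dtype=float) - self.component_means(x)[self.component_labels]

    def index_of(self, label) -> int:
        """Index of an external area label."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown area label {label!r}") from None


# -- readers / writers -----------------------------------------------------


def read_neighbors(source: IO[str] | Iterable[str], dialect: str = "gal",
                   n_areas: int | None = None) -> AdjacencyGraph:
    """Read an adjacency structure from a neighbor file.

    Two dialects are supported:

    ``gal``
        GAL spatial-weights format: a header line carrying the area count
        (either ``n`` alone or the conventional ``0 n ...`` header), then per
        area a record line ``id k`` followed by a line with the ``k``
        neighbor ids.  Labels are arbitrary tokens; indices are assigned in
        order of record declaration.
    ``flat_pairs``
        One ``i j`` pair per line, 0-based integer indices; ``n_areas`` may
        be passed to declare areas beyond the largest index mentioned.

    Duplicate pair declarations are collapsed; a pair declared on one side
    only is symmetrized with a logged warning.  A neighbor id outside the
    declared set raises :class:`NeighborFormatError` naming the line.
    """
    lines = list(source if not hasattr(source, "read") else source)
    if dialect == "flat_pairs":
        return _read_flat_pairs(lines, n_areas)
    if dialect == "gal":
        return _read_gal(lines)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_flat_pairs(lines: Sequence[str], n_areas: int | None) -> AdjacencyGraph:
    edges = set()
    max_idx = -1
    for ln, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        toks = s.split()
        if len(toks) != 2:
            raise NeighborFormatError(f"line {ln}: expected 'i j', got {raw!r}")
        try:
            i, j = int(toks[0]), int(toks[1])
        except ValueError:
            raise NeighborFormatError(f"line {ln}: non-integer pair {raw!r}") from None
        if i == j:
            raise NeighborFormatError(f"line {ln}: self-pair {i}")
        if i < 0 or j < 0:
            raise NeighborFormatError(f"line {ln}: negative index")
        if n_areas is not None and (i >= n_areas or j >= n_areas):
            raise NeighborFormatError(
                f"line {ln}: index out of declared range 0..{n_areas - 1}")
        max_idx = max(max_idx, i, j)
        edges.add((min(i, j), max(i, j)))
    n = n_areas if n_areas is not None else max_idx + 1
    if n < 1:
        raise NeighborFormatError("no areas declared")
    return AdjacencyGraph(n_areas=n, edges=frozenset(edges))


def _read_gal(lines: Sequence[str]) -> AdjacencyGraph:
    content = [(ln, raw.strip()) for ln, raw in enumerate(lines, start=1)
               if raw.strip() and not raw.strip().startswith("#")]
    if not content:
        raise NeighborFormatError("empty GAL file")
    hdr_ln, hdr = content[0]
    toks = hdr.split()
    try:
        n = int(toks[0]) if len(toks) == 1 else int(toks[1])
    except ValueError:
        raise NeighborFormatError(f"line {hdr_ln}: bad GAL header {hdr!r}") from None
    if n < 1:
        raise NeighborFormatError(f"line {hdr_ln}: nonpositive area count")

    records: list[tuple[int, str, list[str]]] = []  # (line, id, neighbor ids)
    body = content[1:]
    k = 0
    while k < len(body):
        ln, rec = body[k]
        toks = rec.split()
        if len(toks) != 2:
            raise NeighborFormatError(f"line {ln}: expected 'id n_neighbors', got {rec!r}")
        aid, nn_s = toks
        try:
            nn = int(nn_s)
        except ValueError:
            raise NeighborFormatError(f"line {ln}: bad neighbor count {nn_s!r}") from None
        if nn == 0:
            records.append((ln, aid, []))
            k += 1
            continue
        if k + 1 >= len(body):
            raise NeighborFormatError(f"line {ln}: missing neighbor line for area {aid}")
        nln, nrec = body[k + 1]
        nbrs = nrec.split()
        if len(nbrs) != nn:
            raise NeighborFormatError(
                f"line {nln}: expected {nn} neighbor ids, got {len(nbrs)}")
        records.append((ln, aid, nbrs))
        k += 2

    if len(records) != n:
        raise NeighborFormatError(
            f"GAL header declares {n} areas but {len(records)} records found")
    index = {aid: i for i, (_, aid, _) in enumerate(records)}
    if len(index) != n:
        raise NeighborFormatError("duplicate area ids in GAL records")

    declared: set[tuple[int, int]] = set()  # directed declarations
    for ln, aid, nbrs in records:
        i = index[aid]
        for b in nbrs:
            if b not in index:
                raise NeighborFormatError(
                    f"line {ln}: neighbor id {b!r} outside declared range")
            j = index[b]
            if i == j:
                raise NeighborFormatError(f"line {ln}: area {aid} lists itself")
            declared.add((i, j))
    edges = set()
    for (i, j) in declared:
        if (j, i) not in declared:
            li = records[i][1]
            lj = records[j][1]
            logger.warning(
                "GAL: pair (%s,%s) declared only one way; symmetrizing", li, lj)
        edges.add((min(i, j), max(i, j)))
    return AdjacencyGraph(n_areas=n, edges=frozenset(edges),
                          labels=tuple(aid for _, aid, _ in records))


def write_edge_list(graph: AdjacencyGraph, stream: IO[str]) -> None:
    """Write the edge set as one ``label_i label_j`` pair per line."""
    for i, j in sorted(graph.edges):
        stream.write(f"{graph.labels[i]} {graph.labels[j]}\n")


def write_gal(graph: AdjacencyGraph, stream: IO[str]) -> None:
    """Write the graph in GAL format (symmetric declarations)."""
    nbrs: list[list] = [[] for _ in range(graph.n_areas)]
    for i, j in sorted(graph.edges):
        nbrs[i].append(graph.labels[j])
        nbrs[j].append(graph.labels[i])
    stream.write(f"{graph.n_areas}\n")
    for i in range(graph.n_areas):
        stream.write(f"{graph.labels[i]} {len(nbrs[i])}\n")
        if nbrs[i]:
            stream.write(" ".join(str(b) for b in nbrs[i]) + "\n")


# -- constructors ----------------------------------------------------------


def build_lattice(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency rectangular lattice (synthetic stand-in geography).

    Areas are indexed row-major; horizontal and vertical neighbors share an
    edge.  Always a single connected component.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    edges = set()
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.add((i, i + 1))
            if r + 1 < rows:
                edges.add((i, i + cols))
    return AdjacencyGraph(n_areas=rows * cols, edges=frozenset(edges))


# -- CAR kernels -----------------------------------------------------------


def car_pairwise_quadratic(effects: np.ndarray, graph: AdjacencyGraph) -> float:
    """Sum over edges (i,j) of (phi_i - phi_j)^2.

    The quadratic form of the intrinsic CAR prior; equals ``phi' L phi``
    with ``L`` the graph Laplacian.  Invariant under adding a constant to
    all effects within one connected component.
    """
    phi = np.asarray(effects, dtype=float)
    if phi.shape != (graph.n_areas,):
        raise ValueError(
            f"effects length {phi.shape} does not match n_areas={graph.n_areas}")
    ei, ej = graph.edge_arrays
    d = phi[ei] - phi[ej]
    return float(d @ d)


def car_log_kernel(effects: np.ndarray, tau: float, graph: AdjacencyGraph) -> float:
    """Log density of the intrinsic CAR prior, up to an additive constant.

    ``((n - c)/2) log tau - (tau/2) sum_{i~j} (phi_i - phi_j)^2``
    with ``c`` the number of connected components (rank deficiency).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    q = car_pairwise_quadratic(effects, graph)
    n, c = graph.n_areas, graph.n_components
    return 0.5 * (n - c) * np.log(tau) - 0.5 * tau * q
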