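"""Non-revisiting archive over a binary space partition of the genome space.

Every genome the search evaluates is quantized to a cell (per-gene resolution,
e.g. 0.25 Å for translations, 2 degrees for torsions) and stored in a BSP
tree.  The tree starts as a single leaf covering the whole (discretized)
search space; when a second distinct cell lands in an occupied leaf, the leaf
splits along the dimension where the two occupants are farthest apart (in
bound-normalized units), at the midpoint between them, so every leaf ends up
holding at most one visited cell and the two children of any internal node
exactly partition its box.

A candidate whose cell is already stored is *revisited*: it is redirected to
a uniformly drawn point inside the nearest leaf subspace that still contains
unvisited cells (distance measured from the query to the box in
bound-normalized coordinates), and that point's cell is stored in turn.  The
archive therefore guarantees that no cell is ever evaluated twice, and raises
:class:`SpaceSaturatedError` once every cell has been visited.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genome import GeneBounds

__all__ = ["BSPNode", "BSPTree", "SpaceSaturatedError"]


class SpaceSaturatedError(RuntimeError):
    """Every cell of the discretized search space has been visited."""


class BSPNode:
    """One subspace of the partition: a per-gene integer cell-index box.

    ``lo``/``hi`` are inclusive/exclusive cell-index bounds.  A leaf holds at
    most one visited cell; an internal node holds a split dimension/value and
    two children whose boxes partition its own.
    """

    __slots__ = ("lo", "hi", "nlo", "nhi", "occupant", "split_dim",
                 "split_val", "left", "right", "free")

    def __init__(self, lo: tuple[int, ...], hi: tuple[int, ...]):
        self.lo = lo
        self.hi = hi
        self.nlo: tuple[float, ...] = ()
        self.nhi: tuple[float, ...] = ()
        self.occupant: tuple[int, ...] | None = None
        self.split_dim: int | None = None
        self.split_val: int | None = None
        self.left: "BSPNode | None" = None
        self.right: "BSPNode | None" = None
        self.free = self.capacity  # unvisited cells in this subtree

    @property
    def capacity(self) -> int:
        c = 1
        for a, b in zip(self.lo, self.hi):
            c *= int(b) - int(a)  # Python ints: capacities can exceed int64
        return c

    @property
    def is_leaf(self) -> bool:
        return self.split_dim is None

    def contains(self, cell: tuple[int, ...]) -> bool:
        return all(a <= v < b for v, a, b in zip(cell, self.lo, self.hi))


class BSPTree:
    """Non-revisiting archive of visited genome cells.

    Parameters
    ----------
    bounds
        Continuous per-gene search limits.
    resolution
        Per-gene cell edge length (same units as the gene).  Genes are
        quantized as ``floor((x - lower) / resolution)``, clamped to the cell
        range; two genomes collide exactly when every quantized index matches.
    """

    def __init__(self, bounds: GeneBounds, resolution: np.ndarray | float):
        self.bounds = bounds
        res = np.broadcast_to(np.asarray(resolution, dtype=float),
                              (bounds.n_genes,)).copy()
        if np.any(res <= 0):
            raise ValueError("resolution must be positive")
        self.resolution = res
        self.n_cells = np.maximum(
            np.ceil(bounds.widths / res - 1e-9).astype(int), 1)
        self.root = BSPNode((0,) * bounds.n_genes,
                            tuple(int(n) for n in self.n_cells))
        self.visited = 0
        self.redirects = 0
        self._tick = itertools.count()  # heap tie-break, keeps left-first order
        # plain-float caches for the pure-Python hot paths
        self._inv_cells = tuple(1.0 / int(n) for n in self.n_cells)
        self._lower = tuple(float(v) for v in bounds.lower)
        self._res = tuple(float(v) for v in res)
        self._attach_norm(self.root)

    def _attach_norm(self, node: BSPNode) -> None:
        node.nlo = tuple(v * inv for v, inv in zip(node.lo, self._inv_cells))
        node.nhi = tuple(v * inv for v, inv in zip(node.hi, self._inv_cells))

    # -- geometry -----------------------------------------------------------

    def cell_of(self, genome: np.ndarray) -> tuple[int, ...]:
        v = np.asarray(genome, dtype=float)
        idx = np.floor((v - self.bounds.lower) / self.resolution).astype(int)
        return tuple(np.clip(idx, 0, self.n_cells - 1))

    def cell_sample(self, cell: tuple[int, ...],
                    rng: np.random.Generator) -> np.ndarray:
        """Uniform continuous point inside a cell, clipped to the bounds."""
        lo = self.bounds.lower + np.array(cell) * self.resolution
        pt = lo + rng.uniform(size=len(cell)) * self.resolution
        return self.bounds.clip(pt)

    def _norm_point(self, genome: np.ndarray) -> tuple[float, ...]:
        """Query point in cell units scaled to [0, 1] per gene."""
        return tuple(
            (float(v) - lo) / r * inv
            for v, lo, r, inv in zip(genome, self._lower, self._res,
                                     self._inv_cells)
        )

    def _box_distance_sq(self, qn: tuple[float, ...], node: BSPNode) -> float:
        # pure Python: genomes are short and this sits in the redirect loop
        total = 0.0
        for q, a, b in zip(qn, node.nlo, node.nhi):
            if q < a:
                d = a - q
                total += d * d
            elif q > b:
                d = q - b
                total += d * d
        return total

    @property
    def total_cells(self) -> int:
        c = 1
        for n in self.n_cells:
            c *= int(n)
        return c

    @property
    def node_count(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            if not node.is_leaf:
                stack.extend((node.left, node.right))
        return count

    def leaves(self) -> Iterator[BSPNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend((node.right, node.left))

    def visited_cells(self) -> Iterator[tuple[int, ...]]:
        for leaf in self.leaves():
            if leaf.occupant is not None:
                yield leaf.occupant

    # -- insertion ----------------------------------------------------------

    def _descend(self, cell: tuple[int, ...]) -> tuple[BSPNode, list[BSPNode]]:
        """Leaf whose box contains ``cell``, plus the path down to it.

        Because sibling boxes partition the parent box, the child whose box
        contains the cell is also the child at distance 0 (ties impossible).
        """
        node = self.root
        path = [node]
        while not node.is_leaf:
            node = node.left if cell[node.split_dim] < node.split_val else node.right
            path.append(node)
        return node, path

    def _split(self, leaf: BSPNode, old: tuple[int, ...],
               new: tuple[int, ...]) -> None:
        dim = max(range(len(old)),
                  key=lambda d: abs(old[d] - new[d]) * self._inv_cells[d])
        a, b = sorted((old[dim], new[dim]))
        sv = (a + b) // 2 + 1  # integer boundary strictly separating a and b
        left = BSPNode(leaf.lo, tuple(
            v if i != dim else sv for i, v in enumerate(leaf.hi)))
        right = BSPNode(tuple(
            v if i != dim else sv for i, v in enumerate(leaf.lo)), leaf.hi)
        for cell in (old, new):
            child = left if cell[dim] < sv else right
            if child.occupant is not None:  # pragma: no cover - by construction
                raise AssertionError("split failed to separate occupants")
            child.occupant = cell
            child.free -= 1
        leaf.occupant = None
        leaf.split_dim = dim
        leaf.split_val = sv
        leaf.left = left
        leaf.right = right
        self._attach_norm(left)
        self._attach_norm(right)

    def _store(self, cell: tuple[int, ...]) -> None:
        """Record a cell known to be unvisited."""
        leaf, path = self._descend(cell)
        if leaf.occupant is None:
            leaf.occupant = cell
        elif leaf.occupant == cell:  # pragma: no cover - caller guarantees
            raise AssertionError("storing an already-visited cell")
        else:
            self._split(leaf, leaf.occupant, cell)
        for node in path:
            node.free -= 1
        self.visited += 1

    # -- public API ---------------------------------------------------------

    def query_insert(self, genome: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, int]:
        """Archive a candidate; redirect it if its cell was already visited.

        Returns ``(genome', revisit_flag)``: the genome unchanged with flag 0
        when its cell was new, or a replacement drawn from the nearest
        unvisited neighbor subspace with flag 1.  Either way the returned
        genome's cell is stored.
        """
        genome = np.asarray(genome, dtype=float)
        cell = self.cell_of(genome)
        leaf, _ = self._descend(cell)
        if leaf.occupant == cell:
            if self.root.free <= 0:
                raise SpaceSaturatedError(
                    f"all {self.total_cells} cells visited at the current "
                    "resolution")
            self.redirects += 1
            return self.nearest_unvisited(genome, rng), 1
        self._store(cell)
        return genome, 0

    def nearest_unvisited(self, genome: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
        """Uniform point inside the closest leaf subspace with free cells.

        Distance is Euclidean from the bound-normalized query to each box
        (zero inside); the winning leaf's free cells are sampled uniformly,
        the chosen cell is stored, and a uniform point within it is returned.
        Raises :class:`SpaceSaturatedError` when no free cell exists.
        """
        if self.root.free <= 0:
            raise SpaceSaturatedError("search space exhausted")
        q = self._norm_point(np.asarray(genome, dtype=float))
        heap: list[tuple[float, int, BSPNode]] = [
            (self._box_distance_sq(q, self.root), next(self._tick), self.root)]
        while heap:
            dist, _, node = heapq.heappop(heap)
            if node.free <= 0:
                continue
            if node.is_leaf:
                cell = self._sample_free_cell(node, rng)
                self._store(cell)
                return self.cell_sample(cell, rng)
            # push left before right: equal-distance ties resolve left-first
            for child in (node.left, node.right):
                if child.free > 0:
                    heapq.heappush(
                        heap,
                        (self._box_distance_sq(q, child), next(self._tick), child))
        raise SpaceSaturatedError("search space exhausted")  # pragma: no cover

    def _sample_free_cell(self, leaf: BSPNode,
                          rng: np.random.Generator) -> tuple[int, ...]:
        """Uniform unvisited cell within a leaf box (occupant excluded)."""
        for _ in range(64):
            cell = tuple(int(rng.integers(a, b))
                         for a, b in zip(leaf.lo, leaf.hi))
            if cell != leaf.occupant:
                return cell
        # capacity 2 with extreme luck, or capacity 1 occupied (cannot happen
        # when free > 0): deterministic scan fallback
        for cell in itertools.product(*(range(a, b)
                                        for a, b in zip(leaf.lo, leaf.hi))):
            if cell != leaf.occupant:
                return cell
        raise SpaceSaturatedError("leaf has no free cell")  # pragma: no cover

    def dump(self) -> str:
        """Line-oriented text dump: one visited cell per line (tab-separated)."""
        lines = sorted(self.visited_cells())
        return "\n".join("\t".join(str(v) for v in cell) for cell in lines) + (
            "\n" if lines else "")
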