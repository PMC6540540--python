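"""Enumeration of subclone phylogenies and allocation/multiplicity combinations.

A tumor's subclones are modeled as nodes of a rooted tree under a perfect
(infinite-sites) phylogeny: every subclone inherits all mutations of its
parent, each node has at most two children, and copy-number alterations are
clonal.  A mutation that originates in subclone ``s`` is therefore carried by
``s`` and all of its descendants; the binary indicator of that set over
subclones is the mutation's *allocation* vector.  Because copy-number events
are clonal, a subclonal mutation always sits on a single allele (multiplicity
one), whereas a clonal mutation may predate the copy-number event and carry
multiplicity 1, the minor copy number, or the major copy number.

This module enumerates all non-isomorphic rooted binary-bounded trees with up
to ``s_max`` subclones, derives each tree's allocation set, and builds the
allocation x multiplicity combination table for a collection of allele-specific
copy-number states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np

__all__ = [
    "CopyState",
    "TreeConfig",
    "Combo",
    "ComboTable",
    "enumerate_trees",
    "allocations_from_tree",
    "build_combos",
]


@dataclass(frozen=True, order=True)
class CopyState:
    """Clonal allele-specific copy number at a locus, minor <= major."""

    cn_minor: int
    cn_major: int

    def __post_init__(self) -> None:
        if self.cn_minor < 0 or self.cn_major < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.cn_minor > self.cn_major:
            raise ValueError("cn_minor must not exceed cn_major")
        if self.total == 0:
            raise ValueError("total copy number must be at least 1")

    @property
    def total(self) -> int:
        return self.cn_minor + self.cn_major

    def multiplicities(self) -> list[int]:
        """Possible mutated-allele counts: unique positive of {1, minor, major}."""
        return sorted({m for m in (1, self.cn_minor, self.cn_major) if m > 0})


@dataclass(frozen=True)
class TreeConfig:
    """One enumerated subclone phylogeny with its allocation set.

    Subclones are labeled 0..S-1 in breadth-first order from the root, with
    sibling subtrees ordered by their canonical form, so the labeling — and
    hence ``index`` — is reproducible across runs.
    """

    index: int
    n_subclones: int
    parent: tuple[int | None, ...]
    allocations: tuple[tuple[int, ...], ...] = field(repr=False)

    @property
    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_subclones)]
        for child, par in enumerate(self.parent):
            if par is not None:
                out[par].append(child)
        return out

    def allocation_matrix(self) -> np.ndarray:
        """Allocation set as an (S, S) 0/1 array, row u = allocation vector."""
        return np.asarray(self.allocations, dtype=np.int8)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "n_subclones": self.n_subclones,
            "parent": [-1 if p is None else p for p in self.parent],
            "allocations": [list(a) for a in self.allocations],
        }


@dataclass(frozen=True)
class Combo:
    """One (allocation, multiplicity) combination for a copy-number state."""

    allocation: tuple[int, ...]
    multiplicity: int
    origin: int  # subclone where the mutation arose (0 = root/clonal)


@dataclass(frozen=True)
class ComboTable:
    """Allocation x multiplicity combinations per unique copy-number state."""

    tree: TreeConfig
    states: tuple[CopyState, ...]
    combos: dict[CopyState, tuple[Combo, ...]]

    def n_combos(self, state: CopyState) -> int:
        return len(self.combos[state])


# ---------------------------------------------------------------------------
# Tree enumeration
# ---------------------------------------------------------------------------

# A shape is a recursively nested tuple: (child_shape, child_shape, ...) with
# children sorted so that each shape is its own canonical form.


def _shapes(n_nodes: int) -> list[tuple]:
    """All canonical rooted-tree shapes with n_nodes nodes and <= 2 children."""
    if n_nodes == 1:
        return [()]
    out: list[tuple] = []
    # one child holding all remaining nodes
    for sub in _shapes(n_nodes - 1):
        out.append((sub,))
    # two children splitting the remaining nodes
    rest = n_nodes - 1
    for a in range(1, rest // 2 + 1):
        b = rest - a
        if a == b:
            pool = _shapes(a)
            for left, right in combinations_with_replacement(sorted(pool), 2):
                out.append(tuple(sorted((left, right))))
        else:
            for left in _shapes(a):
                for right in _shapes(b):
                    out.append(tuple(sorted((left, right))))
    return out


def _shape_to_parent(shape: tuple) -> tuple[int | None, ...]:
    """Breadth-first labeling of a canonical shape into a parent map."""
    parent: list[int | None] = [None]
    queue: list[tuple[int, tuple]] = [(0, shape)]
    while queue:
        label, node = queue.pop(0)
        for child_shape in node:
            parent.append(label)
            queue.append((len(parent) - 1, child_shape))
    return tuple(parent)


def allocations_from_tree(parent: Sequence[int | None]) -> list[tuple[int, ...]]:
    """Allocation vectors of a parent map: one per origin subclone.

    Vector ``u`` has ones exactly on subclone ``u`` and its descendants, the
    cells that carry a mutation arising in ``u`` under a perfect phylogeny.
    The root's vector is all ones (clonal).

    Raises ``ValueError`` on cyclic or multi-root parent maps.
    """
    s = len(parent)
    roots = [i for i, p in enumerate(parent) if p is None]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root, found {len(roots)}")
    # verify acyclicity by walking each node up to the root
    for i in range(s):
        seen = set()
        node: int | None = i
        while node is not None:
            if node in seen:
                raise ValueError("cyclic parent map")
            seen.add(node)
            node = parent[node]
    children: list[list[int]] = [[] for _ in range(s)]
    for child, par in enumerate(parent):
        if par is not None:
            children[par].append(child)
    allocations = []
    for origin in range(s):
        vec = [0] * s
        stack = [origin]
        while stack:
            node = stack.pop()
            vec[node] = 1
            stack.extend(children[node])
        allocations.append(tuple(vec))
    return allocations


def enumerate_trees(s_max: int = 5) -> list[TreeConfig]:
    """Enumerate all non-isomorphic rooted subclone trees with 1..s_max nodes.

    Each node has at most two children.  Trees are returned in deterministic
    order: by subclone count, then by canonical shape.  Configuration indices
    are 1-based and stable for a given ``s_max`` prefix (the list for
    ``s_max=3`` is a prefix of the list for ``s_max=5``).
    """
    if not isinstance(s_max, (int, np.integer)) or isinstance(s_max, bool):
        raise ValueError("s_max must be an integer")
    if not 1 <= s_max <= 6:
        raise ValueError(f"s_max must be in [1, 6], got {s_max}")
    configs: list[TreeConfig] = []
    for s in range(1, s_max + 1):
        for shape in sorted(set(_shapes(s))):
            parent = _shape_to_parent(shape)
            configs.append(
                TreeConfig(
                    index=len(configs) + 1,
                    n_subclones=s,
                    parent=parent,
                    allocations=tuple(allocations_from_tree(parent)),
                )
            )
    return configs


# ---------------------------------------------------------------------------
# Allocation x multiplicity combinations
# ---------------------------------------------------------------------------


def build_combos(tree: TreeConfig, states: Sequence[CopyState]) -> ComboTable:
    """Build the combination table for a tree over unique copy-number states.

    For each state the clonal (all-ones) allocation pairs with every possible
    multiplicity (ascending), then each subclonal allocation pairs with
    multiplicity 1, in tree order.  The table therefore has
    ``|M| + S - 1`` rows per state, where ``M`` is the state's multiplicity
    set.
    """
    unique_states = tuple(dict.fromkeys(states))
    table: dict[CopyState, tuple[Combo, ...]] = {}
    clonal = tree.allocations[0]
    for state in unique_states:
        rows = [Combo(clonal, m, 0) for m in state.multiplicities()]
        for origin in range(1, tree.n_subclones):
            rows.append(Combo(tree.allocations[origin], 1, origin))
        table[state] = tuple(rows)
    return ComboTable(tree=tree, states=unique_states, combos=table)
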