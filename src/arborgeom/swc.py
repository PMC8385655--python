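"""Reading, writing and perturbing SWC neuron reconstructions.

SWC is the de-facto plain-text format for neuron traces: one node per line
with seven whitespace-separated columns ``id type x y z radius parent``,
where ``parent = -1`` marks the root.  Coordinates are in micrometres.
Comment lines start with ``#`` and blank lines are ignored; node lines need
not appear in topological order.  The structure-type code (column 2) is
carried through untouched — the analyses here treat the whole trace as a
single axonal arbor and never filter on it.

Besides IO, this module implements the node-dropout perturbation used to
probe robustness of downstream geometry: each non-root node is removed
independently with a fixed probability and its children are re-attached to
its parent, which emulates annotators spacing their trace points
differently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "SWCParseError",
    "SWCStructureError",
    "read_swc",
    "write_swc",
    "remove_random_nodes",
]


class SWCParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SWCStructureError(ValueError):
    """The nodes of an SWC file do not form a single rooted tree."""


ROOT_PARENT = -1


@dataclass(frozen=True, eq=False)
class NeuronNode:
    """One trace point of a neuron reconstruction.

    Attributes
    ----------
    id : int
        Positive integer identifier, unique within a tree.
    structure_type : int
        SWC column-2 code (soma/axon/dendrite ...), carried through verbatim.
    position : (3,) ndarray
        Coordinates in micrometres.
    radius : float
        Local process radius in micrometres (not used by the analyses).
    parent_id : int
        Identifier of the parent node, ``-1`` for the root.
    """

    id: int
    structure_type: int
    position: np.ndarray
    radius: float
    parent_id: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        object.__setattr__(self, "position", pos)
        if self.id <= 0:
            raise ValueError(f"node id must be positive, got {self.id}")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")

    def same_as(self, other: "NeuronNode") -> bool:
        """Field-by-field equality (exact coordinate comparison)."""
        return (
            self.id == other.id
            and self.structure_type == other.structure_type
            and bool(np.all(self.position == other.position))
            and self.radius == other.radius
            and self.parent_id == other.parent_id
        )


@dataclass
class NeuronTree:
    """A validated rooted tree of :class:`NeuronNode` objects."""

    nodes: dict[int, NeuronNode]
    root_id: int
    source_name: str = ""

    def __post_init__(self) -> None:
        self._validate()

    # -- structure -----------------------------------------------------

    def _validate(self) -> None:
        if not self.nodes:
            raise SWCStructureError("tree has no nodes")
        roots = [n.id for n in self.nodes.values() if n.parent_id == ROOT_PARENT]
        if len(roots) != 1:
            raise SWCStructureError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)}"
            )
        if roots[0] != self.root_id:
            raise SWCStructureError(
                f"root_id={self.root_id} does not match the parentless node {roots[0]}"
            )
        for node in self.nodes.values():
            if node.parent_id != ROOT_PARENT and node.parent_id not in self.nodes:
                raise SWCStructureError(
                    f"node {node.id} refers to missing parent {node.parent_id}"
                )
        # connectivity + acyclicity: everything must be reachable from the root
        seen = set()
        stack = [self.root_id]
        children = self._children_map()
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise SWCStructureError("cycle detected")
            seen.add(nid)
            stack.extend(children.get(nid, ()))
        if len(seen) != len(self.nodes):
            missing = sorted(set(self.nodes) - seen)
            raise SWCStructureError(
                f"{len(missing)} node(s) unreachable from root, e.g. {missing[:5]}"
            )

    def _children_map(self) -> dict[int, list[int]]:
        children: dict[int, list[int]] = {}
        for node in self.nodes.values():
            if node.parent_id != ROOT_PARENT:
                children.setdefault(node.parent_id, []).append(node.id)
        for v in children.values():
            v.sort()
        return children

    @cached_property
    def children(self) -> Mapping[int, list[int]]:
        """Child ids per node id, sorted ascending (absent key = leaf)."""
        return self._children_map()

    # -- convenience ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def leaf_ids(self) -> list[int]:
        return sorted(nid for nid in self.nodes if nid not in self.children)

    def position(self, nid: int) -> np.ndarray:
        return self.nodes[nid].position

    def topological_order(self) -> list[int]:
        """Depth-first preorder from the root; children visited in id order."""
        order: list[int] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self.children.get(nid, ())))
        return order

    def same_as(self, other: "NeuronTree") -> bool:
        """Exact node-by-node equality (ids, coordinates, topology)."""
        if set(self.nodes) != set(other.nodes) or self.root_id != other.root_id:
            return False
        return all(self.nodes[i].same_as(other.nodes[i]) for i in self.nodes)


# ---------------------------------------------------------------------------
# IO


def _parse_line(line: str, lineno: int) -> NeuronNode:
    fields = line.split()
    if len(fields) != 7:
        raise SWCParseError(
            f"line {lineno}: expected 7 columns, found {len(fields)}"
        )
    try:
        nid = int(fields[0])
        stype = int(fields[1])
        xyz = [float(v) for v in fields[2:5]]
        radius = float(fields[5])
        parent = int(fields[6])
    except ValueError as exc:
        raise SWCParseError(f"line {lineno}: {exc}") from None
    try:
        return NeuronNode(nid, stype, np.array(xyz), radius, parent)
    except ValueError as exc:
        raise SWCParseError(f"line {lineno}: {exc}") from None


def read_swc(path: str | os.PathLike) -> NeuronTree:
    """Read a single-tree SWC file.

    Raises
    ------
    SWCParseError
        On a malformed line (the message names the line number).
    SWCStructureError
        If the nodes do not form a single rooted tree (multiple roots,
        dangling parent references, cycles, duplicate ids).
    """
    nodes: dict[int, NeuronNode] = {}
    root_id = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            node = _parse_line(line, lineno)
            if node.id in nodes:
                raise SWCStructureError(
                    f"line {lineno}: duplicate node id {node.id}"
                )
            nodes[node.id] = node
            if node.parent_id == ROOT_PARENT:
                root_id = node.id
    if not nodes:
        raise SWCStructureError(f"{path}: no data lines")
    if root_id is None:
        raise SWCStructureError(f"{path}: no root node (parent -1)")
    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return NeuronTree(nodes=nodes, root_id=root_id, source_name=name)


def write_swc(tree: NeuronTree, path: str | os.PathLike) -> None:
    """Write ``tree`` as 7-column SWC.

    Ids are renumbered ``1..n`` in a depth-first topological order (parent
    before child); coordinates are emitted with ``repr`` so that a read/write
    round trip is bitwise exact on the float values.
    """
    order = tree.topological_order()
    new_id = {old: i + 1 for i, old in enumerate(order)}
    lines = ["# id type x y z radius parent"]
    for old in order:
        node = tree.nodes[old]
        parent = (
            ROOT_PARENT if node.parent_id == ROOT_PARENT else new_id[node.parent_id]
        )
        x, y, z = (repr(float(v)) for v in node.position)
        lines.append(
            f"{new_id[old]} {node.structure_type} {x} {y} {z} "
            f"{repr(float(node.radius))} {parent}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Perturbation


def remove_random_nodes(
    tree: NeuronTree, p_remove: float, rng_seed: int
) -> NeuronTree:
    """Remove each non-root node independently with probability ``p_remove``.

    A removed node's children are re-attached to its closest surviving
    ancestor, so the result is always a single connected rooted tree.  The
    root is never removed (removing it would change the arbor's origin and
    hence the primary-segment definition).  Deterministic for a given seed.
    """
    if not 0.0 <= p_remove < 1.0:
        raise ValueError(f"p_remove must be in [0, 1), got {p_remove}")
    rng = np.random.default_rng(rng_seed)
    candidates = sorted(nid for nid in tree.nodes if nid != tree.root_id)
    draws = rng.random(len(candidates))
    removed = {nid for nid, u in zip(candidates, draws) if u < p_remove}
    if not removed:
        return NeuronTree(dict(tree.nodes), tree.root_id, tree.source_name)

    def surviving_parent(nid: int) -> int:
        pid = tree.nodes[nid].parent_id
        while pid in removed:
            pid = tree.nodes[pid].parent_id
        return pid

    kept: dict[int, NeuronNode] = {}
    for nid, node in tree.nodes.items():
        if nid in removed:
            continue
        if node.parent_id in removed:
            node = replace(node, parent_id=surviving_parent(nid))
        kept[nid] = node
    return NeuronTree(kept, tree.root_id, tree.source_name)
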