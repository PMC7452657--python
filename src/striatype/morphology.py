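"""SWC neuronal morphologies: reading, validation, synthesis.

SWC is the 7-column plain-text reconstruction format: ``id type x y z radius
parent``, coordinates and radii in micrometers, ``parent = -1`` marking the
root.  Validation enforces a single tree: unique ids, exactly one root,
every parent defined before it is referenced, no cycles, positive radii.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SpecError, ValidationError

__all__ = ["SWCNode", "Morphology", "read_swc", "write_swc", "synthesize_tree", "TreeSpec"]

SOMA_TYPE = 1


@dataclass(frozen=True)
class SWCNode:
    id: int
    structure_type: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root


@dataclass
class Morphology:
    """A validated SWC node tree."""

    nodes: list[SWCNode]
    name: str = ""
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[int, SWCNode] = {}
        self._children: dict[int, list[int]] = {}
        roots = []
        for i, nd in enumerate(self.nodes):
            if nd.id in self._index:
                raise ValidationError(f"node {i + 1}: duplicate id {nd.id}")
            if nd.radius <= 0:
                raise ValidationError(f"node {i + 1}: radius must be positive")
            if nd.parent_id == -1:
                roots.append(nd.id)
            elif nd.parent_id not in self._index:
                raise ValidationError(
                    f"node {i + 1}: parent {nd.parent_id} undefined before child "
                    f"{nd.id} (orphan or cycle)"
                )
            self._index[nd.id] = nd
            self._children.setdefault(nd.id, [])
            if nd.parent_id != -1:
                self._children[nd.parent_id].append(nd.id)
        if len(roots) != 1:
            raise ValidationError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]

    def node(self, node_id: int) -> SWCNode:
        return self._index[node_id]

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def parent(self, node_id: int) -> int | None:
        pid = self._index[node_id].parent_id
        return None if pid == -1 else pid

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def xyz(self, node_id: int) -> np.ndarray:
        nd = self._index[node_id]
        return np.array([nd.x, nd.y, nd.z])

    def soma_center(self) -> np.ndarray:
        """Centroid of the type-1 nodes (the root alone if none are typed)."""
        soma = [nd for nd in self.nodes if nd.structure_type == SOMA_TYPE]
        if not soma:
            soma = [self._index[self.root]]
        return np.mean([[nd.x, nd.y, nd.z] for nd in soma], axis=0)

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs in file order."""
        return [(nd.parent_id, nd.id) for nd in self.nodes if nd.parent_id != -1]

    def tips(self) -> list[int]:
        return [nd.id for nd in self.nodes if not self._children[nd.id]]

    def recentered(self) -> "Morphology":
        """Coordinates shifted so the soma centroid is the origin."""
        c = self.soma_center()
        moved = [
            SWCNode(nd.id, nd.structure_type, nd.x - c[0], nd.y - c[1], nd.z - c[2],
                    nd.radius, nd.parent_id)
            for nd in self.nodes
        ]
        return Morphology(moved, name=self.name, ground_truth=dict(self.ground_truth))


def read_swc(path: str | os.PathLike, recenter: bool = False) -> Morphology:
    """Parse and validate a 7-column SWC file ('#' comments allowed)."""
    nodes: list[SWCNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 7:
                raise ValidationError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nodes.append(
                    SWCNode(
                        id=int(parts[0]),
                        structure_type=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        z=float(parts[4]),
                        radius=float(parts[5]),
                        parent_id=int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if not nodes:
        raise ValidationError(f"{path}: no nodes")
    try:
        m = Morphology(nodes, name=os.path.splitext(os.path.basename(str(path)))[0])
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return m.recentered() if recenter else m


def write_swc(m: Morphology, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nd in m.nodes:
            fh.write(
                f"{nd.id} {nd.structure_type} {nd.x:.6f} {nd.y:.6f} {nd.z:.6f} "
                f"{nd.radius:.6f} {nd.parent_id}\n"
            )


@dataclass(frozen=True)
class TreeSpec:
    """Branching parameters for the random-tree fixture generator.

    A dendrite grows as straight segments of Gaussian length; after each
    segment it bifurcates with probability ``branch_prob`` (up to
    ``max_bifurcations`` in total) or terminates with probability
    ``term_prob`` once past ``min_depth`` segments.
    """

    n_stems: int = 2
    branch_prob: float = 0.3
    term_prob: float = 0.25
    max_bifurcations: int = 10
    min_depth: int = 1
    max_depth: int = 12
    segment_length_mean: float = 20.0  # um
    segment_length_sd: float = 5.0
    radius: float = 0.5  # um, neurite radius
    soma_radius: float = 6.0
    taper: float = 0.95  # child radius / parent radius at bifurcations

    def __post_init__(self) -> None:
        if self.segment_length_mean <= 0:
            raise SpecError("segment_length_mean must be positive")
        if not (0 <= self.branch_prob <= 1 and 0 <= self.term_prob <= 1):
            raise SpecError("probabilities must be in [0, 1]")
        if self.n_stems < 1:
            raise SpecError("need at least one stem")


def _random_direction(rng: np.random.Generator, bias: np.ndarray | None = None) -> np.ndarray:
    v = rng.normal(size=3)
    if bias is not None:
        v = 0.7 * bias + 0.5 * v
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def synthesize_tree(spec: TreeSpec | None = None, seed: int = 0) -> Morphology:
    """Seeded random dendritic tree with recorded ground-truth counts.

    ``ground_truth`` holds n_nodes, n_tips, n_bifurcations (soma branching
    excluded), n_stems and total_length.
    """
    spec = spec or TreeSpec()
    rng = np.random.default_rng(seed)
    nodes = [SWCNode(1, SOMA_TYPE, 0.0, 0.0, 0.0, spec.soma_radius, -1)]
    next_id = 2
    n_bif = 0
    total_length = 0.0

    def seg_len() -> float:
        return max(float(rng.normal(spec.segment_length_mean, spec.segment_length_sd)),
                   spec.segment_length_mean * 0.1)

    # Stack of (parent_id, position, direction, depth, radius).
    stack = []
    for _ in range(spec.n_stems):
        stack.append((1, np.zeros(3), _random_direction(rng), 0, spec.radius))

    while stack:
        parent_id, pos, direction, depth, radius = stack.pop()
        L = seg_len()
        new_pos = pos + direction * L
        total_length += L
        nid = next_id
        next_id += 1
        nodes.append(
            SWCNode(nid, 3, float(new_pos[0]), float(new_pos[1]), float(new_pos[2]),
                    radius, parent_id)
        )
        if depth >= spec.max_depth:
            continue
        can_branch = n_bif < spec.max_bifurcations
        u = rng.random()
        if can_branch and u < spec.branch_prob:
            n_bif += 1
            for _ in range(2):
                stack.append(
                    (nid, new_pos, _random_direction(rng, bias=direction), depth + 1,
                     radius * spec.taper)
                )
        elif depth >= spec.min_depth and u < spec.branch_prob + spec.term_prob:
            continue
        else:
            stack.append(
                (nid, new_pos, _random_direction(rng, bias=direction), depth + 1, radius)
            )

    m = Morphology(nodes, name=f"synthetic_seed{seed}")
    m.ground_truth = {
        "n_nodes": len(nodes),
        "n_tips": len(m.tips()),
        "n_bifurcations": n_bif,
        "n_stems": spec.n_stems,
        "total_length": total_length,
        "seed": seed,
    }
    return m
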