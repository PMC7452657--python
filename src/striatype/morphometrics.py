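"""Global morphometric features and Sholl analysis.

Computes a fixed set of 23 global scalars per reconstruction, following the
widespread conventions for whole-neuron metrics (frustum-based surface and
volume, branches defined as maximal unbranched paths between
root/bifurcations/tips, contraction as the euclidean/path ratio per branch).
The exact list is this package's declared set — an approximation of what
common morphometry plug-ins report, documented feature-by-feature below —
not a reproduction of any one tool's output.

Conventions:

* the soma is the set of type-1 nodes, collapsed to its centroid for all
  distance and Sholl computations; edges between two soma nodes carry no
  length, surface or volume;
* a *bifurcation* is any node with two or more children, the soma root
  included when it branches;
* ``overall_width >= overall_height >= overall_depth`` are the extents of
  the node cloud along its principal axes, which makes all 23 features
  invariant to rigid rotation and translation;
* Sholl intersections count neurite edges whose endpoint distances straddle
  each concentric sphere (``min < r <= max``), so a sphere through a node is
  counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .morphology import SOMA_TYPE, Morphology

__all__ = ["MORPHO_FEATURE_NAMES", "MorphoFeatures", "global_features", "sholl", "ShollProfile"]

MORPHO_FEATURE_NAMES = (
    "soma_surface",
    "n_stems",
    "n_bifurcations",
    "n_branches",
    "n_tips",
    "overall_width",
    "overall_height",
    "overall_depth",
    "average_diameter",
    "total_length",
    "total_surface",
    "total_volume",
    "max_euclidean_distance",
    "max_path_distance",
    "max_branch_order",
    "average_contraction",
    "average_fragmentation",
    "average_parent_daughter_ratio",
    "average_bif_angle_local",
    "average_bif_angle_remote",
    "average_branch_length",
    "partition_asymmetry",
    "average_tortuosity",
)


@dataclass
class MorphoFeatures:
    """The 23 global scalars for one reconstruction."""

    cell_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(MORPHO_FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValidationError(f"missing morphometric features: {sorted(missing)}")

    def as_series(self) -> pd.Series:
        s = pd.Series({k: self.values[k] for k in MORPHO_FEATURE_NAMES})
        s.name = self.cell_id
        return s


@dataclass
class ShollProfile:
    radii: np.ndarray  # um, strictly increasing
    intersections: np.ndarray  # counts

    def as_series(self) -> pd.Series:
        return pd.Series(self.intersections, index=self.radii)


def _neurite_edges(m: Morphology) -> list[tuple[int, int]]:
    """Edges carrying geometry: everything except soma-soma internal edges."""
    out = []
    for pid, cid in m.edges():
        if (
            m.node(pid).structure_type == SOMA_TYPE
            and m.node(cid).structure_type == SOMA_TYPE
        ):
            continue
        out.append((pid, cid))
    return out


def _edge_length(m: Morphology, pid: int, cid: int) -> float:
    return float(np.linalg.norm(m.xyz(cid) - m.xyz(pid)))


def _branches(m: Morphology) -> list[list[int]]:
    """Maximal unbranched node paths between critical nodes (root,
    bifurcations, tips), each as [start, ..., end] node ids."""
    critical = {m.root} | {
        nid for nid in (nd.id for nd in m.nodes) if len(m.children(nid)) >= 2
    }
    branches = []
    for nd in m.nodes:
        nid = nd.id
        if nid == m.root:
            continue
        is_end = (not m.children(nid)) or nid in critical
        if not is_end:
            continue
        path = [nid]
        cur = m.parent(nid)
        while cur is not None:
            path.append(cur)
            if cur in critical:
                break
            cur = m.parent(cur)
        branches.append(path[::-1])
    return branches


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _subtree_tip_count(m: Morphology, nid: int) -> int:
    stack, count = [nid], 0
    while stack:
        cur = stack.pop()
        kids = m.children(cur)
        if not kids:
            count += 1
        stack.extend(kids)
    return count


def _next_critical(m: Morphology, nid: int) -> int:
    """Walk down an unbranched path to the next bifurcation or tip."""
    cur = nid
    while True:
        kids = m.children(cur)
        if len(kids) != 1:
            return cur
        cur = kids[0]


def global_features(m: Morphology) -> MorphoFeatures:
    """Compute the 23 global morphometric features.

    A soma-only morphology gets zeros for every neurite-dependent feature
    (averages over empty sets are reported as 0, not NaN).
    """
    soma_nodes = [nd for nd in m.nodes if nd.structure_type == SOMA_TYPE] or [
        m.node(m.root)
    ]
    soma_c = m.soma_center()
    soma_r = float(np.mean([nd.radius for nd in soma_nodes]))
    neurite_nodes = [nd for nd in m.nodes if nd.structure_type != SOMA_TYPE]
    edges = _neurite_edges(m)

    f: dict[str, float] = {}
    f["soma_surface"] = 4.0 * np.pi * soma_r**2
    soma_ids = {nd.id for nd in soma_nodes}
    f["n_stems"] = float(
        sum(
            1
            for nd in m.nodes
            if nd.parent_id in soma_ids and nd.id not in soma_ids
        )
    )
    bifurcations = [nd.id for nd in m.nodes if len(m.children(nd.id)) >= 2]
    f["n_bifurcations"] = float(len(bifurcations))
    branches = _branches(m)
    f["n_branches"] = float(len(branches))
    f["n_tips"] = float(len(m.tips()))

    coords = np.array([[nd.x, nd.y, nd.z] for nd in m.nodes])
    centered = coords - coords.mean(axis=0)
    if len(coords) > 1:
        cov = centered.T @ centered
        _, vecs = np.linalg.eigh(cov)
        proj = centered @ vecs[:, ::-1]  # descending variance
        extents = proj.max(axis=0) - proj.min(axis=0)
    else:
        extents = np.zeros(3)
    f["overall_width"], f["overall_height"], f["overall_depth"] = map(float, extents)

    diam_nodes = neurite_nodes or m.nodes
    f["average_diameter"] = float(np.mean([2.0 * nd.radius for nd in diam_nodes]))

    total_length = 0.0
    total_surface = 0.0
    total_volume = 0.0
    for pid, cid in edges:
        L = _edge_length(m, pid, cid)
        r1, r2 = m.node(pid).radius, m.node(cid).radius
        slant = float(np.sqrt(L**2 + (r1 - r2) ** 2))
        total_length += L
        total_surface += np.pi * (r1 + r2) * slant
        total_volume += np.pi * L * (r1**2 + r1 * r2 + r2**2) / 3.0
    f["total_length"] = total_length
    f["total_surface"] = float(total_surface)
    f["total_volume"] = float(total_volume)

    f["max_euclidean_distance"] = float(
        max((np.linalg.norm(m.xyz(nd.id) - soma_c) for nd in m.nodes), default=0.0)
    )

    # Path distance from root, soma-internal edges free.
    path_dist: dict[int, float] = {m.root: 0.0}
    soma_pair = lambda pid, cid: (
        m.node(pid).structure_type == SOMA_TYPE
        and m.node(cid).structure_type == SOMA_TYPE
    )
    for nd in m.nodes:
        if nd.parent_id == -1:
            continue
        step = 0.0 if soma_pair(nd.parent_id, nd.id) else _edge_length(m, nd.parent_id, nd.id)
        path_dist[nd.id] = path_dist[nd.parent_id] + step
    f["max_path_distance"] = float(max(path_dist.values(), default=0.0))

    # Branch order: stems are order 1; +1 below every bifurcating ancestor.
    order: dict[int, float] = {m.root: 0.0}
    for nd in m.nodes:
        if nd.parent_id == -1:
            continue
        pid = nd.parent_id
        if pid == m.root:
            order[nd.id] = 1.0
        else:
            order[nd.id] = order[pid] + (1.0 if len(m.children(pid)) >= 2 else 0.0)
    f["max_branch_order"] = float(max(order.values(), default=0.0))

    contractions, tortuosities, lengths, frags = [], [], [], []
    for path in branches:
        plen = sum(_edge_length(m, a, b) for a, b in zip(path, path[1:]))
        elen = float(np.linalg.norm(m.xyz(path[-1]) - m.xyz(path[0])))
        if plen > 0:
            contractions.append(elen / plen)
            if elen > 0:
                tortuosities.append(plen / elen)
        lengths.append(plen)
        frags.append(len(path) - 1)
    f["average_contraction"] = float(np.mean(contractions)) if contractions else 0.0
    f["average_tortuosity"] = float(np.mean(tortuosities)) if tortuosities else 0.0
    f["average_branch_length"] = float(np.mean(lengths)) if lengths else 0.0
    f["average_fragmentation"] = float(np.mean(frags)) if frags else 0.0

    ratios, local_angles, remote_angles, asymmetries = [], [], [], []
    for bid in bifurcations:
        kids = m.children(bid)[:2]
        rp = m.node(bid).radius
        for k in m.children(bid):
            ratios.append(m.node(k).radius / rp)
        v1 = m.xyz(kids[0]) - m.xyz(bid)
        v2 = m.xyz(kids[1]) - m.xyz(bid)
        local_angles.append(_angle_deg(v1, v2))
        r1 = m.xyz(_next_critical(m, kids[0])) - m.xyz(bid)
        r2 = m.xyz(_next_critical(m, kids[1])) - m.xyz(bid)
        remote_angles.append(_angle_deg(r1, r2))
        lt, rt = _subtree_tip_count(m, kids[0]), _subtree_tip_count(m, kids[1])
        asymmetries.append(abs(lt - rt) / (lt + rt - 2) if lt + rt > 2 else 0.0)
    f["average_parent_daughter_ratio"] = float(np.mean(ratios)) if ratios else 0.0
    f["average_bif_angle_local"] = float(np.mean(local_angles)) if local_angles else 0.0
    f["average_bif_angle_remote"] = float(np.mean(remote_angles)) if remote_angles else 0.0
    f["partition_asymmetry"] = float(np.mean(asymmetries)) if asymmetries else 0.0

    return MorphoFeatures(cell_id=m.name, values=f)


def sholl(m: Morphology, radius_step: float = 10.0) -> ShollProfile:
    """Concentric-sphere intersection counts centered on the soma centroid."""
    if radius_step <= 0:
        raise ValidationError("radius_step must be positive")
    soma_c = m.soma_center()
    edges = _neurite_edges(m)
    dmax = max(
        (float(np.linalg.norm(m.xyz(nd.id) - soma_c)) for nd in m.nodes), default=0.0
    )
    n_radii = max(1, int(np.ceil(dmax / radius_step)) + 1)
    radii = radius_step * np.arange(1, n_radii + 1)
    counts = np.zeros(n_radii, dtype=int)
    for pid, cid in edges:
        d1 = float(np.linalg.norm(m.xyz(pid) - soma_c))
        d2 = float(np.linalg.norm(m.xyz(cid) - soma_c))
        lo, hi = min(d1, d2), max(d1, d2)
        counts += (lo < radii) & (radii <= hi)
    return ShollProfile(radii=radii, intersections=counts)
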