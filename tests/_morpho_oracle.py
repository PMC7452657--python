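"""Independent re-implementation of the 23 global morphometrics and Sholl
counts, built on a networkx graph instead of the package's node-index walk.
Used as the brute-force oracle in unit and acceptance tests; follows the
same documented definitions but shares no code with the implementation."""

import networkx as nx
import numpy as np

SOMA = 1


def _graph(m):
    g = nx.DiGraph()
    for nd in m.nodes:
        g.add_node(nd.id, t=nd.structure_type, p=np.array([nd.x, nd.y, nd.z]), r=nd.radius)
    for nd in m.nodes:
        if nd.parent_id != -1:
            g.add_edge(nd.parent_id, nd.id)
    return g


def oracle_features(m):
    g = _graph(m)
    root = [n for n in g if g.in_degree(n) == 0][0]
    pos = nx.get_node_attributes(g, "p")
    rad = nx.get_node_attributes(g, "r")
    typ = nx.get_node_attributes(g, "t")
    soma_ids = [n for n in g if typ[n] == SOMA] or [root]
    soma_c = np.mean([pos[n] for n in soma_ids], axis=0)
    soma_r = float(np.mean([rad[n] for n in soma_ids]))

    def elen(u, v):
        return float(np.linalg.norm(pos[v] - pos[u]))

    geom_edges = [
        (u, v) for u, v in g.edges if not (typ[u] == SOMA and typ[v] == SOMA)
    ]
    tips = [n for n in g if g.out_degree(n) == 0]
    bifs = [n for n in g if g.out_degree(n) >= 2]

    f = {}
    f["soma_surface"] = 4 * np.pi * soma_r**2
    f["n_stems"] = float(
        sum(1 for u, v in g.edges if u in set(soma_ids) and v not in set(soma_ids))
    )
    f["n_bifurcations"] = float(len(bifs))
    f["n_tips"] = float(len(tips))

    coords = np.array([pos[n] for n in sorted(g)])
    c = coords - coords.mean(axis=0)
    if len(coords) > 1:
        w_, vecs = np.linalg.eigh(c.T @ c)
        proj = c @ vecs[:, ::-1]
        ext = proj.max(axis=0) - proj.min(axis=0)
    else:
        ext = np.zeros(3)
    f["overall_width"], f["overall_height"], f["overall_depth"] = map(float, ext)

    neurite = [n for n in g if typ[n] != SOMA] or list(g)
    f["average_diameter"] = float(np.mean([2 * rad[n] for n in neurite]))

    tl = ts = tv = 0.0
    for u, v in geom_edges:
        L = elen(u, v)
        r1, r2 = rad[u], rad[v]
        tl += L
        ts += np.pi * (r1 + r2) * np.sqrt(L**2 + (r1 - r2) ** 2)
        tv += np.pi * L * (r1**2 + r1 * r2 + r2**2) / 3
    f["total_length"], f["total_surface"], f["total_volume"] = tl, float(ts), float(tv)

    f["max_euclidean_distance"] = float(
        max(np.linalg.norm(pos[n] - soma_c) for n in g)
    )
    ug = g.to_undirected()
    wlen = {
        (u, v): 0.0 if (typ[u] == SOMA and typ[v] == SOMA) else elen(u, v)
        for u, v in g.edges
    }
    for (u, v), L in list(wlen.items()):
        ug[u][v]["w"] = L
    dist = nx.single_source_dijkstra_path_length(ug, root, weight="w")
    f["max_path_distance"] = float(max(dist.values()))

    order = {root: 0}
    for u, v in nx.bfs_edges(g, root):
        if u == root:
            order[v] = 1
        else:
            order[v] = order[u] + (1 if g.out_degree(u) >= 2 else 0)
    f["max_branch_order"] = float(max(order.values()))

    # Branches: maximal unbranched paths between root/bifurcations/tips.
    critical = set([root]) | set(bifs)
    branches = []
    for n in g:
        if n == root:
            continue
        if g.out_degree(n) == 0 or n in critical:
            path = [n]
            cur = next(iter(g.predecessors(n)))
            while True:
                path.append(cur)
                if cur in critical:
                    break
                cur = next(iter(g.predecessors(cur)))
            branches.append(list(reversed(path)))

    contr, tort, blen, frag = [], [], [], []
    for path in branches:
        plen = sum(elen(a, b) for a, b in zip(path, path[1:]))
        e = float(np.linalg.norm(pos[path[-1]] - pos[path[0]]))
        if plen > 0:
            contr.append(e / plen)
            if e > 0:
                tort.append(plen / e)
        blen.append(plen)
        frag.append(len(path) - 1)
    f["n_branches"] = float(len(branches))
    f["average_contraction"] = float(np.mean(contr)) if contr else 0.0
    f["average_tortuosity"] = float(np.mean(tort)) if tort else 0.0
    f["average_branch_length"] = float(np.mean(blen)) if blen else 0.0
    f["average_fragmentation"] = float(np.mean(frag)) if frag else 0.0

    def angle(v1, v2):
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            return 0.0
        return float(
            np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1)))
        )

    def down_to_critical(n):
        while g.out_degree(n) == 1:
            n = next(iter(g.successors(n)))
        return n

    ratios, la, ra, pa = [], [], [], []
    for bnode in bifs:
        kids = list(g.successors(bnode))
        for kk in kids:
            ratios.append(rad[kk] / rad[bnode])
        k1, k2 = kids[0], kids[1]
        la.append(angle(pos[k1] - pos[bnode], pos[k2] - pos[bnode]))
        ra.append(
            angle(
                pos[down_to_critical(k1)] - pos[bnode],
                pos[down_to_critical(k2)] - pos[bnode],
            )
        )
        t1 = sum(1 for d in nx.descendants(g, k1) | {k1} if g.out_degree(d) == 0)
        t2 = sum(1 for d in nx.descendants(g, k2) | {k2} if g.out_degree(d) == 0)
        pa.append(abs(t1 - t2) / (t1 + t2 - 2) if t1 + t2 > 2 else 0.0)
    f["average_parent_daughter_ratio"] = float(np.mean(ratios)) if ratios else 0.0
    f["average_bif_angle_local"] = float(np.mean(la)) if la else 0.0
    f["average_bif_angle_remote"] = float(np.mean(ra)) if ra else 0.0
    f["partition_asymmetry"] = float(np.mean(pa)) if pa else 0.0
    return f


def oracle_sholl(m, step):
    g = _graph(m)
    root = [n for n in g if g.in_degree(n) == 0][0]
    pos = nx.get_node_attributes(g, "p")
    typ = nx.get_node_attributes(g, "t")
    soma_ids = [n for n in g if typ[n] == SOMA] or [root]
    soma_c = np.mean([pos[n] for n in soma_ids], axis=0)
    dmax = max(float(np.linalg.norm(pos[n] - soma_c)) for n in g)
    radii = step * np.arange(1, max(1, int(np.ceil(dmax / step)) + 1) + 1)
    counts = np.zeros(len(radii), dtype=int)
    for u, v in g.edges:
        if typ[u] == SOMA and typ[v] == SOMA:
            continue
        d1 = float(np.linalg.norm(pos[u] - soma_c))
        d2 = float(np.linalg.norm(pos[v] - soma_c))
        for i, r in enumerate(radii):
            if min(d1, d2) < r <= max(d1, d2):
                counts[i] += 1
    return radii, counts
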