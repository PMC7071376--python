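"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written against different primitives than
the package (networkx traversals, dense numerical sampling, quadratic-time
definitions) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from dendroplast.swc import SOMA, NeuronReconstruction


def brute_morphometry(neuron: NeuronReconstruction) -> dict:
    """Recompute all eight parameters by explicit graph traversal."""
    g = nx.DiGraph()
    soma_ids = set(int(i) for i, t in zip(neuron.ids, neuron.types)
                   if t == SOMA)
    pos = {int(i): neuron.xyz[k] for k, i in enumerate(neuron.ids)}
    for i, p in zip(neuron.ids, neuron.parents):
        i, p = int(i), int(p)
        if i in soma_ids:
            continue
        if p != -1 and p not in soma_ids:
            g.add_edge(p, i)
        else:
            g.add_node(i)

    stems = [int(i) for i, p in zip(neuron.ids, neuron.parents)
             if int(i) not in soma_ids and int(p) in soma_ids]
    tips = [v for v in g.nodes if g.out_degree(v) == 0]
    nodes = [v for v in g.nodes if g.out_degree(v) >= 2]

    total_length = sum(float(np.linalg.norm(pos[u] - pos[v]))
                       for u, v in g.edges)

    orders = []
    for tip in sorted(tips):
        order = 0
        v = tip
        while g.in_degree(v):
            v = next(g.predecessors(v))
            if g.out_degree(v) >= 2:
                order += g.out_degree(v) - 1
        orders.append(order)

    # maximal unbranched segments: one per tip or branch point
    branch_sum = 0
    for start in stems:
        stack = [start]
        while stack:
            v = stack.pop()
            while g.out_degree(v) == 1:
                v = next(g.successors(v))
            branch_sum += 1
            stack.extend(g.successors(v))

    n_dend = len(stems)
    rec = {
        "n_dendrites": n_dend,
        "n_ends": len(tips),
        "n_nodes": len(nodes),
        "total_length": total_length,
        "sum_terminal_orders": int(sum(orders)),
        "branch_sum": branch_sum,
        "terminal_orders": sorted(orders),
    }
    rec["avg_dendrite_length"] = total_length / n_dend
    rec["complexity"] = (rec["sum_terminal_orders"] + rec["n_ends"]) * \
        rec["avg_dendrite_length"]
    return rec


def dense_sholl(neuron: NeuronReconstruction, shell_width: float = 10.0,
                step: float = 0.01) -> dict:
    """Sholl intersections/length by dense arc-length sampling of each edge."""
    origin = neuron.soma_centroid
    dend = ~neuron.soma_mask
    dmax = float(np.linalg.norm(neuron.xyz[dend] - origin, axis=1).max())
    K = int(np.floor(dmax / shell_width)) + 1
    boundaries = shell_width * np.arange(1, K + 1)
    inter = np.zeros(K)
    length = np.zeros(K)
    for p, c in neuron.dendrite_edges():
        a = neuron.xyz[neuron.index_of(p)] - origin
        b = neuron.xyz[neuron.index_of(c)] - origin
        seg = float(np.linalg.norm(b - a))
        if seg == 0:
            continue
        n = max(2, int(np.ceil(seg / step)) + 1)
        t = np.linspace(0.0, 1.0, n)
        d = np.linalg.norm(a[None, :] + t[:, None] * (b - a)[None, :], axis=1)
        for k, r in enumerate(boundaries):
            s = np.sign(d - r)
            inter[k] += int(np.sum(s[:-1] * s[1:] < 0))
        mid = 0.5 * (d[:-1] + d[1:])
        sub = seg / (n - 1)
        for m in mid:
            length[min(int(m // shell_width), K - 1)] += sub
    return {"boundaries": boundaries, "intersections": inter,
            "length": length}


def bh_brute(pvalues) -> np.ndarray:
    """Quadratic-time Benjamini-Hochberg step-up from its definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos_i, i in enumerate(order):
        best = 1.0
        for pos_j in range(pos_i, m):
            j = order[pos_j]
            best = min(best, p[j] * m / (pos_j + 1))
        q[i] = best
    return q
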