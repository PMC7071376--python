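"""Per-neuron dendritic morphometry.

Eight scalar parameters are computed per reconstruction, matching the
Neurolucida-style vocabulary used in Golgi studies of medium spiny neurons:

- **n_dendrites** — primary dendrites (stems attached to the soma)
- **n_nodes** — branch points (points with >= 2 dendritic children)
- **n_ends** — terminal tips
- **total_length** (um) — summed Euclidean length of all dendritic segments
- **avg_dendrite_length** (um) — total_length / n_dendrites
- **sum_terminal_orders** — terminal order of a tip is the number of sister
  branches encountered tracing from that tip back to the soma (an
  unbranched dendrite's tip has order 0); summed over tips
- **branch_sum** — number of maximal unbranched segments, whose endpoints
  are soma attachments, branch points and tips
- **complexity** (um) —
  ``(sum_terminal_orders + n_ends) * (total_length / n_dendrites)``

Conventions: soma points carry no length; stems are dendrite points whose
parent is a soma point; a multifurcation with c children counts as one node
and contributes (c - 1) sisters to each descendant tip's order.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .swc import NeuronReconstruction, read_swc

MORPHOMETRY_PARAMETERS = (
    "complexity", "avg_dendrite_length", "n_nodes", "n_ends",
    "total_length", "sum_terminal_orders", "n_dendrites", "branch_sum")


@dataclass(frozen=True)
class MorphometryRecord:
    complexity: float
    avg_dendrite_length: float
    n_nodes: int
    n_ends: int
    total_length: float
    sum_terminal_orders: int
    n_dendrites: int
    branch_sum: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _dendritic_children(neuron: NeuronReconstruction) -> dict[int, list[int]]:
    """Children map restricted to non-soma points."""
    out: dict[int, list[int]] = {}
    for i in neuron.ids:
        i = int(i)
        if neuron.is_soma(i):
            continue
        out[i] = [c for c in neuron.children(i) if not neuron.is_soma(c)]
    return out


def tip_ids(neuron: NeuronReconstruction) -> list[int]:
    ch = _dendritic_children(neuron)
    return [i for i, cs in ch.items() if not cs]


def node_ids(neuron: NeuronReconstruction) -> list[int]:
    """Branch points: non-soma points with >= 2 dendritic children."""
    ch = _dendritic_children(neuron)
    return [i for i, cs in ch.items() if len(cs) >= 2]


def terminal_orders(neuron: NeuronReconstruction) -> list[int]:
    """One integer per tip: sister branches passed walking tip -> soma."""
    ch = _dendritic_children(neuron)
    orders = []
    for tip in sorted(tip_ids(neuron)):
        order = 0
        v = neuron.parent(tip)
        while v != -1 and not neuron.is_soma(v):
            c = len(ch[v])
            if c >= 2:
                order += c - 1
            v = neuron.parent(v)
        orders.append(order)
    return orders


def branch_sum(neuron: NeuronReconstruction) -> int:
    """Count maximal unbranched segments by explicit enumeration.

    Each segment starts at a soma attachment or just distal to a branch
    point and runs through single-child points until a tip or the next
    branch point.
    """
    ch = _dendritic_children(neuron)
    count = 0
    stack = list(neuron.stem_ids)
    while stack:
        v = stack.pop()
        # follow the unbranched run starting at v
        while len(ch[v]) == 1:
            v = ch[v][0]
        count += 1
        for c in ch[v]:
            stack.append(c)
    return count


def total_dendritic_length(neuron: NeuronReconstruction) -> float:
    length = 0.0
    for p, c in neuron.dendrite_edges():
        a = neuron.xyz[neuron.index_of(p)]
        b = neuron.xyz[neuron.index_of(c)]
        length += float(np.linalg.norm(b - a))
    return length


def compute_morphometry(neuron: NeuronReconstruction) -> MorphometryRecord:
    """All eight parameters for one neuron.

    Raises ``ValueError`` if the reconstruction has no dendrite stems, since
    the complexity formula divides by the number of dendrites.
    """
    n_dendrites = len(neuron.stem_ids)
    if n_dendrites == 0:
        raise ValueError(
            "reconstruction has no dendrite stems: complexity is undefined "
            "(division by zero dendrites)")
    orders = terminal_orders(neuron)
    n_ends = len(orders)
    n_nodes = len(node_ids(neuron))
    total_length = total_dendritic_length(neuron)
    sum_orders = int(sum(orders))
    avg_len = total_length / n_dendrites
    complexity = (sum_orders + n_ends) * avg_len
    return MorphometryRecord(
        complexity=complexity,
        avg_dendrite_length=avg_len,
        n_nodes=n_nodes,
        n_ends=n_ends,
        total_length=total_length,
        sum_terminal_orders=sum_orders,
        n_dendrites=n_dendrites,
        branch_sum=branch_sum(neuron),
    )


def morphometry_table(manifest: pd.DataFrame,
                      swc_dir: os.PathLike | str) -> pd.DataFrame:
    """One row of the eight parameters per manifest cell, keyed by cell_id."""
    rows = []
    for _, r in manifest.iterrows():
        neuron = read_swc(os.path.join(str(swc_dir), r["swc_path"]))
        rec = compute_morphometry(neuron).as_dict()
        rec["cell_id"] = r["cell_id"]
        rows.append(rec)
    return pd.DataFrame(rows)[["cell_id", *MORPHOMETRY_PARAMETERS]]


class MorphometryExtractor:
    """Transformer turning reconstructions into the 8-parameter feature matrix.

    Follows the scikit-learn transformer protocol (stateless: ``fit`` is a
    no-op) so morphometric features can sit inside sklearn pipelines.
    """

    def fit(self, X: Sequence[NeuronReconstruction], y=None):
        return self

    def transform(self, X: Sequence[NeuronReconstruction]) -> np.ndarray:
        return np.array([
            [getattr(compute_morphometry(n), p)
             for p in MORPHOMETRY_PARAMETERS]
            for n in X], dtype=float)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.array(MORPHOMETRY_PARAMETERS, dtype=object)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self
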