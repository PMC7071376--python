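"""Sholl analysis: dendritic measures in concentric shells around the soma.

For a shell width *w* (default 10 um) the profile reports, per shell
``[k*w, (k+1)*w)`` and per boundary sphere ``r = k*w``:

- **intersections** — transversal crossings of each boundary sphere by the
  dendritic arbour
- **length** — dendritic length falling inside each shell, apportioned by
  exact linear sub-division of every straight segment at its boundary
  crossings
- **nodes**, **ends** — branch points and tips binned by the radial
  distance of the point itself

Radial distance is 3-D Euclidean distance from the soma centroid.  Shells
are half-open, a point exactly on a boundary belongs to the outer shell,
and a segment endpoint exactly on a boundary sphere counts as a crossing
only if the segment's other endpoint is strictly inside.  Along a straight
segment the squared radial distance is quadratic in the path parameter, so
crossings and sub-spans are found by solving that quadratic rather than by
sampling; locally re-entrant segments therefore contribute one crossing per
sign change.

The area under the curve (AUC) of each measure uses the trapezoid rule, on
the boundary-radius grid for intersections and on shell midpoints for the
binned measures.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import node_ids, tip_ids
from .swc import NeuronReconstruction, read_swc

SHOLL_MEASURES = ("intersections", "length", "nodes", "ends")

_EPS = 1e-9


@dataclass(frozen=True)
class ShollProfile:
    shell_width: float
    boundaries: np.ndarray      # k*w for k = 1..K
    intersections: np.ndarray   # per boundary
    length: np.ndarray          # per shell [k*w, (k+1)*w), k = 0..K-1
    nodes: np.ndarray
    ends: np.ndarray

    @property
    def shell_midpoints(self) -> np.ndarray:
        w = self.shell_width
        return (np.arange(len(self.length)) + 0.5) * w

    def values(self, measure: str) -> tuple[np.ndarray, np.ndarray]:
        """(grid, values) for one measure, on its native radius grid."""
        if measure == "intersections":
            return self.boundaries, self.intersections
        if measure in SHOLL_MEASURES:
            return self.shell_midpoints, getattr(self, measure)
        raise KeyError(f"unknown Sholl measure {measure!r}")

    @property
    def auc(self) -> dict[str, float]:
        return {m: sholl_auc(self, m) for m in SHOLL_MEASURES}


def _segment_boundary_crossings(a: np.ndarray, b: np.ndarray,
                                r: float) -> int:
    """Transversal crossings of the sphere |x| = r by segment a -> b."""
    u = b - a
    A = float(u @ u)
    da, db = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    tol = _EPS * max(1.0, r)
    count = 0
    a_on = abs(da - r) <= tol
    b_on = abs(db - r) <= tol
    if a_on and db < r - tol:
        count += 1
    if b_on and da < r - tol:
        count += 1
    if A <= _EPS ** 2:
        return count
    B = 2.0 * float(a @ u)
    C = float(a @ a) - r * r
    disc = B * B - 4.0 * A * C
    if disc <= 0.0:
        return count
    sq = math.sqrt(disc)
    for t in ((-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)):
        if _EPS < t < 1.0 - _EPS:
            # skip roots belonging to an endpoint already handled above
            if (a_on and t < 10 * tol) or (b_on and t > 1 - 10 * tol):
                continue
            count += 1
    return count


def _segment_cut_points(a: np.ndarray, b: np.ndarray,
                        boundaries: np.ndarray) -> list[float]:
    """Path parameters in (0, 1) where the segment meets any boundary."""
    u = b - a
    A = float(u @ u)
    if A <= _EPS ** 2:
        return []
    B = 2.0 * float(a @ u)
    C0 = float(a @ a)
    ts = []
    for r in boundaries:
        disc = B * B - 4.0 * A * (C0 - r * r)
        if disc <= 0.0:
            continue
        sq = math.sqrt(disc)
        for t in ((-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)):
            if _EPS < t < 1.0 - _EPS:
                ts.append(t)
    return sorted(ts)


def sholl_profile(neuron: NeuronReconstruction,
                  shell_width: float = 10.0) -> ShollProfile:
    """Compute the full Sholl profile of one reconstruction."""
    if shell_width <= 0:
        raise ValueError("shell_width must be > 0")
    w = float(shell_width)
    origin = neuron.soma_centroid
    edges = neuron.dendrite_edges()
    dend_mask = ~neuron.soma_mask
    if not np.any(dend_mask):
        warnings.warn("empty dendritic tree: all-zero Sholl profile",
                      stacklevel=2)
        return ShollProfile(w, np.array([w]), np.zeros(1),
                            np.zeros(1), np.zeros(1), np.zeros(1))

    dists = np.linalg.norm(neuron.xyz[dend_mask] - origin, axis=1)
    # squared radial distance is convex along a straight segment, so the
    # maximum over the arbour is attained at a sample point
    K = int(math.floor(float(dists.max()) / w)) + 1
    boundaries = w * np.arange(1, K + 1)

    inter = np.zeros(K)
    length = np.zeros(K)
    for p, c in edges:
        a = neuron.xyz[neuron.index_of(p)] - origin
        b = neuron.xyz[neuron.index_of(c)] - origin
        seg_len = float(np.linalg.norm(b - a))
        for k, r in enumerate(boundaries):
            inter[k] += _segment_boundary_crossings(a, b, r)
        if seg_len > 0.0:
            ts = [0.0, *_segment_cut_points(a, b, boundaries), 1.0]
            for t0, t1 in zip(ts[:-1], ts[1:]):
                if t1 <= t0:
                    continue
                tm = 0.5 * (t0 + t1)
                d_mid = float(np.linalg.norm(a + tm * (b - a)))
                shell = min(int(d_mid // w), K - 1)
                length[shell] += seg_len * (t1 - t0)

    nodes = np.zeros(K)
    for i in node_ids(neuron):
        d = float(np.linalg.norm(neuron.xyz[neuron.index_of(i)] - origin))
        nodes[min(int(d // w), K - 1)] += 1
    ends = np.zeros(K)
    for i in tip_ids(neuron):
        d = float(np.linalg.norm(neuron.xyz[neuron.index_of(i)] - origin))
        ends[min(int(d // w), K - 1)] += 1

    return ShollProfile(w, boundaries, inter, length, nodes, ends)


def sholl_auc(profile: ShollProfile, measure: str) -> float:
    """Trapezoidal area under one Sholl measure over its radius grid."""
    grid, vals = profile.values(measure)
    if len(grid) < 2:
        raise ValueError(
            f"AUC needs >= 2 grid points for {measure!r}, got {len(grid)}")
    return float(np.trapezoid(vals, grid))


def sholl_tables(manifest: pd.DataFrame, swc_dir: os.PathLike | str,
                 shell_width: float = 10.0
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-shell values plus an AUC summary, keyed by cell_id.

    The long table has columns (cell_id, measure, radius, value), where
    radius is the boundary radius for intersections and the shell midpoint
    for binned measures.
    """
    long_rows, auc_rows = [], []
    for _, r in manifest.iterrows():
        neuron = read_swc(os.path.join(str(swc_dir), r["swc_path"]))
        prof = sholl_profile(neuron, shell_width)
        for m in SHOLL_MEASURES:
            grid, vals = prof.values(m)
            for radius, value in zip(grid, vals):
                long_rows.append({"cell_id": r["cell_id"], "measure": m,
                                  "radius": float(radius),
                                  "value": float(value)})
        auc_row = {"cell_id": r["cell_id"]}
        for m in SHOLL_MEASURES:
            try:
                auc_row[f"auc_{m}"] = sholl_auc(prof, m)
            except ValueError:
                auc_row[f"auc_{m}"] = np.nan
        auc_rows.append(auc_row)
    return pd.DataFrame(long_rows), pd.DataFrame(auc_rows)


class ShollFeaturizer:
    """sklearn-style transformer emitting the four Sholl AUC features."""

    def __init__(self, shell_width: float = 10.0):
        self.shell_width = shell_width

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        out = []
        for neuron in X:
            prof = sholl_profile(neuron, self.shell_width)
            out.append([sholl_auc(prof, m) for m in SHOLL_MEASURES])
        return np.array(out, dtype=float)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.array([f"auc_{m}" for m in SHOLL_MEASURES], dtype=object)

    def get_params(self, deep=True):
        return {"shell_width": self.shell_width}

    def set_params(self, **params):
        for k, v in params.items():
            if k != "shell_width":
                raise ValueError(f"unknown parameter {k!r}")
            self.shell_width = v
        return self
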