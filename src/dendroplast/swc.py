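"""Reading, validating and writing neuron reconstructions in SWC format.

The SWC format describes a neuron as a rooted tree of sample points, one per
line, with seven whitespace-separated columns::

    id  type  x  y  z  radius  parent

Coordinates and radii are in micrometres.  ``type`` follows the standard
convention (1 = soma, 3 = basal dendrite); ``parent`` is the id of the
point this sample attaches to, or ``-1`` for the root.  All downstream
morphometry in this package (branch orders, Sholl shells, dendritic length)
is computed from the :class:`NeuronReconstruction` built here, so parsing is
strict: duplicate ids, orphan parents, cycles, missing somata and
disconnected forests are all rejected with distinct diagnostics.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Sequence

import numpy as np

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4


class SWCError(ValueError):
    """Base class for malformed or inconsistent SWC content."""


class DuplicateIdError(SWCError):
    pass


class OrphanParentError(SWCError):
    pass


class CycleError(SWCError):
    pass


class MissingSomaError(SWCError):
    pass


class DisconnectedError(SWCError):
    pass


class NeuronReconstruction:
    """A validated rooted tree of 3-D sample points.

    Parameters
    ----------
    ids, types, parents : int arrays of length n
    xyz : float array of shape (n, 3), micrometres
    radii : float array of length n, micrometres

    Derived quantities used throughout the package:

    ``soma_centroid``
        Mean position of all soma-type points; the Sholl origin.
    ``stem_ids``
        Non-soma points whose parent is a soma point — the primary
        dendrites.
    """

    def __init__(self, ids, types, xyz, radii, parents):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.types = np.asarray(types, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.parents = np.asarray(parents, dtype=np.int64)
        n = self.ids.shape[0]
        if not (self.types.shape == (n,) and self.xyz.shape == (n, 3)
                and self.radii.shape == (n,) and self.parents.shape == (n,)):
            raise SWCError("inconsistent array shapes in reconstruction")
        self._validate()
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._children: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for i, p in zip(self.ids, self.parents):
            if p != -1:
                self._children[int(p)].append(int(i))

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        ids = self.ids
        if len(np.unique(ids)) != len(ids):
            seen: set[int] = set()
            for i in ids:
                if int(i) in seen:
                    raise DuplicateIdError(f"duplicate point id {int(i)}")
                seen.add(int(i))
        id_set = set(int(i) for i in ids)
        for i, p in zip(ids, self.parents):
            if p != -1 and int(p) not in id_set:
                raise OrphanParentError(
                    f"point {int(i)} references missing parent {int(p)}")
        if not np.any(self.types == SOMA):
            raise MissingSomaError("reconstruction contains no soma point")
        # cycle / connectivity check by walking parent chains with memoization
        parent_of = {int(i): int(p) for i, p in zip(ids, self.parents)}
        state: dict[int, int] = {}  # 0 in progress, 1 reaches a root
        n_roots = sum(1 for p in self.parents if p == -1)
        if n_roots == 0:
            raise CycleError("no root point (every point has a parent)")
        if n_roots > 1:
            raise DisconnectedError(
                f"{n_roots} root points: reconstruction is not a single tree")
        for start in parent_of:
            path = []
            v = start
            while True:
                if v in state:
                    if state[v] == 0:
                        raise CycleError(
                            f"cycle detected through point {v}")
                    break
                state[v] = 0
                path.append(v)
                p = parent_of[v]
                if p == -1:
                    break
                v = p
            for u in path:
                state[u] = 1

    # -- derived structure ----------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.ids.shape[0])

    @property
    def soma_mask(self) -> np.ndarray:
        return self.types == SOMA

    @property
    def soma_centroid(self) -> np.ndarray:
        return self.xyz[self.soma_mask].mean(axis=0)

    def index_of(self, point_id: int) -> int:
        return self._index[int(point_id)]

    def children(self, point_id: int) -> list[int]:
        return self._children[int(point_id)]

    def parent(self, point_id: int) -> int:
        return int(self.parents[self.index_of(point_id)])

    def is_soma(self, point_id: int) -> bool:
        return int(self.types[self.index_of(point_id)]) == SOMA

    @property
    def stem_ids(self) -> list[int]:
        """Ids of dendrite points attached directly to a soma point."""
        out = []
        for i, p in zip(self.ids, self.parents):
            if self.types[self.index_of(int(i))] == SOMA:
                continue
            if p != -1 and self.is_soma(int(p)):
                out.append(int(i))
        return out

    def dendrite_edges(self) -> list[tuple[int, int]]:
        """(parent_id, child_id) pairs where both endpoints are non-soma.

        These edges carry all dendritic length; soma points contribute no
        length.  Zero-length edges are legal but trigger a warning because
        they usually indicate duplicated sample points in a tracing.
        """
        edges = []
        zero = 0
        for i, p in zip(self.ids, self.parents):
            i = int(i)
            if p == -1 or self.is_soma(i) or self.is_soma(int(p)):
                continue
            edges.append((int(p), i))
            a = self.xyz[self.index_of(int(p))]
            b = self.xyz[self.index_of(i)]
            if np.allclose(a, b):
                zero += 1
        if zero:
            warnings.warn(
                f"{zero} zero-length dendrite segment(s) contribute no "
                "length and are effectively dropped", stacklevel=2)
        return edges

    # -- equality / serialization ---------------------------------------

    def __eq__(self, other) -> bool:  # structural equality, used in tests
        if not isinstance(other, NeuronReconstruction):
            return NotImplemented
        return (np.array_equal(self.ids, other.ids)
                and np.array_equal(self.types, other.types)
                and np.array_equal(self.parents, other.parents)
                and np.allclose(self.xyz, other.xyz)
                and np.allclose(self.radii, other.radii))

    def __repr__(self) -> str:
        return (f"NeuronReconstruction(n_points={self.n_points}, "
                f"n_stems={len(self.stem_ids)})")


def _parse_lines(lines: Iterable[str], source: str) -> NeuronReconstruction:
    ids, types, xyz, radii, parents = [], [], [], [], []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCError(
                f"{source}:{ln}: expected 7 columns, found {len(cols)}")
        try:
            ids.append(int(cols[0]))
            types.append(int(cols[1]))
            xyz.append([float(cols[2]), float(cols[3]), float(cols[4])])
            radii.append(float(cols[5]))
            parents.append(int(cols[6]))
        except ValueError as exc:
            raise SWCError(f"{source}:{ln}: unparsable value ({exc})") from None
    if not ids:
        raise SWCError(f"{source}: no data lines")
    return NeuronReconstruction(ids, types, np.array(xyz), radii, parents)


def read_swc(path: os.PathLike | str) -> NeuronReconstruction:
    """Parse and validate a single SWC file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_lines(fh, source=str(path))


def parse_swc_string(text: str) -> NeuronReconstruction:
    """Parse SWC content from a string (convenient for tests)."""
    return _parse_lines(text.splitlines(), source="<string>")


def swc_string(neuron: NeuronReconstruction) -> str:
    """Canonical text serialization (4 decimal places, no header).

    Writing then re-reading a canonical file reproduces it byte for byte,
    which is what makes generator determinism checkable at the file level.
    """
    out = []
    for k in range(neuron.n_points):
        x, y, z = neuron.xyz[k]
        out.append(
            f"{int(neuron.ids[k])} {int(neuron.types[k])} "
            f"{x:.4f} {y:.4f} {z:.4f} {neuron.radii[k]:.4f} "
            f"{int(neuron.parents[k])}")
    return "\n".join(out) + "\n"


def write_swc(neuron: NeuronReconstruction, path: os.PathLike | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(swc_string(neuron))
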