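"""Shared fixtures: hand-built toy trees and a small generated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from dendroplast import (CohortDesign, NeuronReconstruction, NeuronSimParams,
                         generate_cohort, morphometry_table, sholl_tables)


def build_neuron(points):
    """Construct a reconstruction from (id, type, x, y, z, parent) tuples."""
    ids = [p[0] for p in points]
    types = [p[1] for p in points]
    xyz = np.array([[p[2], p[3], p[4]] for p in points], dtype=float)
    radii = [1.0] * len(points)
    parents = [p[5] for p in points]
    return NeuronReconstruction(ids, types, xyz, radii, parents)


@pytest.fixture
def unbranched_100():
    """One straight dendrite of total length 100 um (soma at origin)."""
    pts = [(1, 1, 0.0, 0.0, 0.0, -1), (2, 3, 0.0, 0.0, 0.0, 1)]
    for k in range(1, 6):
        pts.append((2 + k, 3, 20.0 * k, 0.0, 0.0, 1 + k))
    return build_neuron(pts)


@pytest.fixture
def y_neuron():
    """One dendrite with a single bifurcation; total length 120 um.

    Stem 40 um along +x, daughters 40 um each into +-y.
    """
    pts = [
        (1, 1, 0.0, 0.0, 0.0, -1),
        (2, 3, 0.0, 0.0, 0.0, 1),
        (3, 3, 40.0, 0.0, 0.0, 2),   # branch point
        (4, 3, 40.0, 20.0, 0.0, 3),
        (5, 3, 40.0, 40.0, 0.0, 4),  # tip
        (6, 3, 40.0, -20.0, 0.0, 3),
        (7, 3, 40.0, -40.0, 0.0, 6),  # tip
    ]
    return build_neuron(pts)


@pytest.fixture
def two_dendrites():
    """Two unbranched dendrites of lengths 50 and 70 um."""
    pts = [
        (1, 1, 0.0, 0.0, 0.0, -1),
        (2, 3, 0.0, 0.0, 0.0, 1),
        (3, 3, 50.0, 0.0, 0.0, 2),
        (4, 3, 0.0, 0.0, 0.0, 1),
        (5, 3, -70.0, 0.0, 0.0, 4),
    ]
    return build_neuron(pts)


@pytest.fixture
def radial_35():
    """A straight radial dendrite reaching 35 um from the soma centroid."""
    pts = [(1, 1, 0.0, 0.0, 0.0, -1), (2, 3, 0.0, 0.0, 0.0, 1)]
    for k in range(1, 8):
        pts.append((2 + k, 3, 5.0 * k, 0.0, 0.0, 1 + k))
    return build_neuron(pts)


@pytest.fixture
def y_radial():
    """Radial stem to 15 um, bifurcation there, both tips at radius 25 um."""
    pts = [
        (1, 1, 0.0, 0.0, 0.0, -1),
        (2, 3, 0.0, 0.0, 0.0, 1),
        (3, 3, 15.0, 0.0, 0.0, 2),      # node at radius 15
        (4, 3, 24.0, 7.0, 0.0, 3),      # tip at radius 25
        (5, 3, 24.0, -7.0, 0.0, 3),     # tip at radius 25
    ]
    return build_neuron(pts)


def random_neurons(n, seed=0, **overrides):
    """Generated neurons with varied growth parameters (deterministic)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        params = NeuronSimParams(
            n_stems=int(rng.integers(1, 6)),
            branch_prob=float(rng.uniform(0.1, 0.7)),
            max_order=int(rng.integers(2, 6)),
            segment_length_mean=float(rng.uniform(15, 45)),
            segment_length_sd=float(rng.uniform(0, 15)),
            **overrides)
        out.append(generate_neuron_cached(params, (seed, k)))
    return out


def generate_neuron_cached(params, key):
    from dendroplast import generate_neuron
    return generate_neuron(params, np.random.default_rng(key))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small generated cohort with its morphometry and Sholl tables."""
    d = tmp_path_factory.mktemp("cohort")
    design = CohortDesign(animals_per_group=3, cells_per_animal=4, seed=11)
    base = NeuronSimParams(n_stems=3, max_order=4)
    manifest = generate_cohort(design, base, d)
    morpho = morphometry_table(manifest, d)
    sholl_long, sholl_auc = sholl_tables(manifest, d)
    return {"dir": d, "manifest": manifest, "morpho": morpho,
            "sholl_long": sholl_long, "sholl_auc": sholl_auc}
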