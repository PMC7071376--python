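"""Synthetic data generators: Golgi-style neuron cohorts and bulk RNA-seq counts.

The study design emulated throughout the package is a 2x2 between-animal
factorial: fluid (EtOH vs H2O) crossed with chemogenetic treatment (CNO vs
VEH), with several Golgi-stained medium spiny neurons reconstructed per
animal (nested data) and one bulk RNA-seq library per animal.

Neurons are grown by a stochastic binary branching process (a Galton-Watson
tree with a depth cap): each dendritic segment has a lognormal length, is
traced in fixed micrometre steps with small direction jitter, and bifurcates
at its distal end with probability ``branch_prob`` until ``max_order``
branch orders are reached.  Group and animal effects act multiplicatively on
``branch_prob`` — chronic EtOH raises it, and CNO removes a configurable
fraction of that increase ("amelioration") — which propagates into exactly
the statistics the morphometry stage measures (complexity, terminal orders,
branch sum, nodes, ends).

Counts are negative-binomial (gamma-Poisson) with lognormal library sizes
and planted log2 fold changes: "binge" genes respond to EtOH, a configurable
fraction of them are ameliorated (effect absent under CNO), and "cno" genes
respond to CNO in both fluids.  The truth table records every gene's class
and planted effect so recovery can be scored.

Determinism: every generator is a pure function of its parameters and seed.
Per-animal and per-cell random streams are split with
``numpy.random.SeedSequence`` keyed by (seed, stream, group, animal, cell),
so enlarging a cohort never shifts the draws of existing animals.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .swc import SOMA, BASAL_DENDRITE, NeuronReconstruction, write_swc

FLUIDS = ("EtOH", "H2O")
TREATMENTS = ("CNO", "VEH")
GROUPS = ("H2O_VEH", "H2O_CNO", "EtOH_VEH", "EtOH_CNO")

# stream keys so independent draws never share a SeedSequence
_STREAM_ANIMAL = 101
_STREAM_CELL = 102
_STREAM_COUNTS = 201
_STREAM_NEURON = 301

_BRANCH_HALF_ANGLE = 0.5  # radians between a daughter and the parent heading


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(*vals: float) -> bool:
    return all(np.isfinite(v) for v in vals)


@dataclass(frozen=True)
class NeuronSimParams:
    """Growth parameters for one simulated medium spiny neuron.

    Defaults are set to produce MSN-like trees: ~5 primary dendrites,
    a few hundred micrometres of dendrite per primary, and on the order of
    ten branch points per cell.
    """

    n_stems: int = 5
    branch_prob: float = 0.45
    max_order: int = 6
    segment_length_mean: float = 35.0  # um
    segment_length_sd: float = 12.0    # um
    step_size: float = 2.0             # um between reconstruction points
    wiggle_sd: float = 0.15            # radians of per-step heading jitter
    soma_radius: float = 8.0           # um

    def __post_init__(self):
        _check(_finite(self.branch_prob, self.segment_length_mean,
                       self.segment_length_sd, self.step_size,
                       self.wiggle_sd, self.soma_radius),
               "neuron parameters must be finite")
        _check(0.0 <= self.branch_prob <= 1.0, "branch_prob must be in [0, 1]")
        _check(self.n_stems >= 1, "n_stems must be >= 1")
        _check(self.max_order >= 1, "max_order must be >= 1")
        _check(self.segment_length_mean > 0, "segment_length_mean must be > 0")
        _check(self.segment_length_sd >= 0, "segment_length_sd must be >= 0")
        _check(self.step_size > 0, "step_size must be > 0")
        _check(self.wiggle_sd >= 0, "wiggle_sd must be >= 0")
        _check(self.soma_radius > 0, "soma_radius must be > 0")


@dataclass(frozen=True)
class CohortDesign:
    """The 2x2 nested cohort layout and its planted effects.

    ``etoh_branch_effect`` is the multiplicative increase in ``branch_prob``
    for EtOH(VEH) animals; EtOH(CNO) animals receive
    ``1 + etoh_branch_effect * (1 - cno_amelioration)``, so
    ``cno_amelioration = 1`` makes the EtOH(CNO) and H2O(CNO) branch
    probabilities identically distributed.  Animal heterogeneity is a
    lognormal multiplier with log-scale SD ``animal_effect_sd`` shared by all
    of that animal's cells.
    """

    groups: tuple[tuple[str, str], ...] = (
        ("H2O", "VEH"), ("H2O", "CNO"), ("EtOH", "VEH"), ("EtOH", "CNO"))
    animals_per_group: int = 4
    cells_per_animal: int | Sequence[int] = 7
    animal_effect_sd: float = 0.075
    etoh_branch_effect: float = 0.60
    cno_amelioration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for fluid, treatment in self.groups:
            if fluid not in FLUIDS or treatment not in TREATMENTS:
                raise ValueError(
                    f"group ({fluid}, {treatment}) is not one of the four "
                    f"design cells {FLUIDS} x {TREATMENTS}")
        _check(self.animals_per_group >= 1, "animals_per_group must be >= 1")
        cells = self.cells_per_animal
        if isinstance(cells, (int, np.integer)):
            _check(cells >= 1, "cells_per_animal must be >= 1")
        else:
            _check(len(cells) == self.animals_per_group,
                   "per-animal cell counts must match animals_per_group")
            _check(all(c >= 1 for c in cells), "cells_per_animal must be >= 1")
        _check(0.0 <= self.cno_amelioration <= 1.0,
               "cno_amelioration must be in [0, 1]")
        _check(self.animal_effect_sd >= 0, "animal_effect_sd must be >= 0")
        _check(self.etoh_branch_effect >= 0,
               "etoh_branch_effect must be >= 0")


@dataclass(frozen=True)
class CountSimParams:
    """Negative-binomial bulk RNA-seq simulation for the 2x2 design.

    ``n_binge_genes`` genes carry a planted log2 fold change in the
    EtOH(VEH) group; a fraction ``amelioration_fraction`` of them lose that
    effect under CNO (binge-ameliorated) while the rest keep it in both
    EtOH groups (binge-only).  ``n_cno_genes`` further genes respond to CNO
    in both fluids.
    """

    n_genes: int = 20000
    samples_per_group: int = 12
    lib_size_mean: float = 2e7
    lib_size_cv: float = 0.3
    dispersion: float = 0.08
    n_binge_genes: int = 600
    binge_lfc_sd: float = 1.0
    amelioration_fraction: float = 0.5
    n_cno_genes: int = 600
    seed: int = 0

    def __post_init__(self):
        _check(self.n_genes >= 1, "n_genes must be >= 1")
        if self.samples_per_group < 2:
            raise ValueError(
                "samples_per_group must be >= 2 (no residual df otherwise)")
        _check(self.lib_size_mean > 0, "lib_size_mean must be > 0")
        _check(self.lib_size_cv >= 0, "lib_size_cv must be >= 0")
        _check(self.dispersion > 0, "dispersion must be > 0")
        _check(self.n_binge_genes >= 0, "n_binge_genes must be >= 0")
        _check(self.n_cno_genes >= 0, "n_cno_genes must be >= 0")
        _check(self.n_binge_genes + self.n_cno_genes <= self.n_genes,
               "planted genes exceed n_genes")
        _check(0.0 <= self.amelioration_fraction <= 1.0,
               "amelioration_fraction must be in [0, 1]")
        _check(self.binge_lfc_sd >= 0, "binge_lfc_sd must be >= 0")


# ---------------------------------------------------------------------------
# neuron growth
# ---------------------------------------------------------------------------

def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_neuron(params: NeuronSimParams, rng_state) -> NeuronReconstruction:
    """Grow one neuron: a soma point plus ``n_stems`` stochastic dendrites.

    Stems are order-1 branches attached to the soma at the origin; a segment
    of order ``o`` bifurcates with probability ``branch_prob`` provided
    ``o < max_order``, so at most ``max_order`` branch orders exist.  With
    ``branch_prob = 1`` every dendrite is a full binary tree with
    ``2**(max_order - 1)`` tips.
    """
    rng = _as_rng(rng_state)
    mu, sigma = _lognormal_params(
        params.segment_length_mean, params.segment_length_sd)

    ids = [1]
    types = [SOMA]
    xyz = [np.zeros(3)]
    radii = [params.soma_radius]
    parents = [-1]
    next_id = 2

    # FIFO queue: (parent point id, start position, heading, branch order)
    queue: list[tuple[int, np.ndarray, np.ndarray, int]] = []
    for _ in range(params.n_stems):
        queue.append((1, np.zeros(3), _random_unit(rng), 1))

    qi = 0
    while qi < len(queue):
        parent_id, pos, heading, order = queue[qi]
        qi += 1
        length = float(np.exp(mu + sigma * rng.standard_normal()))
        n_steps = max(1, int(round(length / params.step_size)))
        step_len = length / n_steps
        d = heading
        for _ in range(n_steps):
            if params.wiggle_sd > 0:
                d = d + params.wiggle_sd * rng.standard_normal(3)
                d = d / np.linalg.norm(d)
            pos = pos + step_len * d
            ids.append(next_id)
            types.append(BASAL_DENDRITE)
            xyz.append(pos.copy())
            radii.append(0.4)
            parents.append(parent_id)
            parent_id = next_id
            next_id += 1
        if order < params.max_order and rng.random() < params.branch_prob:
            v = rng.standard_normal(3)
            e = v - np.dot(v, d) * d
            n = np.linalg.norm(e)
            e = _random_unit(rng) if n < 1e-12 else e / n
            c, s = math.cos(_BRANCH_HALF_ANGLE), math.sin(_BRANCH_HALF_ANGLE)
            for sign in (1.0, -1.0):
                daughter = c * d + sign * s * e
                queue.append((parent_id, pos.copy(),
                              daughter / np.linalg.norm(daughter), order + 1))

    return NeuronReconstruction(ids, types, np.array(xyz), radii, parents)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def group_branch_multiplier(fluid: str, treatment: str,
                            etoh_branch_effect: float,
                            cno_amelioration: float) -> float:
    """Multiplier applied to ``branch_prob`` for one design cell."""
    if fluid != "EtOH":
        return 1.0
    if treatment == "VEH":
        return 1.0 + etoh_branch_effect
    return 1.0 + etoh_branch_effect * (1.0 - cno_amelioration)


def generate_cohort(design: CohortDesign, base: NeuronSimParams,
                    out_dir: os.PathLike | str) -> pd.DataFrame:
    """Write one SWC file per cell plus ``manifest.csv``; return the manifest.

    Manifest columns: cell_id, animal_id, fluid, treatment, swc_path and the
    realized per-animal ``branch_prob`` (useful for diagnostics; downstream
    analysis modules ignore it).
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for gi, (fluid, treatment) in enumerate(design.groups):
        gmult = group_branch_multiplier(
            fluid, treatment, design.etoh_branch_effect,
            design.cno_amelioration)
        for ai in range(design.animals_per_group):
            a_rng = np.random.default_rng(np.random.SeedSequence(
                (design.seed, _STREAM_ANIMAL, gi, ai)))
            amult = float(np.exp(
                design.animal_effect_sd * a_rng.standard_normal()))
            p_animal = float(np.clip(
                base.branch_prob * amult * gmult, 0.0, 1.0))
            animal_id = f"{fluid}_{treatment}_a{ai + 1:02d}"
            cells = design.cells_per_animal
            n_cells = int(cells if isinstance(cells, (int, np.integer))
                          else cells[ai])
            for ci in range(n_cells):
                c_rng = np.random.default_rng(np.random.SeedSequence(
                    (design.seed, _STREAM_CELL, gi, ai, ci)))
                neuron = generate_neuron(
                    replace(base, branch_prob=p_animal), c_rng)
                cell_id = f"{animal_id}_c{ci + 1:02d}"
                swc_name = f"{cell_id}.swc"
                write_swc(neuron, os.path.join(out_dir, swc_name))
                rows.append({
                    "cell_id": cell_id, "animal_id": animal_id,
                    "fluid": fluid, "treatment": treatment,
                    "swc_path": swc_name, "branch_prob": p_animal,
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(params: CountSimParams
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples count matrix for the 2x2 design.

    Returns
    -------
    counts : DataFrame, genes x samples, nonnegative integers
    metadata : DataFrame with sample, group, fluid, treatment
    truth : DataFrame with gene, class in {null, binge_only,
        binge_ameliorated, cno_only} and the planted log2 fold change
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        (params.seed, _STREAM_COUNTS)))
    G = params.n_genes
    genes = np.array([f"gene{i + 1:05d}" for i in range(G)])

    # planted classes
    perm = rng.permutation(G)
    nb, nc = params.n_binge_genes, params.n_cno_genes
    n_amel = int(round(params.amelioration_fraction * nb))
    binge = perm[:nb]
    ameliorated = binge[:n_amel]
    persistent = binge[n_amel:]
    cno = perm[nb:nb + nc]
    klass = np.full(G, "null", dtype=object)
    klass[ameliorated] = "binge_ameliorated"
    klass[persistent] = "binge_only"
    klass[cno] = "cno_only"
    lfc = np.zeros(G)
    lfc[binge] = rng.normal(0.0, params.binge_lfc_sd, size=nb)
    lfc[cno] = rng.normal(0.0, params.binge_lfc_sd, size=nc)

    # per-group log2 effect matrix (genes x 4 groups)
    delta = np.zeros((G, 4))
    g_index = {g: k for k, g in enumerate(GROUPS)}
    delta[ameliorated, g_index["EtOH_VEH"]] = lfc[ameliorated]
    delta[persistent, g_index["EtOH_VEH"]] = lfc[persistent]
    delta[persistent, g_index["EtOH_CNO"]] = lfc[persistent]
    delta[cno, g_index["EtOH_CNO"]] += lfc[cno]
    delta[cno, g_index["H2O_CNO"]] += lfc[cno]

    base_log2 = rng.normal(5.0, 2.0, size=G)
    mu = np.power(2.0, base_log2)

    n = params.samples_per_group
    mu_lib, sd_lib = _lognormal_params(
        params.lib_size_mean, params.lib_size_cv * params.lib_size_mean)

    cols, col_groups, count_cols = [], [], []
    for g in GROUPS:
        w = mu * np.power(2.0, delta[:, g_index[g]])
        p = w / w.sum()
        for j in range(n):
            lib = float(np.exp(mu_lib + sd_lib * rng.standard_normal()))
            m = p * lib
            lam = rng.gamma(shape=1.0 / params.dispersion,
                            scale=m * params.dispersion)
            count_cols.append(rng.poisson(lam))
            cols.append(f"{g}_s{j + 1:02d}")
            col_groups.append(g)

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=genes, columns=cols)
    metadata = pd.DataFrame({
        "sample": cols,
        "group": col_groups,
        "fluid": [g.split("_")[0] for g in col_groups],
        "treatment": [g.split("_")[1] for g in col_groups],
    })
    truth = pd.DataFrame({"gene": genes, "class": klass, "log2fc": lfc})
    return counts, metadata, truth


# ---------------------------------------------------------------------------
# direct nested-response simulation (for statistics calibration)
# ---------------------------------------------------------------------------

def simulate_nested_response(animals_per_cell: int, cells_per_animal: int,
                             beta: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
                             sigma_u: float = 0.5, sigma_e: float = 1.0,
                             rng_state=0) -> pd.DataFrame:
    """Gaussian responses under the random-intercept model on the 2x2 design.

    ``beta`` is (intercept, fluid[EtOH], treatment[CNO], interaction).
    Returns a tidy frame with response, animal_id, fluid, treatment —
    exactly the shape the mixed-model stage consumes.  Used for type-I and
    parameter-recovery calibration of the inference engine.
    """
    rng = _as_rng(rng_state)
    b0, bf, bt, bft = beta
    rows = []
    k = 0
    for fluid in ("H2O", "EtOH"):
        for treatment in ("VEH", "CNO"):
            xf = 1.0 if fluid == "EtOH" else 0.0
            xt = 1.0 if treatment == "CNO" else 0.0
            mean = b0 + bf * xf + bt * xt + bft * xf * xt
            for _ in range(animals_per_cell):
                k += 1
                u = sigma_u * rng.standard_normal()
                eps = sigma_e * rng.standard_normal(cells_per_animal)
                for e in eps:
                    rows.append({
                        "response": mean + u + e,
                        "animal_id": f"a{k:03d}",
                        "fluid": fluid, "treatment": treatment,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML config round-trip
# ---------------------------------------------------------------------------

def config_to_dict(neuron: NeuronSimParams | None = None,
                   cohort: CohortDesign | None = None,
                   counts: CountSimParams | None = None) -> dict:
    out: dict = {}
    if neuron is not None:
        out["neuron"] = {k: getattr(neuron, k)
                         for k in NeuronSimParams.__dataclass_fields__}
    if cohort is not None:
        d = {k: getattr(cohort, k)
             for k in CohortDesign.__dataclass_fields__}
        d["groups"] = [list(g) for g in d["groups"]]
        if not isinstance(d["cells_per_animal"], (int, np.integer)):
            d["cells_per_animal"] = list(d["cells_per_animal"])
        out["cohort"] = d
    if counts is not None:
        out["counts"] = {k: getattr(counts, k)
                         for k in CountSimParams.__dataclass_fields__}
    return out


def config_from_dict(cfg: dict) -> dict:
    """Inverse of :func:`config_to_dict`; missing sections use defaults."""
    out: dict = {}
    if "neuron" in cfg:
        out["neuron"] = NeuronSimParams(**cfg["neuron"])
    if "cohort" in cfg:
        d = dict(cfg["cohort"])
        if "groups" in d:
            d["groups"] = tuple(tuple(g) for g in d["groups"])
        out["cohort"] = CohortDesign(**d)
    if "counts" in cfg:
        out["counts"] = CountSimParams(**cfg["counts"])
    return out
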