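"""Small packaged datasets: the cohort accounting table and the gene panel."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_BRAIN_COLS = [f"cells_brain{i}" for i in range(1, 6)]


def load_cohort_table() -> pd.DataFrame:
    """Per-brain neuron counts of the morphology cohort (2x2 design).

    Columns: group, fluid, treatment, n_animals, cells_brain1..5 (NaN where
    a group has fewer brains) and the published per-group totals.
    """
    with resources.files("dendroplast.data").joinpath(
            "cohort_table.csv").open("r") as fh:
        return pd.read_csv(fh)


def summarize_cohort_table(table: pd.DataFrame | None = None) -> dict:
    """Recompute group and overall totals from the per-brain counts.

    Returns a dict with ``per_group`` (group -> summed cells),
    ``total_cells``, ``total_animals`` and ``consistent`` (True when each
    recomputed group total equals the published one and the per-brain
    nonzero counts match ``n_animals``).
    """
    if table is None:
        table = load_cohort_table()
    per_group = {}
    consistent = True
    for _, r in table.iterrows():
        cells = np.array([r[c] for c in _BRAIN_COLS], dtype=float)
        total = int(np.nansum(cells))
        per_group[r["group"]] = total
        n_brains = int(np.sum(~np.isnan(cells) & (cells > 0)))
        if total != int(r["total_cells_printed"]) or \
                n_brains != int(r["n_animals"]):
            consistent = False
    return {
        "per_group": per_group,
        "total_cells": int(sum(per_group.values())),
        "total_animals": int(table["n_animals"].sum()),
        "consistent": consistent,
    }


def load_mediator_panel() -> list[str]:
    """The curated structural-plasticity mediator gene panel, in file order."""
    with resources.files("dendroplast.data").joinpath(
            "morphology_mediator_panel.txt").open("r") as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")]
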