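"""Shared fixtures: synthetic stands and hand-built rings."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import xylotrait as xt
from xylotrait.io_formats import CELL_COLUMNS


@pytest.fixture(scope="session")
def default_stand():
    """One full default stand (30 trees x 5 years) with derived traits."""
    config = xt.GeneratorConfig(rng_seed=20240521)
    rings, meta, truth = xt.simulate_dataset(config)
    cells = xt.concat_rings(rings)
    traits = xt.derive_trait_table(cells, meta)
    return {"config": config, "rings": rings, "meta": meta,
            "truth": truth, "cells": cells, "traits": traits}


def build_ring(cell_dicts) -> pd.DataFrame:
    """Assemble a canonical cell table from partial per-cell dicts."""
    defaults = {"tree_id": "T1", "year": 2012, "file_index": 1,
                "cell_index": 1, "rel_pos": 0.5, "drad_lumen": 20.0,
                "dtan_lumen": 20.0, "cwt_pi": 2.0, "cwt_ba": 2.0,
                "cwt_le": 2.0, "cwt_ri": 2.0}
    rows = []
    for spec in cell_dicts:
        row = {**defaults, **spec}
        if "lumen_area" not in row:
            row["lumen_area"] = (np.pi / 4.0) * row["drad_lumen"] * row["dtan_lumen"]
        if "cwa" not in row:
            footprint = ((row["drad_lumen"] + row["cwt_le"] + row["cwt_ri"])
                         * (row["dtan_lumen"] + row["cwt_pi"] + row["cwt_ba"]))
            row["cwa"] = footprint - row["lumen_area"]
        rows.append(row)
    return pd.DataFrame(rows)[CELL_COLUMNS]


def uniform_file(n, *, drad=20.0, cwt=2.0, dtan=20.0, file_index=1,
                 n_lw=0, lw_drad=6.0, lw_cwt=3.0):
    """One radial file of identical EW cells with an optional LW tail."""
    cells = []
    for i in range(1, n + 1):
        lw = i > n - n_lw
        cells.append({
            "file_index": file_index, "cell_index": i,
            "rel_pos": (i - 0.5) / n,
            "drad_lumen": lw_drad if lw else drad,
            "dtan_lumen": dtan,
            "cwt_pi": lw_cwt if lw else cwt, "cwt_ba": lw_cwt if lw else cwt,
            "cwt_le": lw_cwt if lw else cwt, "cwt_ri": lw_cwt if lw else cwt,
        })
    return cells


@pytest.fixture
def rng():
    return np.random.default_rng(42)
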