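"""Minimal choropleth-style plotting for lattice geometries."""

from __future__ import annotations

import re

import numpy as np


def plot_lattice_values(tract_ids, values, n_rows=None, n_cols=None, title="", ax=None):
    """Heat-map of per-tract values laid out on their r{row}c{col} lattice ids.

    Returns the matplotlib Axes; tracts whose ids do not parse as lattice
    coordinates raise, since no geometry is available for them.
    """
    import matplotlib.pyplot as plt

    coords = []
    for t in tract_ids:
        m = re.fullmatch(r"r(\d+)c(\d+)", t)
        if not m:
            raise ValueError(f"tract id {t!r} is not a lattice id; no geometry to plot")
        coords.append((int(m.group(1)), int(m.group(2))))
    rows = np.array([c[0] for c in coords])
    cols = np.array([c[1] for c in coords])
    n_rows = n_rows or rows.max() + 1
    n_cols = n_cols or cols.max() + 1
    grid = np.full((n_rows, n_cols), np.nan)
    grid[rows, cols] = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, n_cols / 3), max(3, n_rows / 3)))
    im = ax.imshow(grid, cmap="RdYlBu_r")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
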