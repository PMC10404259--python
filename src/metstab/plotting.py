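"""Thin matplotlib layer for AMMI1 and GGE biplots (all analysis stays tabular)."""

from __future__ import annotations

import numpy as np

from .ammi import Ammi1Coords
from .gge import GGEFit, SectorAssignment


def plot_ammi1(coords: Ammi1Coords, ax=None):
    """Mean vs IPCA1 biplot: genotypes as points, environments as triangles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    gen, env = coords.genotypes, coords.environments
    ax.scatter(gen["mean"], gen["ipca1"], s=12, label="genotypes")
    ax.scatter(env["mean"], env["ipca1"], marker="^", color="firebrick",
               label="environments")
    for name, row in env.iterrows():
        ax.annotate(name, (row["mean"], row["ipca1"]), fontsize=8)
    ax.axvline(coords.grand_mean, ls="--", lw=0.8, color="grey")
    ax.axhline(0.0, ls="-", lw=0.8, color="grey")
    ax.set_xlabel("marginal mean")
    ax.set_ylabel("IPCA1 score")
    ax.legend(fontsize=8)
    return ax


def plot_gge(fit: GGEFit, sectors: SectorAssignment | None = None, ax=None):
    """GGE biplot with optional convex hull and sector boundary rays."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    g = fit.genotype_coords
    e = fit.environment_coords
    ax.scatter(g["axis1"], g["axis2"], s=12, label="genotypes")
    for name, row in e.iterrows():
        ax.plot([0, row["axis1"]], [0, row["axis2"]], color="firebrick", lw=1)
        ax.annotate(name, (row["axis1"], row["axis2"]), fontsize=8,
                    color="firebrick")
    if sectors is not None:
        hull = g.loc[sectors.hull_vertices + sectors.hull_vertices[:1]]
        ax.plot(hull["axis1"], hull["axis2"], color="steelblue", lw=1)
        rmax = 1.1 * float(np.abs(np.concatenate([g.to_numpy().ravel(),
                                                  e.to_numpy().ravel()])).max())
        for ang in sectors.sector_boundaries:
            ax.plot([0, rmax * np.cos(ang)], [0, rmax * np.sin(ang)],
                    ls=":", lw=0.8, color="grey")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"axis 1 ({fit.pct_explained:.1f}% G+GE in 2-D)")
    ax.set_ylabel("axis 2")
    ax.set_aspect("equal", adjustable="datalim")
    return ax
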