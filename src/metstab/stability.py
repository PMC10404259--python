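"""MASI stability index, ranking, and the simultaneous selection index (SSI).

MASI (modified AMMI stability index) summarizes a genotype's interaction
scores over the first N' principal-component axes, weighting each axis by its
share theta_n of the interaction sum of squares:

    MASI_i = sqrt( sum_{n=1..N'} PC_in^2 * theta_n^2 )

Smaller MASI means more stable.  The simultaneous selection index combines
stability with performance:

    SSI_i = rank(MASI_i, ascending) + rank(mean_i, descending)

so the genotype(s) with the lowest SSI are jointly stable and high-yielding.
Because MASI is positively homogeneous in theta, rescaling all theta_n by a
common constant rescales MASI but cannot change any rank or SSI.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ammi import AmmiFit
from .met_core import AxisError


def masi(scores: np.ndarray | pd.DataFrame, theta: np.ndarray) -> np.ndarray:
    """Per-genotype MASI from a g x N' score matrix and N' axis weights."""
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    t = np.asarray(theta, dtype=float)
    if t.ndim != 1 or s.shape[1] != t.shape[0]:
        raise ValueError(
            f"shape mismatch: scores {s.shape} vs theta length {t.shape}"
        )
    return np.sqrt((s ** 2 * t ** 2).sum(axis=1))


def rank_values(values, direction: str = "ascending") -> np.ndarray:
    """Integer competition-free ranks, best value = 1.

    ``ascending`` ranks the smallest value first (stability indices),
    ``descending`` the largest first (performance means).  Ties receive
    consecutive integer ranks broken by input order (stable sort), so ranks
    are always a permutation of 1..n.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("cannot rank non-finite values")
    if direction == "ascending":
        order = np.argsort(v, kind="stable")
    elif direction == "descending":
        order = np.argsort(-v, kind="stable")
    else:
        raise ValueError(f"direction must be ascending|descending, got {direction!r}")
    ranks = np.empty(len(v), dtype=int)
    ranks[order] = np.arange(1, len(v) + 1)
    return ranks


@dataclasses.dataclass
class StabilityTable:
    """Per-genotype MASI / mean / ranks / SSI, one row per genotype."""

    table: pd.DataFrame        # genotype, masi, r_masi, mean, r_mean, ssi
    trait: str
    n_axes_used: int
    theta_used: np.ndarray
    selected: list[str]        # genotype(s) attaining the minimum SSI
    tied_masi: list[tuple[str, ...]] = dataclasses.field(default_factory=list)


def ssi_table(fit: AmmiFit, n_axes: int | None = None,
              trait: str = "value") -> StabilityTable:
    """Build the MASI / rank / SSI table from a fitted AMMI model.

    ``n_axes`` defaults to all K = min(g-1, e-1) axes.  The genotype mean is
    the marginal mean across environments (identical to the least-squares
    adjusted mean under balance).  Exact MASI ties are reported in
    ``tied_masi`` because their relative ranks are decided by input order.
    """
    k = fit.n_axes if n_axes is None else n_axes
    if not 1 <= k <= fit.n_axes:
        raise AxisError(f"n_axes={k} outside 1..{fit.n_axes}")
    scores = fit.genotype_scores.to_numpy()[:, :k]
    theta = fit.theta[:k]
    m = masi(scores, theta)
    means = fit.genotype_means().to_numpy()
    r_masi = rank_values(m, "ascending")
    r_mean = rank_values(means, "descending")
    ssi = r_masi + r_mean
    table = pd.DataFrame({
        "genotype": fit.genotypes,
        "masi": m,
        "r_masi": r_masi,
        "mean": means,
        "r_mean": r_mean,
        "ssi": ssi,
    })
    best = int(ssi.min())
    selected = [g for g, s in zip(fit.genotypes, ssi) if s == best]
    ties = []
    for val, grp in pd.Series(fit.genotypes).groupby(pd.Series(m)):
        if len(grp) > 1:
            ties.append(tuple(grp))
    return StabilityTable(table=table, trait=trait, n_axes_used=k,
                          theta_used=theta.copy(), selected=selected,
                          tied_masi=ties)


def rank_table(masi_values, means, genotypes=None) -> pd.DataFrame:
    """Rank/SSI layer applied to externally supplied MASI and mean columns.

    Useful for re-deriving the rank columns of a published stability table
    from its printed MASI and mean values.
    """
    m = np.asarray(masi_values, dtype=float)
    mu = np.asarray(means, dtype=float)
    if m.shape != mu.shape:
        raise ValueError("masi_values and means must have equal length")
    r_masi = rank_values(m, "ascending")
    r_mean = rank_values(mu, "descending")
    out = pd.DataFrame({
        "masi": m, "r_masi": r_masi, "mean": mu, "r_mean": r_mean,
        "ssi": r_masi + r_mean,
    })
    if genotypes is not None:
        out.insert(0, "genotype", list(genotypes))
    return out
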