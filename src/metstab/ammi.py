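"""AMMI analysis: RCBD-across-environments ANOVA plus SVD of the interaction.

The additive main effects and multiplicative interaction (AMMI) model for a
balanced g x e x r trial is

    Y_ijk = mu + G_i + E_j + sum_k lambda_k alpha_ik gamma_jk + d_ij + e_ijk

where the multiplicative terms come from the singular value decomposition of
the doubly-centered cell-mean matrix

    Z_ij = ybar_ij. - ybar_i.. - ybar_.j. + ybar...

Axis k carries interaction sum of squares r * lambda_k^2 on the observation
scale, tested with Gollob degrees of freedom g + e - 1 - 2k.  The ANOVA
strata are Environment (tested against the replicate-within-environment mean
square, the standard convention for blocks nested in environments), Rep(E),
Genotype, the interaction (GEI), its principal-component rows, and the pooled
residual.

The interaction sum of squares is further split into "signal" and "noise":
noise is what pure error would contribute to the interaction stratum,
df_GEI * MS_residual, and signal is the remainder.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .met_core import AxisError, CellMeansMatrix, DesignError, METDataset, cell_means

ANOVA_MAIN_SOURCES = ("Environment", "Rep(Environment)", "Genotype", "GEI", "Residuals")


def gollob_df(g: int, e: int, k: int) -> int:
    """Degrees of freedom for the k-th interaction principal component."""
    kmax = min(g - 1, e - 1)
    if not 1 <= k <= kmax:
        raise AxisError(f"axis k={k} outside 1..min(g-1, e-1)={kmax}")
    return g + e - 1 - 2 * k


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _interaction_matrix(cm: CellMeansMatrix) -> np.ndarray:
    m = cm.matrix.to_numpy()
    return m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + m.mean()


def ammi_anova(data: METDataset) -> pd.DataFrame:
    """ANOVA table for a balanced RCBD trial replicated across environments.

    Rows: Environment, Rep(Environment), Genotype, GEI, PC1..PCK, Residuals.
    Columns: ``df``, ``ss``, ``ms``, ``F``, ``p``, ``signif``.  The F ratio
    for Environment uses the Rep(Environment) mean square as denominator; all
    other effects are tested against the pooled residual mean square.  PC
    rows use Gollob df and partition the GEI sum of squares exactly.
    """
    g, e, r = data.g, data.e, data.r
    if r < 2:
        raise DesignError("no residual stratum with a single replicate")
    y = data.value_array()               # (g, e, r)
    grand = y.mean()
    gmeans = y.mean(axis=(1, 2))         # genotype means
    emeans = y.mean(axis=(0, 2))         # environment means
    repmeans = y.mean(axis=0)            # (e, r) block means
    cellm = y.mean(axis=2)               # (g, e)

    ss_e = g * r * float(((emeans - grand) ** 2).sum())
    ss_rep = g * float(((repmeans - emeans[:, None]) ** 2).sum())
    ss_g = e * r * float(((gmeans - grand) ** 2).sum())
    z = cellm - gmeans[:, None] - emeans[None, :] + grand
    ss_gei = r * float((z ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_e - ss_rep - ss_g - ss_gei

    df_e, df_rep, df_g = e - 1, e * (r - 1), g - 1
    df_gei, df_resid = (g - 1) * (e - 1), e * (g - 1) * (r - 1)
    ms = {
        "Environment": ss_e / df_e,
        "Rep(Environment)": ss_rep / df_rep,
        "Genotype": ss_g / df_g,
        "GEI": ss_gei / df_gei,
        "Residuals": max(ss_resid, 0.0) / df_resid,
    }
    ms_resid = ms["Residuals"]

    def row(source, df, ss, denom_ms, denom_df):
        if denom_ms is None:
            return dict(source=source, df=df, ss=ss, ms=ss / df,
                        F=np.nan, p=np.nan, signif="")
        mean_sq = ss / df
        if denom_ms > 0:
            f = mean_sq / denom_ms
            p = float(stats.f.sf(f, df, denom_df))
        else:
            f, p = np.inf, 0.0
        return dict(source=source, df=df, ss=ss, ms=mean_sq, F=f, p=p,
                    signif=_stars(p))

    rows = [
        row("Environment", df_e, ss_e, ms["Rep(Environment)"], df_rep),
        row("Rep(Environment)", df_rep, ss_rep, ms_resid, df_resid),
        row("Genotype", df_g, ss_g, ms_resid, df_resid),
        row("GEI", df_gei, ss_gei, ms_resid, df_resid),
    ]
    lam = np.linalg.svd(z, compute_uv=False)
    kmax = min(g - 1, e - 1)
    for k in range(1, kmax + 1):
        ss_pc = r * float(lam[k - 1] ** 2)
        rows.append(row(f"PC{k}", gollob_df(g, e, k), ss_pc, ms_resid, df_resid))
    rows.append(row("Residuals", df_resid, max(ss_resid, 0.0), None, None))
    table = pd.DataFrame(rows).set_index("source")
    return table


def percent_ss(anova: pd.DataFrame) -> pd.DataFrame:
    """Add a ``pct_ss`` column to an ANOVA table.

    Main sources (Environment, Rep(Environment), Genotype, GEI, Residuals)
    are expressed as a percentage of their summed SS; PC rows as a percentage
    of the GEI SS.  Values are carried unrounded.
    """
    out = anova.copy()
    main = [s for s in ANOVA_MAIN_SOURCES if s in out.index]
    total = float(out.loc[main, "ss"].sum())
    pct = pd.Series(np.nan, index=out.index, dtype=float)
    if total > 0:
        pct[main] = 100.0 * out.loc[main, "ss"] / total
    ss_gei = float(out.loc["GEI", "ss"]) if "GEI" in out.index else 0.0
    pc_rows = [s for s in out.index if s.startswith("PC")]
    if ss_gei > 0:
        pct[pc_rows] = 100.0 * out.loc[pc_rows, "ss"] / ss_gei
    out["pct_ss"] = pct
    return out


def ipca_pct_of_gei(ss_pc: float, ss_gei: float) -> float | None:
    """Share (%) of the interaction SS carried by one principal component.

    Returns ``None`` when the interaction SS is zero (share undefined).
    """
    if ss_gei == 0:
        return None
    if not 0 <= ss_pc <= ss_gei * (1 + 1e-12):
        raise ValueError(f"need 0 <= ss_pc <= ss_gei, got {ss_pc} vs {ss_gei}")
    return 100.0 * ss_pc / ss_gei


@dataclasses.dataclass
class SignalNoise:
    """Partition of the interaction SS into signal and pure-error noise."""

    ss_signal: float
    ss_noise: float
    pct_signal: float
    pct_noise: float


def partition_signal_noise(ss_gei: float, df_gei: int, ms_resid: float) -> SignalNoise:
    """Split SS_GEI into noise (df_GEI * MS_resid) and signal (the rest)."""
    if ss_gei < 0 or ms_resid < 0:
        raise ValueError("sums of squares and mean squares must be >= 0")
    if df_gei < 1:
        raise ValueError("df_gei must be >= 1")
    if ss_gei == 0:
        raise ValueError("SS_GEI is zero: signal/noise partition undefined")
    ss_noise = df_gei * ms_resid
    if ss_noise > ss_gei:
        warnings.warn(
            f"estimated noise SS ({ss_noise:.4g}) exceeds SS_GEI ({ss_gei:.4g}); "
            "clamping — the interaction is indistinguishable from pure error",
            stacklevel=2,
        )
        ss_noise = ss_gei
    ss_signal = ss_gei - ss_noise
    return SignalNoise(
        ss_signal=ss_signal,
        ss_noise=ss_noise,
        pct_signal=100.0 * ss_signal / ss_gei,
        pct_noise=100.0 * ss_noise / ss_gei,
    )


@dataclasses.dataclass
class AmmiFit:
    """Fitted AMMI decomposition of a balanced trial.

    ``genotype_scores``/``environment_scores`` are symmetrically scaled IPCA
    scores (singular vector entry times sqrt(singular value)), the scaling
    used for AMMI biplots; the raw orthonormal singular vectors are kept in
    ``genotype_vectors``/``environment_vectors``.  ``theta`` holds the
    per-axis proportions of the interaction SS, lambda_k^2 / sum(lambda^2).
    """

    mu: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    singular_values: np.ndarray
    theta: np.ndarray
    genotype_scores: pd.DataFrame
    environment_scores: pd.DataFrame
    genotype_vectors: pd.DataFrame
    environment_vectors: pd.DataFrame
    anova: pd.DataFrame
    n_reps: int

    @property
    def genotypes(self) -> list[str]:
        return list(self.genotype_effects.index)

    @property
    def environments(self) -> list[str]:
        return list(self.environment_effects.index)

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    def interaction_matrix(self, n_axes: int | None = None) -> pd.DataFrame:
        """Rank-``n_axes`` reconstruction of the interaction matrix Z."""
        k = self.n_axes if n_axes is None else n_axes
        if not 0 <= k <= self.n_axes:
            raise AxisError(f"n_axes={k} outside 0..{self.n_axes}")
        u = self.genotype_vectors.to_numpy()[:, :k]
        v = self.environment_vectors.to_numpy()[:, :k]
        z = u @ np.diag(self.singular_values[:k]) @ v.T
        return pd.DataFrame(z, index=self.genotypes, columns=self.environments)

    def residual_matrix(self, n_axes: int) -> pd.DataFrame:
        """Interaction left unexplained (d_ij) when only ``n_axes`` are kept."""
        return self.interaction_matrix(None) - self.interaction_matrix(n_axes)

    def reconstruct(self, n_axes: int | None = None) -> pd.DataFrame:
        """Cell means implied by mu + G_i + E_j + truncated interaction."""
        add = (self.mu
               + self.genotype_effects.to_numpy()[:, None]
               + self.environment_effects.to_numpy()[None, :])
        return pd.DataFrame(add, index=self.genotypes,
                            columns=self.environments) + self.interaction_matrix(n_axes)

    def genotype_means(self) -> pd.Series:
        return self.mu + self.genotype_effects

    def environment_means(self) -> pd.Series:
        return self.mu + self.environment_effects


def fit_ammi(data: METDataset) -> AmmiFit:
    """Fit the AMMI model to a balanced dataset.

    Each axis is oriented so the genotype singular-vector entry of largest
    magnitude is positive, making results deterministic across linear-algebra
    backends (an SVD is otherwise only defined up to per-axis sign).
    """
    cm = cell_means(data)
    m = cm.matrix.to_numpy()
    mu = float(m.mean())
    geno_eff = m.mean(axis=1) - mu
    env_eff = m.mean(axis=0) - mu
    z = _interaction_matrix(cm)

    u, lam, vt = np.linalg.svd(z, full_matrices=False)
    kmax = min(data.g - 1, data.e - 1)
    u, lam, v = u[:, :kmax], lam[:kmax], vt[:kmax].T
    # singular values at rounding-noise level are exact zeros of the model
    lam = np.where(lam < 1e-10 * max(1.0, float(np.abs(m).max())), 0.0, lam)
    for k in range(kmax):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    ss_lam = float((lam ** 2).sum())
    theta = lam ** 2 / ss_lam if ss_lam > 0 else np.zeros_like(lam)
    scale = np.sqrt(lam)
    axes = [f"IPCA{k + 1}" for k in range(kmax)]

    return AmmiFit(
        mu=mu,
        genotype_effects=pd.Series(geno_eff, index=cm.genotypes, name="G_i"),
        environment_effects=pd.Series(env_eff, index=cm.environments, name="E_j"),
        singular_values=lam,
        theta=theta,
        genotype_scores=pd.DataFrame(u * scale, index=cm.genotypes, columns=axes),
        environment_scores=pd.DataFrame(v * scale, index=cm.environments, columns=axes),
        genotype_vectors=pd.DataFrame(u, index=cm.genotypes, columns=axes),
        environment_vectors=pd.DataFrame(v, index=cm.environments, columns=axes),
        anova=percent_ss(ammi_anova(data)),
        n_reps=data.r,
    )


@dataclasses.dataclass
class Ammi1Coords:
    """Coordinates for the AMMI1 biplot: marginal mean vs IPCA1 score."""

    genotypes: pd.DataFrame     # columns: mean, ipca1
    environments: pd.DataFrame  # columns: mean, ipca1
    grand_mean: float


def ammi1_coords(fit: AmmiFit) -> Ammi1Coords:
    """Mean-performance vs first-interaction-axis coordinates for both sets."""
    gen = pd.DataFrame({
        "mean": fit.genotype_means(),
        "ipca1": fit.genotype_scores.iloc[:, 0],
    })
    env = pd.DataFrame({
        "mean": fit.environment_means(),
        "ipca1": fit.environment_scores.iloc[:, 0],
    })
    return Ammi1Coords(genotypes=gen, environments=env, grand_mean=fit.mu)
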