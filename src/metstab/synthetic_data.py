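"""Synthetic balanced MET generator with known additive + multiplicative truth.

Data are generated from the same model the AMMI analysis fits:

    Y_ijk = mu + G_i + E_j + sum_k lambda_k * alpha_ik * gamma_jk
            + b_jk + eps_ijk

with genotype and environment main effects exactly centered, interaction
score vectors (alpha, gamma) centered and orthonormal so the planted
multiplicative term is a valid interaction (zero row and column sums — it
cannot leak into the main effects), replicate-within-environment block
effects b_jk, and i.i.d. Gaussian residuals eps_ijk.

Main-effect vectors are drawn from a standard normal, centered, then rescaled
so their sum of squares is exactly (n-1)*sd**2: the *direction* of the effect
pattern is random but its magnitude is deterministic, which makes the expected
ANOVA sums of squares of simulated data match the configured variance
components without Monte-Carlo drift from the tiny environment dimension.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .met_core import METDataset


@dataclasses.dataclass
class SyntheticConfig:
    """Generative parameters for a balanced g x e x r trial.

    ``gei_singular_values`` are the planted interaction singular values on the
    cell-mean scale; the ANOVA interaction sum of squares they induce is
    ``r * sum(lambda_k**2)``.
    """

    g: int = 30
    e: int = 3
    r: int = 2
    mu: float = 190.0
    genotype_sd: float = 25.0
    environment_sd: float = 150.0
    gei_singular_values: tuple[float, ...] = (400.0, 150.0)
    rep_sd: float = 2.0
    noise_sd: float = 20.0
    rainfall: tuple[float, ...] = (504.1, 228.0, 538.2)
    seed: int = 0

    def validate(self) -> None:
        if self.g < 2 or self.e < 2 or self.r < 2:
            raise ValueError(f"need g,e,r >= 2, got ({self.g},{self.e},{self.r})")
        for name in ("genotype_sd", "environment_sd", "rep_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        k = len(self.gei_singular_values)
        kmax = min(self.g - 1, self.e - 1)
        if k > kmax:
            raise ValueError(
                f"{k} planted singular values exceed the rank bound min(g-1,e-1)={kmax}"
            )
        if any(s < 0 for s in self.gei_singular_values):
            raise ValueError("planted singular values must be >= 0")
        if len(self.rainfall) != self.e:
            raise ValueError(
                f"rainfall has {len(self.rainfall)} entries for e={self.e} environments"
            )
        if any(x <= 0 for x in self.rainfall):
            raise ValueError("rainfall must be positive")


@dataclasses.dataclass
class SyntheticTruth:
    """Exact planted components returned alongside the generated data."""

    mu: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame      # alpha, g x k, orthonormal centered columns
    environment_scores: pd.DataFrame   # gamma, e x k, orthonormal centered columns
    rep_effects: pd.DataFrame          # e x r block effects
    cell_expectation: pd.DataFrame     # g x e noise-free cell means
    rainfall: pd.Series


def _centered_scaled(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Centered normal draw rescaled to sum of squares exactly (n-1)*sd^2."""
    if sd == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    x = x - x.mean()
    norm = np.sqrt((x ** 2).sum())
    if norm == 0:  # probability-zero degenerate draw
        x = np.arange(n, dtype=float) - (n - 1) / 2
        norm = np.sqrt((x ** 2).sum())
    return x * (sd * np.sqrt(n - 1) / norm)


def _orthonormal_centered(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n x k matrix with orthonormal, zero-sum columns."""
    if k == 0:
        return np.zeros((n, 0))
    m = rng.standard_normal((n, k))
    m = m - m.mean(axis=0)
    q, _ = np.linalg.qr(m)
    q = q[:, :k]
    # deterministic orientation: largest-|entry| of each column positive
    for j in range(k):
        i = int(np.argmax(np.abs(q[:, j])))
        if q[i, j] < 0:
            q[:, j] = -q[:, j]
    return q


def generate_met(config: SyntheticConfig, trait: str = "pod_yield",
                 units: str = "g/m^2") -> tuple[METDataset, SyntheticTruth]:
    """Generate a balanced dataset plus its exact planted truth record.

    The same config and seed always yield byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, e, r = config.g, config.e, config.r
    k = len(config.gei_singular_values)

    genotypes = [f"G{i + 1:02d}" for i in range(g)]
    environments = [f"E{j + 1}" for j in range(e)]
    replicates = [f"R{l + 1}" for l in range(r)]

    geno_eff = _centered_scaled(rng, g, config.genotype_sd)
    env_eff = _centered_scaled(rng, e, config.environment_sd)
    alpha = _orthonormal_centered(rng, g, k)
    gamma = _orthonormal_centered(rng, e, k)
    lam = np.asarray(config.gei_singular_values, dtype=float)
    interaction = alpha @ np.diag(lam) @ gamma.T if k else np.zeros((g, e))

    cell = config.mu + geno_eff[:, None] + env_eff[None, :] + interaction
    rep_eff = rng.normal(0.0, config.rep_sd, size=(e, r)) if config.rep_sd > 0 \
        else np.zeros((e, r))
    noise = rng.normal(0.0, config.noise_sd, size=(g, e, r)) if config.noise_sd > 0 \
        else np.zeros((g, e, r))

    rows = []
    for i, gen in enumerate(genotypes):
        for j, env in enumerate(environments):
            for l, rep in enumerate(replicates):
                rows.append((gen, env, rep, cell[i, j] + rep_eff[j, l] + noise[i, j, l]))
    data = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "value"])
    dataset = METDataset(data, trait=trait, units=units)

    axes = [f"IPCA{n + 1}" for n in range(k)]
    truth = SyntheticTruth(
        mu=config.mu,
        genotype_effects=pd.Series(geno_eff, index=genotypes, name="G_i"),
        environment_effects=pd.Series(env_eff, index=environments, name="E_j"),
        singular_values=lam,
        genotype_scores=pd.DataFrame(alpha, index=genotypes, columns=axes),
        environment_scores=pd.DataFrame(gamma, index=environments, columns=axes),
        rep_effects=pd.DataFrame(rep_eff, index=environments, columns=replicates),
        cell_expectation=pd.DataFrame(cell, index=genotypes, columns=environments),
        rainfall=pd.Series(config.rainfall, index=environments, name="rainfall_mm"),
    )
    return dataset, truth


def groundnut_trial_config(seed: int = 0) -> SyntheticConfig:
    """Config emulating a 30-genotype, three-rainy-season rainfed groundnut trial.

    Dimensions are 30 genotypes x 3 environments x 2 replicate blocks (RCBD),
    with seasonal cumulative rainfall 504.1 / 228.0 / 538.2 mm.  Effect scales
    are tuned so the expected ANOVA sum-of-squares shares on the pod-yield
    scale are approximately environment 82%, genotype 4%, interaction 13%,
    replicate-within-environment 0.05% and residual 1.1% — a trial dominated
    by season-to-season rainfall contrast with a moderate, low-rank
    genotype-by-environment interaction:

    * residual sigma^2 = 464 (g/m^2)^2, so E[SS_resid] = 87 * 464;
    * environment_sd solves g*r*(e-1)*sd^2 + (e-1)*sigma^2 ~= 3.01e6;
    * genotype_sd solves e*r*(g-1)*sd^2 + (g-1)*sigma^2 ~= 1.58e5;
    * planted singular values (440, 170) give r*sum(lambda^2) ~= 4.44e5 of
      interaction signal, split ~87/13 between the two axes;
    * rep_sd solves e*(r-1)*(g*sd^2 + sigma^2) ~= 1.7e3.
    """
    return SyntheticConfig(
        g=30, e=3, r=2,
        mu=190.0,
        genotype_sd=28.82,
        environment_sd=158.35,
        gei_singular_values=(440.0, 170.0),
        rep_sd=1.886,
        noise_sd=21.54,
        rainfall=(504.1, 228.0, 538.2),
        seed=seed,
    )
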