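"""Core containers and I/O for balanced multi-environment trials (METs).

A MET here is a randomized complete block design replicated across
environments: every genotype is observed in every environment in every
replicate block, exactly once.  All downstream analyses (AMMI ANOVA,
stability indices, GGE biplots) assume this balance, so unbalanced data are
rejected at load time rather than imputed — imputation would silently change
every downstream sum of squares.

Genotype and environment ordering is first-appearance order in the input,
never lexicographic, so score tables align with the user's file.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("genotype", "environment", "replicate", "value")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MetError(Exception):
    """Base class for all metstab errors."""


class FormatError(MetError):
    """Input file malformed: missing columns or unparseable values."""


class BalanceError(MetError):
    """Design incomplete: not exactly one observation per (g, e, r) triple."""

    def __init__(self, message: str, missing=(), duplicated=()):
        super().__init__(message)
        self.missing = list(missing)
        self.duplicated = list(duplicated)


class MetadataError(MetError):
    """Environment metadata absent or invalid (e.g. missing rainfall)."""


class DesignError(MetError):
    """Design too small for the requested analysis (e.g. r = 1)."""


class AxisError(MetError):
    """A principal-component axis index outside 1..min(g-1, e-1)."""


class GeometryError(MetError):
    """Degenerate biplot geometry (collinear or coincident points)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class METDataset:
    """Balanced long-format trial observations.

    Parameters
    ----------
    data
        Long-format frame with columns ``genotype``, ``environment``,
        ``replicate`` and ``value`` (one observation per row).
    trait
        Name of the measured trait, e.g. ``"pod_yield"``.
    units
        Optional unit string, e.g. ``"g/m^2"``.

    Raises
    ------
    BalanceError
        If the design is not complete (g*e*r rows, one per triple).
    FormatError
        If a key is empty or a value is non-finite.
    """

    data: pd.DataFrame
    trait: str = "value"
    units: str | None = None
    genotypes: list[str] = dataclasses.field(init=False)
    environments: list[str] = dataclasses.field(init=False)
    replicates: list[str] = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise FormatError(f"missing required column(s): {missing_cols}")
        df = self.data.loc[:, list(REQUIRED_COLUMNS)].copy()
        for key in ("genotype", "environment", "replicate"):
            df[key] = df[key].astype(str)
            if (df[key].str.strip() == "").any():
                raise FormatError(f"empty {key} identifier in input")
        values = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise FormatError(f"non-finite/non-numeric value(s) at row(s) {rows}")
        df["value"] = values
        self.data = df.reset_index(drop=True)
        self.genotypes = list(pd.unique(df["genotype"]))
        self.environments = list(pd.unique(df["environment"]))
        self.replicates = list(pd.unique(df["replicate"]))
        self._check_balance()

    def _check_balance(self) -> None:
        g, e, r = len(self.genotypes), len(self.environments), len(self.replicates)
        if g < 2 or e < 2:
            raise DesignError(f"need >= 2 genotypes and environments, got g={g}, e={e}")
        if r < 2:
            raise DesignError(f"need >= 2 replicates, got r={r}")
        observed = list(
            zip(self.data["genotype"], self.data["environment"], self.data["replicate"])
        )
        counts: dict[tuple, int] = {}
        for key in observed:
            counts[key] = counts.get(key, 0) + 1
        expected = set(product(self.genotypes, self.environments, self.replicates))
        missing = sorted(expected - counts.keys())
        duplicated = sorted(k for k, n in counts.items() if n > 1)
        extra = sorted(counts.keys() - expected)
        if missing or duplicated or extra:
            raise BalanceError(
                "unbalanced design: "
                f"{len(missing)} missing triple(s) {missing[:5]}, "
                f"{len(duplicated)} duplicated, {len(extra)} unexpected",
                missing=missing,
                duplicated=duplicated + extra,
            )

    # -- convenience -------------------------------------------------------
    @property
    def g(self) -> int:
        return len(self.genotypes)

    @property
    def e(self) -> int:
        return len(self.environments)

    @property
    def r(self) -> int:
        return len(self.replicates)

    def grand_mean(self) -> float:
        return float(self.data["value"].mean())

    def value_array(self) -> np.ndarray:
        """Observations as a (g, e, r) array in dataset label order."""
        gi = {k: i for i, k in enumerate(self.genotypes)}
        ej = {k: j for j, k in enumerate(self.environments)}
        rk = {k: l for l, k in enumerate(self.replicates)}
        out = np.empty((self.g, self.e, self.r), dtype=float)
        for gen, env, rep, val in self.data.itertuples(index=False):
            out[gi[gen], ej[env], rk[rep]] = val
        return out


@dataclasses.dataclass
class CellMeansMatrix:
    """g x e matrix of genotype-within-environment means."""

    matrix: pd.DataFrame  # index = genotypes, columns = environments
    n_reps: int

    @property
    def genotypes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def environments(self) -> list[str]:
        return list(self.matrix.columns)

    def grand_mean(self) -> float:
        return float(self.matrix.to_numpy().mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_met(path: str | Path, trait: str = "value", units: str | None = None) -> METDataset:
    """Load a long-format MET table from CSV.

    The header must declare ``genotype,environment,replicate,value``.
    Genotype/environment order is taken from first appearance in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    # parse with Python's float for exact (shortest-repr) round-tripping
    values = np.empty(len(df))
    bad = []
    for i, s in enumerate(df["value"]):
        try:
            values[i] = float(s)
        except (TypeError, ValueError):
            bad.append(i)
    if bad:
        # +2: header line and 1-based numbering, matching what an editor shows
        rows = [i + 2 for i in bad[:5]]
        raise FormatError(f"{path}: non-numeric value at file line(s) {rows}")
    df = df.assign(value=values)
    return METDataset(df, trait=trait, units=units)


def write_met(dataset: METDataset, path: str | Path) -> None:
    """Write a dataset back to CSV at full floating-point precision."""
    out = dataset.data.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["value"] = [repr(float(v)) for v in out["value"]]
    out.to_csv(path, index=False)


def load_environment_meta(path: str | Path) -> pd.Series:
    """Load per-environment cumulative rainfall (mm) from CSV.

    Expected header: ``environment,rainfall_mm``.
    """
    df = pd.read_csv(path, dtype={"environment": str})
    for col in ("environment", "rainfall_mm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    rain = pd.to_numeric(df["rainfall_mm"], errors="coerce")
    if rain.isna().any() or (rain <= 0).any():
        raise MetadataError(f"{path}: rainfall must be positive and numeric")
    return pd.Series(rain.to_numpy(dtype=float), index=df["environment"].tolist(),
                     name="rainfall_mm")


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def cell_means(dataset: METDataset) -> CellMeansMatrix:
    """Average replicates into a g x e genotype-by-environment means matrix."""
    arr = dataset.value_array()
    means = arr.mean(axis=2)
    mat = pd.DataFrame(means, index=dataset.genotypes, columns=dataset.environments)
    return CellMeansMatrix(matrix=mat, n_reps=dataset.r)


def derive_rue(yield_value: float, rainfall: float, scale: float = 1.0) -> float:
    """Rain-water-use efficiency: yield per mm of cumulative rainfall.

    Computed as ``scale * yield / rainfall``; with yield in g/m^2 and rainfall
    in mm the result is g/m^2/mm (times ``scale``).  ``scale`` rescales the
    working units without affecting any rank-based statistic downstream.
    """
    if rainfall <= 0:
        raise MetadataError(f"rainfall must be > 0, got {rainfall}")
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    return scale * yield_value / rainfall


def rue_dataset(dataset: METDataset, rainfall: Mapping[str, float] | pd.Series,
                scale: float = 1.0) -> METDataset:
    """Transform a yield dataset into an RUE dataset with identical keys.

    Raises :class:`MetadataError` if any environment lacks a rainfall entry.
    RUE is a positive per-environment rescaling of yield, so genotype rank
    order within each environment is preserved.
    """
    absent = [env for env in dataset.environments if env not in rainfall]
    if absent:
        raise MetadataError(f"no rainfall entry for environment(s): {absent}")
    df = dataset.data.copy()
    df["value"] = [
        derive_rue(v, float(rainfall[env]), scale)
        for v, env in zip(df["value"], df["environment"])
    ]
    units = f"({dataset.units})/mm" if dataset.units else "per mm rainfall"
    return METDataset(df, trait="rue", units=units)


def write_cell_means(cm: CellMeansMatrix, path: str | Path) -> None:
    cm.matrix.to_csv(path, index_label="genotype")
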