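"""GGE biplot computations on the environment-centered cell-mean matrix.

A GGE analysis removes only the environment main effect from the cell means,

    C_ij = ybar_ij - ybar_.j        (environment centering),

so the retained structure is genotype main effect plus genotype-by-
environment interaction (G + GE), and decomposes C by SVD.  The 2-D biplot
uses the first two axes under a singular-value partition (SVP):

* ``svp=2`` (column-metric preserving, the default): environment coordinates
  absorb the singular values (lambda * right vectors), genotype coordinates
  are the bare left vectors — environment vector lengths and angles are then
  interpretable as discriminativeness and correlation;
* ``svp=1`` (row-metric preserving): the singular values go to the genotypes.

Both partitions reproduce the same rank-2 approximation of C as the product
of the two coordinate sets.  Four standard views are derived: which-won-where
(convex-hull sectors), mean vs stability (projection on the average-
environment axis), discriminativeness vs representativeness, and distance to
the ideal genotype.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .met_core import CellMeansMatrix, GeometryError
from .stability import rank_values

_TOL = 1e-9


@dataclasses.dataclass
class GGEFit:
    """Rank-2 SVD view of the environment-centered means matrix."""

    centered: pd.DataFrame          # g x e, columns sum to 0
    genotype_coords: pd.DataFrame   # g x 2
    environment_coords: pd.DataFrame  # e x 2
    singular_values: np.ndarray     # full spectrum
    pct_explained: float            # % of G+GE captured by the 2-D view
    svp: int

    @property
    def genotypes(self) -> list[str]:
        return list(self.genotype_coords.index)

    @property
    def environments(self) -> list[str]:
        return list(self.environment_coords.index)

    def aec_axis(self) -> np.ndarray:
        """Unit vector toward the average environment (the AEC abscissa)."""
        mean_env = self.environment_coords.to_numpy().mean(axis=0)
        norm = float(np.linalg.norm(mean_env))
        if norm <= _TOL * max(1.0, np.abs(self.environment_coords.to_numpy()).max()):
            raise GeometryError("average environment vector has zero length; "
                                "AEC axis undefined")
        return mean_env / norm


def gge_fit(means: CellMeansMatrix | pd.DataFrame, svp: int = 2) -> GGEFit:
    """Environment-center a cell-means matrix and take its rank-2 SVD view.

    Axis signs are fixed by orienting each axis so the genotype entry of
    largest magnitude is positive.
    """
    mat = means.matrix if isinstance(means, CellMeansMatrix) else means
    if svp not in (1, 2):
        raise ValueError(f"svp must be 1 or 2, got {svp}")
    g, e = mat.shape
    if g < 3 or e < 2:
        raise GeometryError(f"GGE needs g >= 3 and e >= 2, got g={g}, e={e}")
    m = mat.to_numpy(dtype=float)
    centered = m - m.mean(axis=0, keepdims=True)
    scale = np.abs(centered).max()
    if scale == 0:
        raise GeometryError("centered matrix is identically zero (no G or GE)")

    u, lam, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T
    for k in range(min(2, len(lam))):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    lam2 = lam[:2]
    if svp == 2:
        gcoords = u[:, :2]
        ecoords = v[:, :2] * lam2[None, :]
    else:
        gcoords = u[:, :2] * lam2[None, :]
        ecoords = v[:, :2]
    total = float((lam ** 2).sum())
    pct = 100.0 * float((lam2 ** 2).sum()) / total
    axes = ["axis1", "axis2"]
    return GGEFit(
        centered=pd.DataFrame(centered, index=mat.index, columns=mat.columns),
        genotype_coords=pd.DataFrame(gcoords, index=mat.index, columns=axes),
        environment_coords=pd.DataFrame(ecoords, index=mat.columns, columns=axes),
        singular_values=lam,
        pct_explained=pct,
        svp=svp,
    )


# ---------------------------------------------------------------------------
# Which-won-where
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SectorAssignment:
    """Convex-hull sectors of the biplot and the winner per environment."""

    hull_vertices: list[str]            # genotypes on the hull, CCW order
    sector_of_environment: dict[str, str]  # environment -> winning genotype
    sector_boundaries: np.ndarray       # ray angles (radians), perpendicular
                                        # to hull edges


def _ccw_angle(a: float) -> float:
    """Normalize an angle difference to (-pi, pi]."""
    a = (a + np.pi) % (2 * np.pi) - np.pi
    return float(np.pi) if a == -np.pi else float(a)


def which_won_where(fit: GGEFit) -> SectorAssignment:
    """Winning genotype for each environment via convex-hull sectoring.

    The winner of an environment is the hull vertex maximizing the dot
    product with the environment's vector — for data that are exactly rank
    2, this is the genotype with the largest centered value in that
    environment's column.  An environment lying exactly on a sector boundary
    (a dot-product tie) is assigned to the counter-clockwise sector: among
    tied vertices, the one reached by the largest counter-clockwise rotation
    from the environment vector wins.
    """
    lam = fit.singular_values
    if len(lam) < 2 or lam[1] <= 1e-9 * lam[0]:
        raise GeometryError(
            "centered matrix is effectively rank 1: genotype points are "
            "collinear in the biplot, sectors are undefined"
        )
    pts = fit.genotype_coords.to_numpy()
    names = fit.genotypes
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise GeometryError(
            f"genotype points are collinear or coincident; no 2-D hull: {err}"
        ) from None
    verts = list(hull.vertices)          # CCW order
    vpts = pts[verts]

    # boundary rays: outward perpendicular of each CCW hull edge
    angles = []
    for a, b in zip(vpts, np.roll(vpts, -1, axis=0)):
        d = b - a
        n = np.array([d[1], -d[0]])      # outward normal for CCW polygons
        angles.append(np.arctan2(n[1], n[0]))
    boundaries = np.sort(np.asarray(angles))

    scale = max(np.abs(vpts).max(), _TOL)
    winners: dict[str, str] = {}
    for env, evec in zip(fit.environments, fit.environment_coords.to_numpy()):
        dots = vpts @ evec
        tol = _TOL * scale * max(1.0, float(np.linalg.norm(evec)))
        tied = np.flatnonzero(dots >= dots.max() - tol)
        if len(tied) == 1:
            best = tied[0]
        else:
            eang = np.arctan2(evec[1], evec[0])
            rot = [_ccw_angle(np.arctan2(vpts[i, 1], vpts[i, 0]) - eang)
                   for i in tied]
            best = tied[int(np.argmax(rot))]
        winners[env] = names[verts[best]]
    return SectorAssignment(
        hull_vertices=[names[i] for i in verts],
        sector_of_environment=winners,
        sector_boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# Mean vs stability, discriminativeness, ideal genotype
# ---------------------------------------------------------------------------

def mean_vs_stability(fit: GGEFit) -> pd.DataFrame:
    """Project genotypes on the average-environment axis.

    ``aec_projection`` is the mean-performance proxy (coordinate along the
    AEC abscissa); ``aec_deviation`` the absolute perpendicular component
    (instability).  ``order`` ranks genotypes by projection, 1 = highest.
    """
    axis = fit.aec_axis()
    pts = fit.genotype_coords.to_numpy()
    proj = pts @ axis
    dev = np.abs(pts @ np.array([-axis[1], axis[0]]))
    return pd.DataFrame({
        "aec_projection": proj,
        "aec_deviation": dev,
        "order": rank_values(proj, "descending"),
    }, index=fit.genotypes)


def discriminativeness_representativeness(
    fit: GGEFit,
    length_threshold: float | None = None,
    cos_threshold: float = float(np.cos(np.pi / 4)),
) -> pd.DataFrame:
    """Per-environment vector length and alignment with the AEC axis.

    Long vectors discriminate among genotypes; small angles to the AEC mark
    representative environments.  Environments are classified type-2
    (discriminating AND representative: length >= threshold, cos >= threshold),
    type-3 (discriminating, not representative) or type-1 (otherwise).  The
    default length threshold is the median vector length; both thresholds are
    configurable and echoed by callers that report them.
    """
    axis = fit.aec_axis()
    evecs = fit.environment_coords.to_numpy()
    lengths = np.linalg.norm(evecs, axis=1)
    with np.errstate(invalid="ignore"):
        cosines = np.where(lengths > 0, evecs @ axis / np.where(lengths > 0, lengths, 1), 0.0)
    thr = float(np.median(lengths)) if length_threshold is None else length_threshold
    cls = []
    for ln, c in zip(lengths, cosines):
        if ln >= thr and c >= cos_threshold:
            cls.append("type-2")
        elif ln >= thr:
            cls.append("type-3")
        else:
            cls.append("type-1")
    return pd.DataFrame({
        "vector_length": lengths,
        "cos_angle_to_aec": cosines,
        "classification": cls,
    }, index=fit.environments)


def ideal_genotype_ranking(fit: GGEFit) -> pd.DataFrame:
    """Rank genotypes by distance to the ideal point.

    The ideal genotype sits on the AEC axis at the maximum observed
    projection (highest mean proxy, zero instability).  Rank 1 is the
    genotype closest to it; ties are broken by input order.
    """
    axis = fit.aec_axis()
    pts = fit.genotype_coords.to_numpy()
    proj = pts @ axis
    ideal = axis * proj.max()
    dist = np.linalg.norm(pts - ideal[None, :], axis=1)
    dev = np.abs(pts @ np.array([-axis[1], axis[0]]))
    return pd.DataFrame({
        "aec_projection": proj,
        "aec_deviation": dev,
        "distance_to_ideal": dist,
        "rank": rank_values(dist, "ascending"),
    }, index=fit.genotypes)
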