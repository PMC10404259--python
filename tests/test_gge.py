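import numpy as np
import pandas as pd
import pytest

from metstab import (
    GeometryError,
    cell_means,
    discriminativeness_representativeness,
    generate_met,
    gge_fit,
    ideal_genotype_ranking,
    mean_vs_stability,
    which_won_where,
)

from conftest import noiseless_config, random_dataset


def random_means(rng, g, e, scale=10.0):
    m = rng.normal(0.0, scale, size=(g, e)) + 100.0
    return pd.DataFrame(m, index=[f"G{i+1:02d}" for i in range(g)],
                        columns=[f"E{j+1}" for j in range(e)])


def rank2_means(rng, g, e):
    """Means whose environment-centered matrix is exactly rank 2."""
    a = rng.normal(size=(g, 2))
    b = rng.normal(size=(e, 2))
    m = a @ b.T
    m = m - m.mean(axis=0, keepdims=True)
    return pd.DataFrame(m + 100.0, index=[f"G{i+1:02d}" for i in range(g)],
                        columns=[f"E{j+1}" for j in range(e)])


def test_centering_and_idempotence(rng):
    fit = gge_fit(random_means(rng, 8, 4))
    np.testing.assert_allclose(fit.centered.sum(axis=0), 0.0, atol=1e-9)
    refit = gge_fit(fit.centered)
    np.testing.assert_allclose(refit.centered, fit.centered, atol=1e-12)


def test_rank2_matrix_fully_explained(rng):
    fit = gge_fit(rank2_means(rng, 8, 5))
    assert fit.pct_explained == pytest.approx(100.0, abs=1e-8)


@pytest.mark.parametrize("svp", [1, 2])
def test_rank2_reconstruction_under_both_partitions(rng, svp):
    """Genotype x environment coordinate products equal the rank-2 truncation
    of the centered matrix regardless of where the singular values sit."""
    fit = gge_fit(random_means(rng, 8, 3), svp=svp)
    recon = fit.genotype_coords.to_numpy() @ fit.environment_coords.to_numpy().T
    u, lam, vt = np.linalg.svd(fit.centered.to_numpy(), full_matrices=False)
    rank2 = u[:, :2] @ np.diag(lam[:2]) @ vt[:2]
    np.testing.assert_allclose(recon, rank2, atol=1e-9)


def test_gge_accounts_for_g_plus_ge(rng):
    """sum(lambda^2) of the centered matrix equals the (G + GEI) SS of cell
    means."""
    ds = random_dataset(rng, 7, 4, 2)
    cm = cell_means(ds)
    fit = gge_fit(cm)
    m = cm.matrix.to_numpy()
    grand = m.mean()
    ss_g = m.shape[1] * ((m.mean(axis=1) - grand) ** 2).sum()
    z = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + grand
    assert (fit.singular_values ** 2).sum() == pytest.approx(
        ss_g + (z ** 2).sum(), rel=1e-10)


def test_degenerate_inputs_raise():
    flat = pd.DataFrame(np.full((4, 3), 7.0))
    with pytest.raises(GeometryError, match="zero"):
        gge_fit(flat)
    with pytest.raises(GeometryError, match="g >= 3"):
        gge_fit(pd.DataFrame(np.random.default_rng(0).normal(size=(2, 3))))
    with pytest.raises(ValueError):
        gge_fit(pd.DataFrame(np.eye(4)), svp=3)


def test_www_winner_equals_column_argmax_on_rank2_data(rng):
    """On exactly rank-2 data the sector winner is the genotype with the
    largest centered value in that environment's column (100 instances)."""
    for _ in range(100):
        g = int(rng.integers(4, 12))
        e = int(rng.integers(2, 6))
        means = rank2_means(rng, g, e)
        fit = gge_fit(means)
        www = which_won_where(fit)
        centered = fit.centered
        for env in fit.environments:
            assert www.sector_of_environment[env] == centered[env].idxmax()


def test_www_dominant_genotype_wins_everywhere(rng):
    """A genotype far outside the cloud in every environment direction wins
    every sector."""
    means = rank2_means(rng, 8, 3)
    means.loc["G01"] = means.loc["G01"] + 500.0  # dominates every column
    www = which_won_where(gge_fit(means))
    assert set(www.sector_of_environment.values()) == {"G01"}
    assert "G01" in www.hull_vertices


def test_www_collinear_points_raise():
    g = np.arange(6, dtype=float)
    means = pd.DataFrame(np.outer(g, [1.0, 2.0, 3.0]),
                         index=[f"G{i}" for i in range(6)],
                         columns=list("ABC"))
    fit = gge_fit(means)
    with pytest.raises(GeometryError, match="collinear"):
        which_won_where(fit)


def test_mean_vs_stability_pythagoras(rng):
    fit = gge_fit(random_means(rng, 9, 4))
    mvs = mean_vs_stability(fit)
    pts = fit.genotype_coords.to_numpy()
    np.testing.assert_allclose(
        mvs["aec_projection"] ** 2 + mvs["aec_deviation"] ** 2,
        (pts ** 2).sum(axis=1), rtol=1e-10)
    assert (mvs["aec_deviation"] >= 0).all()


def test_single_direction_environments(rng):
    """With all environment columns identical, projections order genotypes
    along that common direction and deviations vanish on axis 1."""
    col = rng.normal(size=8)
    means = pd.DataFrame(np.tile(col[:, None], (1, 3)) + 50.0,
                         index=[f"G{i}" for i in range(8)], columns=list("XYZ"))
    fit = gge_fit(means, svp=1)  # singular values on genotypes: rank-1 axis2 = 0
    mvs = mean_vs_stability(fit)
    # rank-1 data: AEC is the first axis, deviation ~ 0
    np.testing.assert_allclose(mvs["aec_deviation"], 0.0, atol=1e-8)
    assert list(mvs.sort_values("aec_projection", ascending=False).index) == \
        list(pd.Series(col, index=means.index).sort_values(ascending=False).index)


def test_discriminativeness_cosines(rng):
    fit = gge_fit(random_means(rng, 8, 5))
    diag = discriminativeness_representativeness(fit)
    assert diag["cos_angle_to_aec"].between(-1 - 1e-12, 1 + 1e-12).all()
    evecs = fit.environment_coords.to_numpy()
    np.testing.assert_allclose(diag["vector_length"],
                               np.linalg.norm(evecs, axis=1), rtol=1e-12)
    # orthogonal-to-AEC environments can never be type-2
    assert not ((diag["cos_angle_to_aec"] < np.cos(np.pi / 4))
                & (diag["classification"] == "type-2")).any()


def test_env_vector_length_linear_in_column_scale(rng):
    """Doubling one environment's centered column doubles its vector length
    under column-metric preserving, when the 2-D view is exact."""
    means = rank2_means(rng, 8, 3)
    fit1 = gge_fit(means)
    scaled = means.copy()
    scaled["E2"] = (means["E2"] - means["E2"].mean()) * 2.0 + means["E2"].mean()
    fit2 = gge_fit(scaled)
    l1 = np.linalg.norm(fit1.environment_coords.loc["E2"])
    l2 = np.linalg.norm(fit2.environment_coords.loc["E2"])
    assert l2 == pytest.approx(2.0 * l1, rel=1e-8)


def test_ideal_genotype_geometry_oracle(rng):
    fit = gge_fit(random_means(rng, 10, 4))
    ranking = ideal_genotype_ranking(fit)
    axis = fit.aec_axis()
    pts = fit.genotype_coords.to_numpy()
    ideal = axis * (pts @ axis).max()
    np.testing.assert_allclose(ranking["distance_to_ideal"],
                               np.linalg.norm(pts - ideal, axis=1), rtol=1e-10)
    assert sorted(ranking["rank"]) == list(range(1, 11))
    # the genotype attaining max projection with (near) zero deviation is at
    # the ideal point
    best = ranking.sort_values("rank").index[0]
    assert ranking.loc[best, "distance_to_ideal"] == ranking["distance_to_ideal"].min()


def test_views_invariant_under_rotation(rng):
    """Winners, ideal-genotype rank order and mean-vs-stability order are
    unchanged by a uniform rotation of both coordinate sets."""
    fit = gge_fit(random_means(rng, 9, 4))
    theta = 0.83
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    import dataclasses
    rfit = dataclasses.replace(
        fit,
        genotype_coords=pd.DataFrame(fit.genotype_coords.to_numpy() @ rot.T,
                                     index=fit.genotypes,
                                     columns=["axis1", "axis2"]),
        environment_coords=pd.DataFrame(fit.environment_coords.to_numpy() @ rot.T,
                                        index=fit.environments,
                                        columns=["axis1", "axis2"]),
    )
    assert which_won_where(fit).sector_of_environment == \
        which_won_where(rfit).sector_of_environment
    pd.testing.assert_series_equal(ideal_genotype_ranking(fit)["rank"],
                                   ideal_genotype_ranking(rfit)["rank"])
    pd.testing.assert_series_equal(mean_vs_stability(fit)["order"],
                                   mean_vs_stability(rfit)["order"])


def test_additive_data_single_winner():
    """With zero GEI the centered matrix has rank <= 1 and the largest-effect
    genotype wins every environment."""
    ds, truth = generate_met(noiseless_config(k=0, gei_singular_values=()))
    cm = cell_means(ds)
    fit = gge_fit(cm)
    assert (fit.singular_values[1:] < 1e-8 * fit.singular_values[0]).all()
    best = truth.genotype_effects.idxmax()
    # rank-1 geometry is collinear by construction; the argmax oracle applies
    assert all(fit.centered[env].idxmax() == best for env in fit.environments)
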