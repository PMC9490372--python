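import numpy as np
import pytest

from metstab import (
    discrimination_representativeness,
    env_collapsed_anova,
    fit_gge,
    mean_vs_stability,
    rank_genotypes,
    which_won_where,
)

from conftest import random_table
from test_stability import table_from_means


def rotate_model(model, theta):
    """Rotate the rank-2 marker plane (projections must not change)."""
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    gscale, escale = model._marker_scales()
    model.genotype_scores = model.genotype_scores.copy()
    model.environment_scores = model.environment_scores.copy()
    # choose new score columns so markers become old markers @ rot
    model.genotype_scores[:, :2] = (model.genotype_markers @ rot) / gscale
    model.environment_scores[:, :2] = (model.environment_markers @ rot) / escale
    return model


class TestFit:
    def test_pure_environment_effects_give_zero_singular_values(self):
        means = np.tile([1.0, 4.0, 2.0, 3.0], (4, 1))  # all genotypes identical
        model = fit_gge(table_from_means(means))
        assert np.allclose(model.singular_values, 0.0, atol=1e-12)

    def test_columns_of_centered_matrix_have_zero_mean(self):
        rng = np.random.default_rng(0)
        model = fit_gge(random_table(rng))
        assert np.allclose(model.centered.mean(axis=0), 0.0, atol=1e-10)

    def test_total_ss_is_g_plus_ge(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, g=7, e=5)
        model = fit_gge(table)
        at = env_collapsed_anova(table, basis="means")
        assert (model.singular_values**2).sum() == pytest.approx(
            at["Genotype"].ss + at["G x E"].ss, rel=1e-10
        )

    @pytest.mark.parametrize("svp", ["genotype", "environment", "symmetric"])
    def test_3x3_markers_match_direct_svd_oracle(self, svp):
        means = np.array([[4.0, 1.0, 2.0], [2.0, 5.0, 1.0], [1.0, 2.0, 6.0]])
        model = fit_gge(table_from_means(means), svp=svp)
        centered = means - means.mean(axis=0)
        u, s, vt = np.linalg.svd(centered)
        expect_g = {"genotype": u[:, :2] * s[:2],
                    "environment": u[:, :2],
                    "symmetric": u[:, :2] * np.sqrt(s[:2])}[svp]
        expect_e = {"genotype": vt[:2].T,
                    "environment": vt[:2].T * s[:2],
                    "symmetric": vt[:2].T * np.sqrt(s[:2])}[svp]
        # sign-free comparison per column
        for k in range(2):
            gm, em = model.genotype_markers[:, k], model.environment_markers[:, k]
            sign = np.sign(gm @ expect_g[:, k]) or 1.0
            assert np.allclose(gm, sign * expect_g[:, k], atol=1e-10)
            assert np.allclose(em, sign * expect_e[:, k], atol=1e-10)

    def test_marker_inner_products_reconstruct_rank2(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, g=6, e=5)
        model = fit_gge(table, svp="genotype")
        u, s, vt = np.linalg.svd(model.centered)
        rank2 = (u[:, :2] * s[:2]) @ vt[:2]
        assert np.allclose(model.genotype_markers @ model.environment_markers.T,
                           rank2, atol=1e-10)
        resid = ((model.centered - rank2) ** 2).sum()
        assert resid == pytest.approx((model.singular_values[2:] ** 2).sum(), rel=1e-8)

    def test_sd_scaling_zero_variance_environment_named(self):
        means = np.array([[1.0, 2.0, 0.0], [2.0, 3.0, 0.0], [3.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="E2"):
            fit_gge(table_from_means(means), scaling="sd")

    def test_genotype_focused_marker_norms_bounded_by_g_plus_ge(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, g=8, e=6)
        model = fit_gge(table, svp="genotype")
        total = (model.singular_values**2).sum()
        norms = (model.genotype_markers**2).sum()
        assert norms <= total + 1e-9


class TestWhichWonWhere:
    def test_uniformly_dominant_genotype_takes_all_environments(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 0.2, size=(5, 4))
        base[2] += 10.0  # one genotype dominates everywhere
        part = which_won_where(fit_gge(table_from_means(5.0 + base)))
        non_empty = [s for s in part.sectors if s[1]]
        assert len(non_empty) == 1
        assert non_empty[0][0] == "G2"
        assert sorted(non_empty[0][1]) == ["E0", "E1", "E2", "E3"]

    def test_winners_match_rank2_argmax_oracle_toy(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, g=4, e=3)
        model = fit_gge(table)
        part = which_won_where(model)
        recon = model.genotype_markers @ model.environment_markers.T
        for j, env in enumerate(model.environments):
            assert part.winner_of(env) == model.genotypes[int(np.argmax(recon[:, j]))]

    def test_every_environment_in_exactly_one_sector(self):
        rng = np.random.default_rng(6)
        model = fit_gge(random_table(rng, g=7, e=6))
        part = which_won_where(model)
        assigned = [e for _, envs in part.sectors for e in envs]
        assert sorted(assigned) == sorted(model.environments)
        assert all(v in part.hull for v, _ in part.sectors)

    def test_collinear_markers_raise_degenerate_geometry(self):
        # rank-1 G+GE: markers fall on a line through the origin
        means = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 1.5])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            which_won_where(fit_gge(table_from_means(means)))


class TestMeanVsStability:
    def test_uniform_offset_genotype_tops_aec_with_zero_perpendicular(self):
        rng = np.random.default_rng(7)
        env = rng.normal(5.0, 1.0, size=5)
        means = np.tile(env, (4, 1)) + rng.normal(0, 0.3, size=(4, 1))
        means[1] = env + 2.5  # uniformly best, purely additive
        model = fit_gge(table_from_means(means), svp="genotype")
        aec, df = mean_vs_stability(model)
        assert df.index[0] == "G1"
        assert df.loc["G1", "stability"] == pytest.approx(0.0, abs=1e-8)
        assert df.loc["G1", "mean_rank"] == 1

    def test_origin_marker_means_average_and_stable(self):
        rng = np.random.default_rng(8)
        model = fit_gge(random_table(rng), svp="genotype")
        model.genotype_scores[0, :] = 0.0
        aec, df = mean_vs_stability(model)
        assert df.loc["G0", "mean_projection"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc["G0", "stability"] == pytest.approx(0.0, abs=1e-12)

    def test_projections_invariant_to_svd_basis_rotation(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, g=6, e=5)
        model = fit_gge(table, svp="symmetric")
        aec1, df1 = mean_vs_stability(model)
        aec2, df2 = mean_vs_stability(rotate_model(model, 0.7))
        assert np.allclose(df1["mean_projection"], df2["mean_projection"], atol=1e-10)
        assert np.allclose(df1["stability"], df2["stability"], atol=1e-10)

    def test_interaction_dominated_data_raise(self):
        rng = np.random.default_rng(10)
        model = fit_gge(random_table(rng), svp="genotype")
        model.environment_scores = model.environment_scores.copy()
        model.environment_scores[:, :2] -= model.environment_scores[:, :2].mean(axis=0)
        with pytest.raises(ValueError, match="AEC|undefined"):
            mean_vs_stability(model)


class TestRanking:
    def test_additive_offset_genotype_is_ranked_first(self):
        rng = np.random.default_rng(11)
        env = rng.normal(5.0, 1.0, size=4)
        means = np.tile(env, (4, 1)) + rng.normal(0, 0.2, size=(4, 1))
        means[2] = env + 3.0
        df = rank_genotypes(fit_gge(table_from_means(means), svp="genotype"))
        assert df.index[0] == "G2"
        assert df.loc["G2", "distance_to_ideal"] == pytest.approx(0.0, abs=1e-8)

    def test_ranking_matches_brute_force_distances(self):
        rng = np.random.default_rng(12)
        table = random_table(rng, g=4, e=3)
        model = fit_gge(table, svp="genotype")
        df = rank_genotypes(model)
        em = model.environment_markers
        d = em.mean(axis=0) / np.linalg.norm(em.mean(axis=0))
        ideal = d * (model.genotype_markers @ d).max()
        dist = np.linalg.norm(model.genotype_markers - ideal, axis=1)
        order = [model.genotypes[i] for i in np.argsort(dist, kind="stable")]
        assert list(df.index) == order


class TestDiscriminationRepresentativeness:
    def test_zero_centered_column_gives_zero_vector(self):
        rng = np.random.default_rng(13)
        means = rng.normal(5.0, 1.0, size=(5, 4))
        means[:, 2] = 7.0  # all genotypes equal: centered column is zero
        model = fit_gge(table_from_means(means), svp="environment")
        df = discrimination_representativeness(model)
        assert df.loc["E2", "vector_length"] == pytest.approx(0.0, abs=1e-10)
        assert np.isnan(df.loc["E2", "cos_angle"])

    def test_environment_vector_length_squared_matches_rank2_ss(self):
        rng = np.random.default_rng(14)
        table = random_table(rng, g=6, e=5)
        model = fit_gge(table, svp="environment")
        df = discrimination_representativeness(model)
        u, s, vt = np.linalg.svd(model.centered)
        rank2 = (u[:, :2] * s[:2]) @ vt[:2]
        for j, env in enumerate(model.environments):
            assert df.loc[env, "vector_length"] ** 2 == pytest.approx(
                (rank2[:, j] ** 2).sum(), rel=1e-8
            )

    def test_flags_exactly_one_ideal_test_environment(self):
        rng = np.random.default_rng(15)
        df = discrimination_representativeness(
            fit_gge(random_table(rng), svp="environment")
        )
        assert df["ideal_test_env"].sum() == 1
        best = df[df["ideal_test_env"]].index[0]
        assert df.loc[best, "score"] == df["score"].max()


def test_goodness_of_fit_is_rank2_share():
    rng = np.random.default_rng(16)
    model = fit_gge(random_table(rng, g=7, e=6))
    lam2 = model.singular_values**2
    assert model.goodness_of_fit == pytest.approx(lam2[:2].sum() / lam2.sum())
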