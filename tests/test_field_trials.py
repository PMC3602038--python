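"""Spatial correction, GGE decomposition, ideal-cultivar ranking, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from exonforge.field_trials import (
    fit_spatial_surface,
    gge_decompose,
    rank_ideal_cultivars,
    relative_decrease,
    scale_by_environment,
    variety_contrast,
)
from exonforge.synthetic_fixtures import FieldPlan, generate_field_trial


def _grid_frame(rng, n_rows, n_cols, n_varieties=2):
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    n = n_rows * n_cols
    varieties = [f"V{(i % n_varieties) + 1}" for i in rng.permutation(n)]
    return pd.DataFrame(
        {
            "env": "E1",
            "row": rows.ravel(),
            "column": cols.ravel(),
            "block": 0,
            "variety": varieties,
            "value": 0.0,
        }
    )


class TestFitSpatialSurface:
    def test_flat_field_gives_negligible_component(self, rng):
        df = _grid_frame(rng, 6, 45)
        df["value"] = 3.0 + rng.normal(0, 0.3, len(df))
        fit = fit_spatial_surface(df)
        assert np.abs(fit.spatial).max() < 0.3
        assert np.corrcoef(fit.corrected, df["value"])[0, 1] > 0.9
        assert abs(fit.spatial.mean()) < 1e-9

    def test_planted_surface_recovered(self):
        fx = generate_field_trial(FieldPlan(seed=11, n_envs=1))
        sub = fx.plots[fx.plots.env == "E1"]
        fit = fit_spatial_surface(sub)
        corr = np.corrcoef(fit.spatial, fx.spatial_truth["E1"])[0, 1]
        assert corr > 0.9

    def test_exact_on_representable_noiseless_surface(self, rng):
        # surface = centered product of cubics lies in the tensor spline span
        df = _grid_frame(rng, 8, 8)
        r = df["row"].to_numpy() / 7.0
        c = df["column"].to_numpy() / 7.0
        surf = (r**3 - 0.5 * r) * (c**3 + c - 1)
        surf = surf - surf.mean()
        df["value"] = 2.0 + surf
        fit = fit_spatial_surface(df, n_knots=1)
        assert np.abs(fit.spatial - surf).max() < 1e-4
        assert np.abs(fit.corrected - 2.0).max() < 1e-4

    def test_single_variety_rejected(self, rng):
        df = _grid_frame(rng, 5, 5, n_varieties=1)
        with pytest.raises(ValueError):
            fit_spatial_surface(df)

    def test_too_few_plots_suggests_smaller_basis(self, rng):
        df = _grid_frame(rng, 5, 5)
        df["row"] = np.linspace(0, 44, 25)  # fine coordinates, full basis
        df["column"] = np.linspace(0, 44, 25)
        with pytest.raises(ValueError, match="n_knots"):
            fit_spatial_surface(df, n_knots=5)

    def test_recovery_over_20_simulations(self):
        corrs = []
        for seed in range(20):
            fx = generate_field_trial(FieldPlan(seed=100 + seed, n_envs=1))
            sub = fx.plots[fx.plots.env == "E1"]
            fit = fit_spatial_surface(sub)
            corrs.append(np.corrcoef(fit.spatial, fx.spatial_truth["E1"])[0, 1])
        assert np.median(corrs) > 0.9

    def test_variety_effects_unbiased(self):
        diffs = []
        for seed in range(10):
            fx = generate_field_trial(FieldPlan(seed=200 + seed, n_envs=1, gxe_sd=0.0))
            sub = fx.plots[fx.plots.env == "E1"]
            fit = fit_spatial_surface(sub)
            est = fit.variety_effects - fit.variety_effects.mean()
            true = fx.g_effects - fx.g_effects.mean()
            diffs.append((est - true.reindex(est.index)).abs().mean())
        assert np.mean(diffs) < 0.2  # noise sd 0.3 over 6 reps -> se ~0.12


class TestScaleByEnvironment:
    def test_unit_column_sd(self, rng):
        plots = generate_field_trial(FieldPlan(seed=4)).plots.rename(
            columns={"value": "corrected"}
        )
        gem = scale_by_environment(plots)
        assert np.allclose(gem.std(axis=0, ddof=1), 1.0)
        assert gem.shape == (45, 8)
        assert not gem.isna().any().any()

    def test_already_unit_sd_unchanged(self, rng):
        vals = rng.normal(size=40)
        vals = vals / vals.std(ddof=1)
        varieties = [f"V{i}" for i in range(40)]
        df = pd.DataFrame({"env": "E1", "variety": varieties, "corrected": vals})
        gem = scale_by_environment(df)
        want = pd.Series(vals, index=varieties)
        assert np.allclose(gem["E1"], want.reindex(gem.index))

    def test_zero_variance_environment_rejected(self):
        df = pd.DataFrame(
            {"env": "E1", "variety": ["V1", "V2"], "corrected": [1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="zero variance"):
            scale_by_environment(df)


class TestGGEDecompose:
    def test_rank_one_matrix_all_variance_on_axis_one(self):
        g = np.array([1.0, 2.0, 4.0])
        e = np.array([1.0, 3.0])
        gem = pd.DataFrame(np.outer(g, e))
        res = gge_decompose(gem, n_axes=2)
        assert res.variance_explained[0] == pytest.approx(100.0)
        assert res.n_axes == 1  # rank truncation warns and truncates

    def test_full_reconstruction(self, rng):
        gem = pd.DataFrame(rng.normal(size=(5, 4)))
        res = gge_decompose(gem, n_axes=4)
        recon = res.genotype_scores.to_numpy() @ res.env_loadings.to_numpy().T
        centered = (gem - gem.mean(axis=0)).to_numpy()
        assert np.abs(recon - centered).max() < 1e-10

    def test_variance_explained_sums_to_100(self, rng):
        for shape in [(5, 4), (45, 8), (3, 3)]:
            gem = pd.DataFrame(rng.normal(size=shape))
            res = gge_decompose(gem)
            assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)

    def test_invariant_under_genotype_relabeling(self, rng):
        gem = pd.DataFrame(rng.normal(size=(10, 5)),
                           index=[f"V{i}" for i in range(10)])
        res1 = gge_decompose(gem)
        perm = rng.permutation(10)
        res2 = gge_decompose(gem.iloc[perm])
        assert np.allclose(res1.variance_explained, res2.variance_explained)

    def test_genotype_ordering_recovery_when_g_dominates(self):
        fx = generate_field_trial(FieldPlan(seed=3, g_sd=1.0, gxe_sd=0.1))
        parts = []
        for _, sub in fx.plots.groupby("env"):
            fit = fit_spatial_surface(sub)
            sub = sub.assign(corrected=fit.corrected)
            parts.append(sub)
        plots = pd.concat(parts)
        gem = scale_by_environment(plots)
        res = gge_decompose(gem)
        rho = spearmanr(
            res.genotype_scores["axis1"].reindex(fx.g_effects.index), fx.g_effects
        )[0]
        assert abs(rho) > 0.95  # axis sign is arbitrary


class TestRankIdealCultivars:
    def _gge_from_values(self, matrix, index):
        gem = pd.DataFrame(matrix, index=index)
        return gge_decompose(gem, n_axes=2)

    def test_constant_lowest_genotype_ranked_first(self, rng):
        fx = generate_field_trial(FieldPlan(seed=5, g_sd=0.5, gxe_sd=0.05))
        g = fx.g_effects.copy()
        # make V1 the constant lowest accumulator by a wide margin
        plots = fx.plots.copy()
        plots.loc[plots.variety == "V1", "value"] -= 5.0
        plots = plots.assign(corrected=plots["value"])
        res = gge_decompose(scale_by_environment(plots))
        ranking = rank_ideal_cultivars(res, direction="low")
        assert ranking.index[0] == "V1"

    def test_stable_low_beats_unstable_equal_mean(self):
        # two genotypes with the same mean across 4 envs; one flat, one swinging
        values = np.array(
            [
                [1.0, 1.0, 1.0, 1.0],   # stable low
                [0.0, 2.0, 0.0, 2.0],   # same mean, high GxE
                [3.0, 3.1, 2.9, 3.0],
                [4.0, 3.9, 4.1, 4.0],
            ]
        )
        res = self._gge_from_values(values, ["stable", "unstable", "mid", "high"])
        ranking = rank_ideal_cultivars(res, direction="low")
        assert ranking.loc["stable", "instability"] < ranking.loc["unstable", "instability"]
        # equal trait level: the stable genotype must outrank the unstable one
        assert ranking.loc["stable", "rank"] < ranking.loc["unstable", "rank"]

    def test_single_effective_axis_zero_instability(self):
        g = np.array([1.0, 2.0, 4.0, 8.0])
        e = np.array([1.0, 1.2])
        res = gge_decompose(pd.DataFrame(np.outer(g, e)), n_axes=2)
        ranking = rank_ideal_cultivars(res)
        assert np.allclose(ranking["instability"], 0.0, atol=1e-10)


class TestVarietyContrast:
    def test_relative_decrease_worked_examples(self):
        # printed group means from the field/greenhouse tables
        assert round(relative_decrease(2.5, 2.9), 1) == 13.8
        assert round(relative_decrease(48.3, 52.59), 1) == 8.2
        assert round(relative_decrease(39.53, 37.44), 1) == -5.6

    def test_identical_groups(self):
        res = variety_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.relative_decrease == 0.0

    def test_ci_brackets_mean(self, rng):
        a = rng.normal(2.0, 0.5, 6)
        b = rng.normal(3.0, 0.5, 6)
        res = variety_contrast(a, b)
        assert res.ci_a[0] <= res.mean_a <= res.ci_a[1]
        assert res.ci_b[0] <= res.mean_b <= res.ci_b[1]

    def test_clear_difference_significant(self, rng):
        a = rng.normal(1.0, 0.2, 8)
        b = rng.normal(3.0, 0.2, 8)
        res = variety_contrast(a, b)
        assert res.p_value < 0.001
        assert res.relative_decrease > 50

    def test_antisymmetry_under_group_swap(self, rng):
        a = rng.normal(2.0, 0.3, 6)
        b = rng.normal(2.6, 0.3, 6)
        d_ab = variety_contrast(a, b).relative_decrease
        d_ba = variety_contrast(b, a).relative_decrease
        assert d_ba == pytest.approx(100 * (1 - 1 / (1 - d_ab / 100)))

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_decrease(1.0, 0.0)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            variety_contrast([1.0], [2.0, 3.0])
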