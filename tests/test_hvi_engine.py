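"""HVI engine: standardization, rotated-PCA weighting, scoring, binning."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from heatcanopy.hvi_engine import (
    RetentionError,
    categorize_score,
    categorize_scores,
    component_scores,
    component_scores_standardize_each,
    fit_weighting_model,
    run_hvi_pipeline,
    standardize_scores,
    standardize_variables,
    total_hvi,
    tucker_congruence,
    varimax,
)
from heatcanopy.io_schema import (
    Direction,
    SchemaError,
    TractVariableTable,
    ValidationError,
    VariableSchema,
    default_schema,
)
from heatcanopy.synthetic import (
    CohortSpec,
    default_loading_matrix,
    generate_tract_cohort,
)


def _categorize_oracle(z: float) -> int:
    """Independent lookup-table binning used to cross-check categorize_score."""
    if z < -2:
        return 1
    if z < -1:
        return 2
    if z < 0:
        return 3
    if z < 1:
        return 4
    if z < 2:
        return 5
    return 6


class TestStandardizeVariables:
    def test_symmetric_three_point_column(self):
        df = pd.DataFrame({"a": [10.0, 20.0, 30.0], "b": [1.0, 5.0, 3.0]})
        z, means, sds = standardize_variables(df)
        # sample SD of [10,20,30] is exactly 10, so z is exactly [-1,0,1]
        assert z["a"].tolist() == [-1.0, 0.0, 1.0]
        assert means["a"] == 20.0 and sds["a"] == 10.0

    def test_constant_column_raises(self):
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="'a'"):
            standardize_variables(df)

    def test_too_few_tracts(self):
        with pytest.raises(ValidationError, match="3 tracts"):
            standardize_variables(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_output_moments(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)


class TestStandardizeScores:
    def test_mean_zero_sd_one(self):
        raw = pd.DataFrame({"c1": [2.0, 4.0, 6.0]})
        z = standardize_scores(raw)
        assert z["c1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["c1"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        raw = pd.DataFrame({"c1": [2.0, 4.0, 6.0, 1.0]})
        once = standardize_scores(raw)
        twice = standardize_scores(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-9, rtol=0)

    def test_zero_variance_component(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            standardize_scores(pd.DataFrame({"c1": [1.0, 1.0, 1.0]}))


class TestCategorize:
    @pytest.mark.parametrize(
        "z,expected",
        [(-2.5, 1), (2.5, 6), (0.0, 4), (-1.0, 3), (2.0, 6), (-2.0, 2),
         (1.0, 5), (-0.001, 3), (1.999, 5)],
    )
    def test_band_assignments(self, z, expected):
        assert categorize_score(z) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            categorize_score(float("nan"))

    def test_grid_against_lookup_oracle_and_monotone(self):
        grid = np.linspace(-5, 5, 10_000)
        got = [categorize_score(z) for z in grid]
        assert got == [_categorize_oracle(z) for z in grid]
        assert all(a <= b for a, b in zip(got, got[1:]))

    def test_vectorized_matches_scalar(self):
        grid = np.linspace(-4, 4, 1000)
        frame = pd.DataFrame({"c": grid})
        vec = categorize_scores(frame)["c"].tolist()
        assert vec == [categorize_score(z) for z in grid]


class TestTotalHvi:
    @pytest.mark.parametrize(
        "scores,expected", [((1, 1, 1), 3), ((6, 6, 6), 18), ((2, 4, 5), 11)]
    )
    def test_sums(self, scores, expected):
        df = pd.DataFrame([scores], index=["25025000001"])
        assert total_hvi(df).iloc[0] == expected

    def test_out_of_band_score_rejected(self):
        with pytest.raises(ValidationError):
            total_hvi(pd.DataFrame([[0, 3, 4]]))


class TestVarimax:
    def test_communality_preserved(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        loadings = eigvecs[:, order[:3]] * np.sqrt(eigvals[order[:3]])
        rotated, R = varimax(loadings)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.allclose(
            (rotated**2).sum(axis=1), (loadings**2).sum(axis=1), atol=1e-6
        )

    def test_single_component_is_identity(self):
        L = np.arange(5.0).reshape(5, 1)
        rotated, R = varimax(L)
        assert np.allclose(rotated, L)
        assert R.shape == (1, 1)


class TestFitWeightingModel:
    def test_three_planted_factors_retained(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema)
        assert model.n_components == 3

    def test_single_dominant_factor_retained(self):
        lam = np.full((13, 1), 0.9)
        lam[default_schema().names.index("pct_open_undeveloped"), 0] = -0.9
        spec = CohortSpec(n_tracts=500, loading_matrix=lam, noise_sd=0.1, seed=7)
        table = generate_tract_cohort(spec)
        z, _, _ = standardize_variables(table)
        # brute-force oracle: eigendecomposition of the sample correlation matrix
        eig = np.linalg.eigvalsh(np.corrcoef(z.to_numpy(), rowvar=False))
        assert (eig > 1.0).sum() == 1
        model = fit_weighting_model(z, table.schema)
        assert model.n_components == 1

    def test_eigenvalue_sum_is_trace(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        eig = np.linalg.eigvalsh(np.corrcoef(z.to_numpy(), rowvar=False))
        assert eig.sum() == pytest.approx(13.0, abs=1e-6)

    def test_orientation_invariant(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        schema = default_cohort.schema
        model = fit_weighting_model(z, schema)
        inc = [schema.names.index(v) for v in schema.increasing]
        for c in range(model.n_components):
            assert model.loadings[inc, c].sum() >= 0

    def test_no_retainable_component_suggests_fixed_k(self):
        # exactly orthogonal two-variable design: both eigenvalues equal 1
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        z = pd.DataFrame({"a": x, "b": y})
        z = (z - z.mean()) / z.std(ddof=1)
        schema = VariableSchema((("a", Direction.INCREASING), ("b", Direction.INCREASING)))
        with pytest.raises(RetentionError, match="fixed"):
            fit_weighting_model(z, schema)
        model = fit_weighting_model(z, schema, retention=2)
        assert model.n_components == 2

    def test_fixed_k_override(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema, retention=2)
        assert model.n_components == 2

    def test_loading_threshold_zeroes_small_weights(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema, loading_threshold=0.4)
        small = np.abs(model.loadings[model.loadings != 0])
        assert (small >= 0.4).all()


class TestComponentScores:
    def test_cohort_mean_tract_scores_zero(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema)
        zero_row = pd.DataFrame(
            np.zeros((1, 13)), columns=z.columns, index=["25025999999"]
        )
        raw = component_scores(zero_row, model)
        assert np.allclose(raw.to_numpy(), 0.0)

    def test_matches_explicit_loop_oracle(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema)
        raw = component_scores(z, model)
        sub = z.head(20)
        for t in sub.index:
            for c in range(model.n_components):
                expected = sum(
                    model.loadings[v, c] * z.loc[t, var]
                    for v, var in enumerate(model.variables)
                )
                assert raw.loc[t].iloc[c] == pytest.approx(expected, abs=1e-9)

    def test_all_ones_loadings_dot_product(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema, retention=1)
        model.loadings = np.ones((13, 1))
        ones_row = pd.DataFrame(np.ones((1, 13)), columns=z.columns, index=["x" * 11])
        ones_row.index = ["25025999999"]
        assert component_scores(ones_row, model).iloc[0, 0] == pytest.approx(13.0)

    def test_doubling_one_loading_doubles_contribution(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema)
        base = component_scores(z, model)
        bumped = model.loadings.copy()
        bumped[0, 0] *= 2.0
        model2 = fit_weighting_model(z, default_cohort.schema)
        model2.loadings = bumped
        diff = component_scores(z, model2).iloc[:, 0] - base.iloc[:, 0]
        expected = model.loadings[0, 0] * z.iloc[:, 0]
        assert np.allclose(diff.to_numpy(), expected.to_numpy(), atol=1e-9)

    def test_column_mismatch_raises(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema)
        with pytest.raises(SchemaError):
            component_scores(z[z.columns[::-1]], model)


class TestPipeline:
    def test_determinism(self, default_cohort):
        a = run_hvi_pipeline(default_cohort)
        b = run_hvi_pipeline(default_cohort)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        assert np.array_equal(a.model.loadings, b.model.loadings)

    def test_permutation_invariance(self, default_cohort):
        a = run_hvi_pipeline(default_cohort)
        shuffled = TractVariableTable(
            default_cohort.data.sample(frac=1, random_state=3).reset_index(),
            default_cohort.schema,
        )
        b = run_hvi_pipeline(shuffled)
        pd.testing.assert_series_equal(
            a.hvi.sort_index(), b.hvi.sort_index(), check_names=False
        )

    def test_z_scores_mean_zero_sd_one(self, default_cohort):
        res = run_hvi_pipeline(default_cohort)
        assert np.allclose(res.z_scores.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(res.z_scores.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_hvi_within_k_to_6k(self, default_cohort):
        res = run_hvi_pipeline(default_cohort)
        k = res.model.n_components
        assert res.hvi.between(k, 6 * k).all()
        assert res.categorical_scores.isin(range(1, 7)).all().all()

    def test_dominant_tract_attains_max_hvi(self, default_cohort):
        df = default_cohort.data.copy()
        extreme = df.index[0]
        for name in default_cohort.schema.increasing:
            if name == "housing_density":
                df.loc[extreme, name] = df[name].max() * 10
            else:
                df.loc[extreme, name] = 100.0
        df.loc[extreme, "pct_open_undeveloped"] = 0.0
        table = TractVariableTable(df.reset_index(), default_cohort.schema)
        res = run_hvi_pipeline(table)
        assert res.hvi.loc[extreme] == res.hvi.max()

    def test_standardize_each_mode(self, default_cohort):
        res = run_hvi_pipeline(default_cohort, scoring="standardize_each")
        assert np.allclose(res.z_scores.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(res.z_scores.std(axis=0, ddof=1), 1.0, atol=1e-9)
        assert res.hvi.between(res.model.n_components, 6 * res.model.n_components).all()

    def test_standardize_each_equals_sign_sum(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema)
        alt = component_scores_standardize_each(z, model)
        for c, label in enumerate(model.component_labels):
            expected = sum(
                np.sign(model.loadings[v, c]) * z[var]
                for v, var in enumerate(model.variables)
                if model.loadings[v, c] != 0
            )
            assert np.allclose(alt[label].to_numpy(), expected.to_numpy(), atol=1e-9)


def _match_congruence(recovered: np.ndarray, planted: np.ndarray) -> list[float]:
    """Best one-to-one matching of recovered to planted components by congruence."""
    k = planted.shape[1]
    C = np.array(
        [
            [tucker_congruence(recovered[:, i], planted[:, j]) for j in range(k)]
            for i in range(recovered.shape[1])
        ]
    )
    rows, cols = linear_sum_assignment(-np.abs(C))
    return [C[r, c] for r, c in zip(rows, cols)]


class TestParameterRecovery:
    def test_tucker_congruence_to_planted_loadings(self, default_cohort):
        z, _, _ = standardize_variables(default_cohort)
        model = fit_weighting_model(z, default_cohort.schema)
        planted = default_loading_matrix(default_cohort.schema)
        congruences = _match_congruence(model.loadings, planted)
        assert len(congruences) == 3
        assert min(congruences) >= 0.95

    def test_tucker_congruence_bounds(self):
        v = np.array([1.0, 2.0, 3.0])
        assert tucker_congruence(v, v) == pytest.approx(1.0)
        assert tucker_congruence(v, -v) == pytest.approx(-1.0)
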