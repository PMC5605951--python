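import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cohortsynth as cs
from cohortsynth.preprocess import ColumnMoments, SexModel
from cohortsynth.simulate import (
    derive_bmi,
    destandardize,
    draw_mvn_block,
    expit,
    simulate_age,
    simulate_dataset,
    simulate_sex,
    write_csv,
)
from cohortsynth.preprocess import standardize


class TestDrawMvnBlock:
    def test_identity_matrix_gives_uncorrelated_columns(self):
        z = draw_mvn_block(100_000, np.eye(2), seed=1)
        r = np.corrcoef(z, rowvar=False)[0, 1]
        assert abs(r) < 0.02

    def test_target_correlation_recovered(self):
        corr = np.array([[1.0, 0.7], [0.7, 1.0]])
        z = draw_mvn_block(100_000, corr, seed=2)
        r = np.corrcoef(z, rowvar=False)[0, 1]
        assert r == pytest.approx(0.7, abs=0.02)

    def test_deterministic_given_seed(self):
        corr = np.array([[1.0, 0.3], [0.3, 1.0]])
        a = draw_mvn_block(1000, corr, seed=5)
        b = draw_mvn_block(1000, corr, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            draw_mvn_block(0, np.eye(2), seed=1)
        with pytest.raises(ValueError, match="symmetric"):
            draw_mvn_block(10, np.array([[1.0, 0.5], [0.1, 1.0]]), seed=1)

    def test_rank_deficient_matrix_sampled_via_eigen_fallback(self):
        corr = np.ones((2, 2))  # perfectly correlated pair, singular
        z = draw_mvn_block(1000, corr, seed=3)
        np.testing.assert_allclose(z[:, 0], z[:, 1], atol=1e-9)


class TestDestandardize:
    def test_zero_maps_to_mean(self):
        m = ColumnMoments(mu=7.5, sigma=2.0)
        np.testing.assert_array_equal(destandardize([0.0, 0.0], m), [7.5, 7.5])

    def test_inverse_of_standardize_example(self):
        m = ColumnMoments(mu=2.0, sigma=1.0)
        np.testing.assert_allclose(destandardize([-1, 0, 1], m), [1.0, 2.0, 3.0])

    @settings(max_examples=200, deadline=None)
    @given(
        x=st.lists(
            st.floats(min_value=-100.0, max_value=100.0), min_size=1, max_size=20
        ),
        mu=st.floats(min_value=-100.0, max_value=100.0),
        sigma=st.floats(min_value=1e-2, max_value=100.0),
    )
    def test_round_trip_identity(self, x, mu, sigma):
        m = ColumnMoments(mu=mu, sigma=sigma)
        back = destandardize(standardize(x, m), m)
        np.testing.assert_allclose(back, x, atol=1e-12, rtol=1e-12)


class TestExpit:
    def test_symmetry_point_and_closed_form(self):
        assert expit(0.0) == 0.5
        assert expit(np.log(3.0)) == pytest.approx(0.75, abs=1e-15)

    def test_saturation_without_overflow(self):
        p = expit(np.array([40.0, 1000.0, -1000.0]))
        assert 1.0 - p[0] < 1e-15
        assert p[1] == 1.0 and p[2] == 0.0  # saturated, not NaN/overflow

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=-700, max_value=700))
    def test_complement_identity(self, y):
        assert expit(-y) == pytest.approx(1.0 - expit(y), abs=1e-12)


class TestSimulateSex:
    def test_fair_coin_when_model_is_null(self):
        model = SexModel(intercept=0.0, coefficients={"x": 0.0})
        table = pd.DataFrame({"x": np.zeros(100_000)})
        sex = simulate_sex(table, model, seed=7)
        assert set(np.unique(sex)) == {1, 2}
        assert (sex == 2).mean() == pytest.approx(0.5, abs=0.006)

    def test_saturated_intercept_gives_all_female_code(self):
        model = SexModel(intercept=40.0, coefficients={"x": 0.0})
        table = pd.DataFrame({"x": np.zeros(100)})
        assert (simulate_sex(table, model, seed=8) == 2).all()

    def test_missing_predictor_named_in_error(self):
        model = SexModel(intercept=0.0, coefficients={"height.7": 0.1})
        with pytest.raises(KeyError, match="height.7"):
            simulate_sex(pd.DataFrame({"x": [1.0]}), model, seed=9)

    def test_source_sex_proportion_transferred(self, params, schema, synthetic_155k):
        prop = (synthetic_155k[schema.sex_column].to_numpy() == 2).mean()
        assert prop == pytest.approx(params.sex_proportion, abs=0.01)


class TestDeriveBmi:
    @pytest.mark.parametrize(
        "weight, height, expected",
        [(64.8, 180.0, 20.0), (0.0, 150.0, 0.0), (50.0, 150.0, 50.0 / 2.25)],
    )
    def test_formula(self, weight, height, expected):
        assert derive_bmi([weight], [height])[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_height_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            derive_bmi([50.0], [0.0])


class TestSimulateAge:
    def test_moments_and_determinism(self):
        a = simulate_age(100_000, 7.6, 0.01, seed=11)
        assert a.mean() == pytest.approx(7.6, abs=0.0013)
        assert np.var(a, ddof=1) == pytest.approx(0.01, rel=0.05)
        np.testing.assert_array_equal(a, simulate_age(100_000, 7.6, 0.01, seed=11))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            simulate_age(10, 7.6, 0.0, seed=1)


class TestSimulateDataset:
    def test_single_row_is_complete(self, params, schema):
        table = simulate_dataset(params, schema, 1, seed=21)
        assert table.shape == (1, 71)
        assert list(table.columns) == schema.column_names
        assert not table.isna().any().any()

    def test_no_missing_values_and_sex_coding(self, synthetic_155k, schema):
        assert not synthetic_155k.isna().any().any()
        assert set(np.unique(synthetic_155k[schema.sex_column])) <= {1, 2}

    def test_bmi_identity_every_row(self, synthetic_155k, schema):
        for col in schema.bmi_columns:
            spec = schema.find(col)
            w = synthetic_155k[schema.same_wave_column(spec.wave, "weight")]
            h = synthetic_155k[schema.same_wave_column(spec.wave, "height")]
            expected = w.to_numpy() / (h.to_numpy() / 100.0) ** 2
            np.testing.assert_allclose(
                synthetic_155k[col].to_numpy(), expected, rtol=1e-9
            )

    def test_age_independent_of_measurements(self, synthetic_155k):
        bound = 4.0 / np.sqrt(len(synthetic_155k))
        for age_col, mvn_col in [
            ("age.7", "height.7"),
            ("age.11", "sbp.11"),
            ("age.17", "weight.17"),
        ]:
            r = np.corrcoef(
                synthetic_155k[age_col], synthetic_155k[mvn_col]
            )[0, 1]
            assert abs(r) < bound

    def test_byte_identical_csv_given_same_seed(self, params, schema, tmp_path):
        a = simulate_dataset(params, schema, 500, seed=33)
        b = simulate_dataset(params, schema, 500, seed=33)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_csv(a, pa)
        write_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_provenance_recorded(self, params, schema):
        table = simulate_dataset(params, schema, 10, seed=77)
        prov = table.attrs["provenance"]
        assert prov["seed"] == 77 and prov["n"] == 10
        assert prov["params_fingerprint"] == params.fingerprint()

    def test_mismatched_params_schema_rejected(self, params, mini_schema):
        with pytest.raises(ValueError, match="disagree"):
            simulate_dataset(params, mini_schema, 10, seed=1)


class TestConvergenceWithSize:
    def test_correlation_error_shrinks_with_n(self, params, schema):
        """Max |corr error| at n=155000 beats n=15500 in >=9/10 seed pairs."""
        target = params.correlation
        wins = 0
        for seed in range(100, 110):
            small = simulate_dataset(params, schema, 15_500, seed=seed)
            big = simulate_dataset(params, schema, 155_000, seed=seed + 50)
            errs = []
            for table in (small, big):
                block = table[schema.mvn_columns].to_numpy(dtype=float)
                errs.append(np.max(np.abs(np.corrcoef(block, rowvar=False) - target)))
            wins += errs[1] < errs[0]
        assert wins >= 9
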