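import numpy as np
import pandas as pd
import pytest

from stormsurv import covariates as cov


class TestStorminessPca:
    def test_perfectly_correlated_pair_explains_everything(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"n_storms": x, "dup": 3 * x + 2})
        res = cov.storminess_pc1(df)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 8)), columns=[f"v{i}" for i in range(8)])
        df = df.rename(columns={"v0": "n_storms"})
        res = cov.storminess_pc1(df)
        Z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        corr = Z.T @ Z / (len(df) - 1)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        assert res.explained * 8 == pytest.approx(eigvals, abs=1e-9)
        for c in range(8):
            ours = res.loadings.iloc[:, c].to_numpy()
            ref = eigvecs[:, c]
            assert min(np.abs(ours - ref).max(), np.abs(ours + ref).max()) < 1e-9

    def test_pc1_oriented_stormy_positive(self, rng):
        n_storms = rng.poisson(12, size=25).astype(float)
        df = pd.DataFrame(
            {
                "n_storms": n_storms,
                "days_wind_ge_30": n_storms * 0.5 + rng.normal(0, 0.5, 25),
                "mean_gap": -2.0 * n_storms + rng.normal(0, 2, 25),  # anti-correlated
            }
        )
        res = cov.storminess_pc1(df)
        assert np.corrcoef(res.pc1, df["n_storms"])[0, 1] > 0
        assert res.loadings.loc["mean_gap", "PC1"] < 0

    def test_scores_invariant_to_variable_order(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        a = cov.storminess_pc1(df, orient_by="a").pc1.to_numpy()
        b = cov.storminess_pc1(df[list("dcba")], orient_by="a").pc1.to_numpy()
        assert a == pytest.approx(b, abs=1e-9)

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12), "c": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            res = cov.storminess_pc1(df, orient_by="a")
        assert "c" not in res.loadings.index


class TestFillPopulation:
    def test_adjacent_mean(self):
        filled, flag = cov.fill_population(pd.Series([100.0, np.nan, 200.0]))
        assert filled.tolist() == [100.0, 150.0, 200.0]
        assert flag.tolist() == [False, True, False]

    def test_multi_year_gap(self):
        filled, _ = cov.fill_population(pd.Series([100.0, np.nan, np.nan, 400.0]))
        assert filled.tolist() == [100.0, 250.0, 250.0, 400.0]

    def test_trailing_carried_forward(self):
        filled, flag = cov.fill_population(pd.Series([5.0, 7.0, np.nan]))
        assert filled.tolist() == [5.0, 7.0, 7.0]
        assert flag.iloc[-1]

    def test_no_gaps_identity(self):
        s = pd.Series([1.0, 2.0, 3.0])
        filled, flag = cov.fill_population(s)
        assert filled.equals(s)
        assert not flag.any()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            cov.fill_population(pd.Series([np.nan, np.nan]))

    def test_observed_values_never_altered(self, rng):
        vals = rng.poisson(1000, 20).astype(float)
        s = pd.Series(vals.copy())
        s[rng.choice(20, 6, replace=False)] = np.nan
        if s.isna().all():
            s[0] = vals[0]
        filled, _ = cov.fill_population(s)
        obs = ~s.isna()
        assert (filled[obs] == s[obs]).all()


class TestLagsAndStandardize:
    def test_lag_shifts_by_one_winter(self):
        df = pd.DataFrame({"sSST": [10.0, 12.0, 14.0], "wSST": [1.0, 2.0, 3.0]})
        out = cov.add_lags_and_standardize(df, standardize_columns=())
        assert out["lag_sSST"].tolist()[1:] == [10.0, 12.0]
        assert np.isnan(out["lag_sSST"].iloc[0])

    def test_standardized_moments(self, rng):
        df = pd.DataFrame({"sSST": rng.normal(14, 2, 30), "wSST": rng.normal(9, 1, 30)})
        out = cov.add_lags_and_standardize(df)
        for c in ("sSST", "wSST"):
            assert abs(out[c].mean()) < 1e-9
            assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_standardization_idempotent(self, rng):
        x = pd.Series(rng.normal(size=25), name="x")
        once = cov.standardize(x)
        assert cov.standardize(once).to_numpy() == pytest.approx(
            once.to_numpy(), abs=1e-12
        )

    def test_oil_never_standardized(self):
        df = pd.DataFrame({"sSST": [1.0, 2.0, 4.0], "wSST": [1.0, 3.0, 2.0],
                           "oil": [0, 1, 0]})
        out = cov.add_lags_and_standardize(df)
        assert out["oil"].tolist() == [0, 1, 0]

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            cov.standardize(pd.Series([2.0, 2.0, 2.0], name="flat"))

    def test_correlation_screen_flags_collinear_pair(self, rng):
        pop = rng.normal(size=40)
        df = pd.DataFrame({"population": pop, "sSST": pop * 0.9 + rng.normal(0, 0.3, 40),
                           "naoi": rng.normal(size=40)})
        screen = cov.correlation_screen(df, threshold=0.7)
        row = screen[(screen["a"] == "population") & (screen["b"] == "sSST")]
        assert row["flagged"].iloc[0]


class TestOilFactor:
    def test_known_spill_assignments(self):
        years = list(range(1970, 2021))
        spills = [(1978, 3), (1992, 12), (1996, 2), (1999, 12), (2002, 11)]
        flags = cov.oil_factor(years, spills)
        flagged_winters = [years[i] for i in np.flatnonzero(flags)]
        # Feb 1996 -> winter 1995/96; Nov 2002 -> winter 2002/03;
        # Mar 1978 -> 1977/78; Dec 1992 -> 1992/93; Dec 1999 -> 1999/2000
        assert flagged_winters == [1977, 1992, 1995, 1999, 2002]

    def test_no_events_all_zero(self):
        assert cov.oil_factor([2000, 2001], []).tolist() == [0, 0]

    def test_out_of_span_and_summer_events_warn(self):
        with pytest.warns(UserWarning):
            flags = cov.oil_factor([2000], [(1980, 12)])
        assert flags.tolist() == [0]
        with pytest.warns(UserWarning, match="Nov-Mar"):
            flags = cov.oil_factor([2000], [(2000, 7)])
        assert flags.tolist() == [0]
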