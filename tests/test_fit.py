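import numpy as np
import pandas as pd
import pytest

from stormsurv import cjs
from stormsurv import synthdata as syn
from stormsurv.encounters import build_marray


class TestStructureParsing:
    @pytest.mark.parametrize(
        "label,phi,p",
        [
            ("phi(t) p(./t)", "t", "./t"),
            ("phi(.) p(t/.)", ".", "t/."),
            ("phi(PC1 + sSST) p(t + m)", "PC1 + sSST", "t+m"),
            ("phi(PC1 × population) p(./.)", "PC1 * population", "./."),
        ],
    )
    def test_roundtrip(self, label, phi, p):
        s = cjs.ModelStructure.parse(label)
        assert s.phi_spec == phi
        assert s.p_spec == p

    def test_interaction_expands_mains(self):
        s = cjs.ModelStructure("PC1 * sSST", "./.")
        assert s.phi_terms() == ["PC1", "sSST", "PC1:sSST"]
        assert s.n_slopes == 3

    def test_unknown_covariate_raises(self):
        s = cjs.ModelStructure("nope", "./.")
        cov = pd.DataFrame({"PC1": [0.0, 1.0]})
        with pytest.raises(ValueError, match="nope"):
            s.phi_design(2, cov)

    def test_trap_offset_is_single_shared_parameter(self):
        s = cjs.ModelStructure("t", "t+m")
        D, names = s.p_design(5)
        assert D.shape == (10, 6)
        assert names[-1] == "m"
        # seen-group rows carry the offset, unseen-group rows do not
        assert D[:5, -1].tolist() == [1.0] * 5
        assert D[5:, -1].tolist() == [0.0] * 5


class TestQaicc:
    def test_formula_example(self):
        assert cjs.qaicc(50.0, 1.0, 1, 100) == pytest.approx(52.0408, abs=1e-4)

    def test_overdispersion_scales_deviance(self):
        assert cjs.qaicc(100.0, 2.0, 3, 1000) == pytest.approx(
            50 + 6 + 24 / 996, abs=1e-10
        )

    def test_small_sample_guard(self):
        assert cjs.qaicc(10.0, 1.0, 10, 11) == np.inf


class TestRankModels:
    def _fit_like(self, label, q, chat=1.0):
        f = cjs.FitResult(
            structure=cjs.ModelStructure.parse(label), estimates=np.zeros(1),
            vcov=np.zeros((1, 1)), minus2lnl=q, k=1, k_structural=1, qaicc=q,
            chat_used=chat, ess=100, converged=True, boundary=np.zeros(1, bool),
            param_names=["x"], n_occasions=5, n_intervals=4,
        )
        return f

    def test_two_model_weights_follow_exp_rule(self):
        table = cjs.rank_models(
            [self._fit_like("phi(.) p(./.)", 100.0), self._fit_like("phi(t) p(./.)", 102.0)]
        )
        assert table["delta_qaicc"].tolist() == [0.0, 2.0]
        w = np.array([1.0, np.exp(-1.0)])
        assert table["weight"].to_numpy() == pytest.approx(w / w.sum(), rel=1e-12)

    def test_model_likelihood_matches_printed_pattern(self):
        # delta = 2.582 must give model likelihood 0.275 (two-sided field table)
        table = cjs.rank_models(
            [
                self._fit_like("phi(t) p(./t)", 5717.600),
                self._fit_like("phi(t) p(t/.)", 5720.182),
                self._fit_like("phi(t) p(./.)", 5814.542),
            ]
        )
        assert table["model_likelihood"].iloc[1] == pytest.approx(0.275, abs=5e-4)
        assert table["model_likelihood"].iloc[2] == pytest.approx(0.0, abs=1e-6)
        ratio = table["weight"].iloc[1] / table["weight"].iloc[0]
        assert ratio == pytest.approx(np.exp(-2.582 / 2), rel=1e-6)

    def test_single_model(self):
        table = cjs.rank_models([self._fit_like("phi(.) p(./.)", 50.0)])
        assert table["weight"].iloc[0] == pytest.approx(1.0)
        assert table["delta_qaicc"].iloc[0] == 0.0

    def test_weights_sum_to_one(self):
        fits = [self._fit_like(f"phi({i}x) p(./.)", 100.0 + 3 * i) for i in range(6)]
        table = cjs.rank_models(fits)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_mixed_chat_rejected(self):
        with pytest.raises(ValueError, match="chat"):
            cjs.rank_models(
                [
                    self._fit_like("phi(.) p(./.)", 1.0, chat=1.0),
                    self._fit_like("phi(t) p(./.)", 2.0, chat=2.0),
                ]
            )


class TestAnodev:
    def _fr(self, m2ll, label="phi(PC1) p(./.)", T=36):
        return cjs.FitResult(
            structure=cjs.ModelStructure.parse(label), estimates=np.zeros(1),
            vcov=np.zeros((1, 1)), minus2lnl=m2ll, k=1, k_structural=1, qaicc=m2ll,
            chat_used=1.0, ess=100, converged=True, boundary=np.zeros(1, bool),
            param_names=["x"], n_occasions=T + 1, n_intervals=T,
        )

    def test_no_explained_variation(self):
        res = cjs.anodev(self._fr(100.0, "phi(.) p(./.)"), self._fr(100.0), self._fr(80.0))
        assert res.r2 == 0.0 and res.f == 0.0

    def test_degrees_of_freedom_rule(self):
        cov = self._fr(90.0, "phi(PC1 + sSST) p(./.)", T=36)
        res = cjs.anodev(self._fr(100.0, "phi(.) p(./.)", T=36), cov, self._fr(80.0, T=36))
        assert (res.df1, res.df2) == (2, 33)
        assert res.r2 == pytest.approx(0.5)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            cjs.anodev(self._fr(70.0, "phi(.) p(./.)"), self._fr(75.0), self._fr(80.0))

    def test_strong_effect_r2_near_one(self):
        """Simulated survival driven almost entirely by one covariate."""
        T = 20
        rng = np.random.default_rng(77)
        cov = syn.simulate_covariates(T, ("PC1",), rng=rng)
        config = syn.SimConfig(
            n_occasions=T + 1, releases_per_occasion=150,
            phi=None, beta0=1.8, betas={"PC1": -2.0},
            p_seen=0.9, p_unseen=0.6, seed=77,
        )
        hists, _ = syn.simulate_histories(config, covariates=cov, rng=rng)
        ma = build_marray(hists)
        f_c = cjs.fit(ma, "phi(.) p(./.)", compute_vcov=False)
        f_x = cjs.fit(ma, "phi(PC1) p(./.)", covariates=cov, compute_vcov=False)
        f_t = cjs.fit(ma, "phi(t) p(./.)", compute_vcov=False)
        res = cjs.anodev(f_c, f_x, f_t)
        assert res.r2 > 0.8
        assert res.p < 1e-4


class TestSurvivalSeries:
    def test_constant_model_flat_series(self, sim_dataset):
        fr = cjs.fit(sim_dataset["marray"], "phi(.) p(./.)")
        series = cjs.survival_series(fr)
        assert series["phi"].nunique() == 1
        assert ((series["lo"] < series["phi"]) & (series["phi"] < series["hi"])).all()

    def test_time_model_flags_confounded_final_interval(self, sim_dataset):
        fr = cjs.fit(sim_dataset["marray"], "phi(t) p(./t)")
        series = cjs.survival_series(fr)
        assert len(series) == sim_dataset["marray"].n_occasions - 1
        assert not series["flagged"][:-1].all()  # interior intervals estimable


class TestCovariateEffect:
    def test_slope_table(self, sim_dataset):
        T = sim_dataset["marray"].n_occasions - 1
        cov = pd.DataFrame({"PC1": np.sin(np.arange(T))})
        fr = cjs.fit(sim_dataset["marray"], "phi(PC1) p(./.)", covariates=cov)
        eff = cjs.covariate_effect(fr)
        assert eff["term"].tolist() == ["PC1"]
        assert np.isfinite(eff["se"]).all()
        assert (eff["lo"] < eff["beta"]).all() and (eff["beta"] < eff["hi"]).all()

    def test_requires_slopes(self, sim_dataset):
        fr = cjs.fit(sim_dataset["marray"], "phi(.) p(./.)", compute_vcov=False)
        with pytest.raises(ValueError):
            cjs.covariate_effect(fr)


class TestCandidateSets:
    def test_puffin_population_unsupported(self):
        with pytest.raises(ValueError, match="puffin"):
            cjs.CandidateConfig(species="puffin", include_population=True)

    def test_guillemot_set_contains_storminess_sst_additive(self):
        config = cjs.CandidateConfig(
            species="guillemot", environmental=("sSST", "wSST", "lag_sSST", "lag_wSST", "naoi")
        )
        labels = {s.label for s in cjs.survival_candidates(config, "./t")}
        assert "phi(PC1 + sSST) p(./t)" in labels
        assert "phi(.) p(./t)" in labels and "phi(t) p(./t)" in labels
        assert "phi(oil) p(./t)" in labels

    def test_storm_set_includes_best_pair_interaction(self):
        config = cjs.CandidateConfig(
            species="razorbill",
            storm_variables=("n_storms", "days_wind_ge_30"),
        )
        labels = {
            s.label
            for s in cjs.storm_candidates(config, "t/.", "days_wind_ge_30", "population")
        }
        assert "phi(days_wind_ge_30 * population) p(t/.)" in labels

    def test_empty_covariates_only_constant_and_time(self):
        config = cjs.CandidateConfig(
            species="x", environmental=(), include_population=False,
            include_oil=False, storminess=None,
        )
        labels = [s.phi_spec for s in cjs.survival_candidates(config, "./.")]
        assert labels == [".", "t"]

    def test_deduplication_and_determinism(self):
        config = cjs.CandidateConfig(species="guillemot")
        a = [s.label for s in cjs.survival_candidates(config, "./t")]
        b = [s.label for s in cjs.survival_candidates(config, "./t")]
        assert a == b
        assert len(a) == len(set(a))
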