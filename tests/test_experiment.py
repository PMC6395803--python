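"""Predictor-set construction, the correlation screen, experiment
bookkeeping, leakage guarding and summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

from eivsdm.experiment import (
    ExperimentConfig,
    ExperimentResult,
    LeakageError,
    assert_no_leakage,
    build_predictor_sets,
    run_experiment,
    select_best_correlated,
    species_seed,
    summarize,
)


class TestBuildPredictorSets:
    @pytest.fixture()
    def sets(self):
        return {s.name: s for s in build_predictor_sets()}

    def test_reference_set_is_all_mapped(self, sets):
        ref = sets["M_ref"]
        assert ref.columns == (
            "temperature", "ph", "precipitation", "topo_position", "slope",
            "radiation",
        )
        assert ref.eiv_dimensions == ()

    def test_full_eiv_set_has_no_mapped_columns(self, sets):
        assert sets["M_EIV"].columns == (
            "eiv_T", "eiv_N", "eiv_R", "eiv_M", "eiv_K", "eiv_L"
        )

    def test_single_substitutions(self, sets):
        assert "eiv_T" in sets["M_T"].columns
        assert "temperature" not in sets["M_T"].columns
        assert "eiv_M" in sets["M_M"].columns
        assert "precipitation" not in sets["M_M"].columns
        assert "eiv_L" in sets["M_L"].columns
        assert "radiation" not in sets["M_L"].columns
        assert "eiv_R" in sets["M_R"].columns and "ph" not in sets["M_R"].columns
        assert "eiv_N" in sets["M_N"].columns and "ph" not in sets["M_N"].columns

    def test_set_sizes_match_substitution_rules(self, sets):
        n_ref = len(sets["M_ref"].columns)
        for name, s in sets.items():
            if name == "M_Soil":
                assert len(s.columns) == n_ref + 1  # pH -> N and R
            elif name == "M_K":
                assert len(s.columns) == n_ref - 1  # two topo cols -> K
            else:
                assert len(s.columns) == n_ref

    def test_mcor_built_from_mapping(self):
        cor = {"T": "temperature", "N": "ph", "R": "ph",
               "M": "precipitation", "K": "slope", "L": "radiation"}
        sets = {s.name: s for s in build_predictor_sets(cor_mapping=cor)}
        # duplicate selection (ph twice) collapses
        assert sets["M_cor"].columns == (
            "temperature", "ph", "precipitation", "slope", "radiation"
        )

    def test_missing_role_rejected(self):
        roles = {"temperature": "t", "soil": "ph", "water": "w",
                 "topography": [], "light": "l"}
        with pytest.raises(ValueError, match="topography"):
            build_predictor_sets(roles)


class TestSelectBestCorrelated:
    def test_strongest_absolute_rank_correlation_wins(self):
        rng = np.random.default_rng(21)
        n = 200
        light = rng.normal(size=n)
        site = pd.DataFrame({"L": light})
        cand = pd.DataFrame(
            {
                "solar_radiation": light + rng.normal(0, 2.5, n),
                "aspect": rng.normal(size=n),
                "cloud_cover": light + rng.normal(0, 0.7, n),
            }
        )
        out = select_best_correlated(site, cand)
        assert out["L"] == "cloud_cover"

    def test_identity_candidate_always_selected(self):
        rng = np.random.default_rng(22)
        v = rng.normal(size=50)
        site = pd.DataFrame({"T": v})
        cand = pd.DataFrame({"noise": rng.normal(size=50), "self": v})
        assert select_best_correlated(site, cand)["T"] == "self"

    def test_sign_symmetric_tie_broken_by_column_order(self):
        # candidate b = -a: |rho| identical, first column wins
        v = np.arange(10, dtype=float)
        site = pd.DataFrame({"K": v})
        cand = pd.DataFrame({"a": v.copy(), "b": -v})
        assert select_best_correlated(site, cand)["K"] == "a"
        cand2 = cand[["b", "a"]]
        assert select_best_correlated(site, cand2)["K"] == "b"

    def test_no_candidates_rejected(self):
        site = pd.DataFrame({"T": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            select_best_correlated(site, pd.DataFrame(index=site.index))


@pytest.fixture(scope="module")
def tiny_result(small_plots, small_eivs):
    roles = {
        "temperature": "temperature",
        "soil": "ph",
        "water": "precipitation",
        "topography": ["slope"],
        "light": "radiation",
    }
    # two techniques x two sets, external evaluation only; the small
    # fixture carries T/M/L only, so M_T is the EIV-bearing set
    cfg = ExperimentConfig(
        techniques=("GLM", "SRE"),
        predictor_sets=("M_ref", "M_T"),
        mapped_roles=roles,
        min_presences=30,
        internal_evaluation=False,
        include_mcor=False,
        compute_importance=False,
        master_seed=5,
    )
    species = sorted(
        small_plots.presence.sum().sort_values(ascending=False).index[:2]
    )
    return run_experiment(small_plots, small_eivs, cfg,
                          species_list=species), cfg


class TestRunExperiment:

    def test_bookkeeping_counts(self, tiny_result):
        result, _ = tiny_result
        # 2 species x 2 techniques x 2 sets -> 8 external fits
        assert result.n_fits == 8
        ext = result.metrics[result.metrics.eval_kind == "external"]
        assert len(ext) == 8

    def test_rerun_identical(self, small_plots, small_eivs, tiny_result):
        result, cfg = tiny_result
        again = run_experiment(small_plots, small_eivs, cfg,
                               species_list=result.species)
        pd.testing.assert_frame_equal(result.metrics, again.metrics)
        pd.testing.assert_frame_equal(result.summaries, again.summaries)

    def test_external_ids_never_fitted(self):
        with pytest.raises(LeakageError):
            assert_no_leakage(["p1", "p2"], frozenset({"p2"}))
        assert_no_leakage(["p1"], frozenset({"p2"}))  # disjoint is fine

    def test_species_seed_stable_and_bounded(self):
        s1 = species_seed(42, "sp001")
        assert s1 == species_seed(42, "sp001")
        assert s1 != species_seed(43, "sp001")
        assert 0 <= s1 < 2**31

    def test_loo_site_eivs_exclude_focal_from_design(
        self, small_plots, small_eivs
    ):
        # circularity guard: the focal species' own indicator values never
        # enter the site means used as its predictors
        from eivsdm.site_eiv import SiteEIVCalculator

        calc = SiteEIVCalculator(small_plots, small_eivs)
        focal = small_plots.species_ids[0]
        loo = calc.site_eivs(focal)
        present = small_plots.presence[focal] == 1
        manual = SiteEIVCalculator(
            type(small_plots)(
                plot_ids=small_plots.plot_ids,
                plot_xy=small_plots.plot_xy,
                presence=small_plots.presence.drop(columns=[focal]),
                plot_predictors=small_plots.plot_predictors,
            ),
            small_eivs,
        ).site_eivs(None)
        pd.testing.assert_frame_equal(
            loo.values.loc[present], manual.values.loc[present]
        )


class TestFullDesign:
    def test_all_techniques_and_sets_on_scaled_down_system(self):
        # end-to-end smoke of the complete design: ten predictor sets
        # (including the correlation-screened M_cor) x five techniques
        from eivsdm.simulate import (
            assemble_communities,
            default_landscape_config,
            default_species_config,
            generate_landscape,
            generate_species_pool,
        )
        from eivsdm.site_eiv import SpeciesEIVTable

        cfgL = default_landscape_config()
        cfgL = type(cfgL)(grid_shape=(48, 48), cell_size=cfgL.cell_size,
                          latent=cfgL.latent, mapped=cfgL.mapped)
        landscape = generate_landscape(cfgL, seed=201)
        pool = generate_species_pool(
            landscape, 60, default_species_config(), seed=202
        )
        plots = assemble_communities(landscape, pool, 300, seed=203)
        eivs = SpeciesEIVTable.from_species_pool(pool)
        cfg = ExperimentConfig(
            techniques=("GLM", "GAM", "RF", "MAXENT", "SRE"),
            predictor_sets=None,  # everything, M_cor included
            min_presences=30,
            n_internal=2,
            include_mcor=True,
            compute_importance=True,
            n_permutations=3,
            master_seed=204,
            hyperparameters={"RF": {"n_estimators": 30}},
        )
        species = list(plots.presence.sum().nlargest(2).index)
        result = run_experiment(plots, eivs, cfg, species_list=species)
        ext = result.metrics[result.metrics.eval_kind == "external"]
        assert set(ext.technique) == {"GLM", "GAM", "RF", "MAXENT", "SRE"}
        assert len(set(ext.predictor_set)) == 10
        assert "M_cor" in set(ext.predictor_set)
        # D2 only for the regression engines
        assert ext[ext.technique.isin(["GLM", "GAM"])]["d2"].notna().all()
        assert ext[~ext.technique.isin(["GLM", "GAM"])]["d2"].isna().all()
        internal = result.metrics[
            result.metrics.eval_kind.str.startswith("internal")
        ]
        assert set(internal.eval_kind) == {"internal_1", "internal_2"}
        assert not result.failures


class TestSummarize:
    def _result_from_metrics(self, metrics):
        return ExperimentResult(
            metrics=metrics, importances=pd.DataFrame(),
            comparisons=pd.DataFrame(), summaries=pd.DataFrame(),
            species=[], predictor_sets=[], n_fits=0,
            evaluation_id_hash={}, failures=[],
        )

    def _metrics(self, values_by_set):
        rows = []
        for pset, vals in values_by_set.items():
            for i, v in enumerate(vals):
                rows.append(
                    dict(species_id=f"s{i}", technique="GLM",
                         predictor_set=pset, eval_kind="external",
                         auc=v, tss=v, kappa=v, accuracy=v, d2=v)
                )
        return pd.DataFrame(rows)

    def test_uniform_improvement_fraction_is_one(self):
        a = np.linspace(0.6, 0.8, 9)
        metrics = self._metrics({"M_ref": a, "M_EIV": a + 0.1})
        out = summarize(self._result_from_metrics(metrics))
        row = out[(out.predictor_set == "M_EIV") & (out.metric == "auc")]
        assert row["fraction_improved"].iloc[0] == 1.0
        assert row["median_delta"].iloc[0] == pytest.approx(0.1)

    def test_reference_against_itself_is_zero_delta(self):
        a = np.linspace(0.6, 0.8, 7)
        metrics = self._metrics({"M_ref": a})
        out = summarize(self._result_from_metrics(metrics))
        row = out[out.predictor_set == "M_ref"]
        assert (row["median_delta"] == 0).all()
        assert (row["fraction_improved"] == 0).all()

    def test_quartiles_match_linear_interpolation(self):
        vals = np.array([0.1, 0.2, 0.35, 0.5, 0.6, 0.62, 0.9])
        metrics = self._metrics(
            {"M_ref": np.zeros(7), "M_EIV": vals}
        )
        out = summarize(self._result_from_metrics(metrics))
        row = out[(out.predictor_set == "M_EIV") & (out.metric == "tss")]
        assert row["q25_delta"].iloc[0] == pytest.approx(
            np.percentile(vals, 25)
        )
        assert row["q75_delta"].iloc[0] == pytest.approx(
            np.percentile(vals, 75)
        )

    def test_missing_reference_rejected(self):
        metrics = self._metrics({"M_EIV": np.linspace(0, 1, 6)})
        with pytest.raises(ValueError, match="M_ref"):
            summarize(self._result_from_metrics(metrics))
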