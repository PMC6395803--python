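"""Generator behaviour: determinism, the latent/mapped error model,
indicator binning and community assembly probabilities."""

import numpy as np
import pytest

from eivsdm.simulate import (
    ConfigurationError,
    LandscapeConfig,
    LatentLayerConfig,
    MappedLayerConfig,
    VirtualSpecies,
    assemble_communities,
    eiv_bin,
    expected_presence_count,
    filter_species_by_prevalence,
    generate_landscape,
    presence_probability,
)

from conftest import small_landscape_config, toy_plots


class TestGenerateLandscape:
    def test_zero_error_mapped_layer_identical_to_latent(self, small_landscape):
        np.testing.assert_array_equal(
            small_landscape.mapped_layers["temperature"],
            small_landscape.latent_layers["temperature"],
        )

    def test_same_seed_bit_identical(self):
        cfg = small_landscape_config()
        a = generate_landscape(cfg, seed=7)
        b = generate_landscape(cfg, seed=7)
        for name in a.latent_layers:
            np.testing.assert_array_equal(
                a.latent_layers[name], b.latent_layers[name]
            )
        for name in a.mapped_layers:
            np.testing.assert_array_equal(
                a.mapped_layers[name], b.mapped_layers[name]
            )

    def test_error_sd_controls_latent_mapped_correlation(self):
        # mapped = latent + k*sd(latent)*noise gives r = 1/sqrt(1+k^2) in
        # expectation: k=2 -> 0.447, so well below 0.6; k=0 -> identity
        cfg = small_landscape_config(
            radiation=MappedLayerConfig("light", 2.0, error_length_scale=1.0)
        )
        cfg = LandscapeConfig(
            grid_shape=(100, 100), cell_size=cfg.cell_size,
            latent=cfg.latent, mapped=cfg.mapped,
        )
        bundle = generate_landscape(cfg, seed=5)
        r_noisy = np.corrcoef(
            bundle.latent_layers["light"].ravel(),
            bundle.mapped_layers["radiation"].ravel(),
        )[0, 1]
        r_exact = np.corrcoef(
            bundle.latent_layers["temperature"].ravel(),
            bundle.mapped_layers["temperature"].ravel(),
        )[0, 1]
        assert r_noisy < 0.6
        assert r_exact > 0.99

    def test_layers_finite_and_standardised(self, small_landscape):
        for layer in small_landscape.latent_layers.values():
            assert np.all(np.isfinite(layer))
            assert abs(layer.mean()) < 1e-9
            assert abs(layer.std() - 1.0) < 1e-9

    @pytest.mark.parametrize(
        "bad",
        [
            dict(grid_shape=(8, 40)),
            dict(latent={"temperature": LatentLayerConfig(-1.0)}),
            dict(mapped={"x": MappedLayerConfig("no_such_dim", 1.0)}),
        ],
    )
    def test_invalid_config_raises(self, bad):
        base = small_landscape_config()
        cfg = LandscapeConfig(
            grid_shape=bad.get("grid_shape", base.grid_shape),
            latent=bad.get("latent", base.latent),
            mapped=bad.get("mapped", base.mapped),
        )
        with pytest.raises(ConfigurationError):
            generate_landscape(cfg, seed=0)


class TestEIVBinning:
    def test_optimum_at_layer_minimum_is_bin_one(self):
        assert eiv_bin(0.0, 0.0, 1.0) == 1

    def test_optimum_at_layer_maximum_clips_to_five(self):
        assert eiv_bin(1.0, 0.0, 1.0) == 5

    def test_uniform_optima_fill_bins_evenly(self):
        # multinomial: each of 5 bins expects 1000 of 5000, SD ~ 28.3
        rng = np.random.default_rng(42)
        opts = rng.uniform(0.0, 1.0, size=5000)
        bins = np.array([eiv_bin(o, 0.0, 1.0) for o in opts])
        counts = np.bincount(bins, minlength=6)[1:]
        sd = np.sqrt(5000 * 0.2 * 0.8)
        assert np.all(np.abs(counts - 1000) < 3 * sd)

    def test_pool_eivs_equal_binned_optima(self, small_landscape, small_pool):
        for sp in small_pool:
            for dim, val in sp.eiv.items():
                lo, hi = small_landscape.latent_range(dim)
                assert val == eiv_bin(sp.niche_optima[dim], lo, hi)

    def test_nonpositive_breadth_rejected(self):
        with pytest.raises(ValueError, match="breadth"):
            VirtualSpecies(
                species_id="x", niche_optima={"temperature": 0.0},
                niche_breadths={"temperature": 0.0},
                prevalence_scale=1.0, driving=("temperature",), eiv={},
            )


class TestAssembleCommunities:
    def _species(self, **kw):
        defaults = dict(
            species_id="s",
            niche_optima={"temperature": 0.5, "moisture": -0.2},
            niche_breadths={"temperature": 1.0, "moisture": 1.0},
            prevalence_scale=1.0,
            driving=("temperature", "moisture"),
            eiv={},
        )
        defaults.update(kw)
        return VirtualSpecies(**defaults)

    def test_probability_one_at_multivariate_optimum(self):
        sp = self._species()
        p = presence_probability(
            sp, {"temperature": 0.5, "moisture": -0.2}
        )
        assert p == pytest.approx(1.0)

    def test_probability_negligible_ten_sigma_away(self):
        sp = self._species()
        p = presence_probability(
            sp, {"temperature": 0.5 + 10.0, "moisture": -0.2}
        )
        assert p < 1e-21

    def test_mean_prevalence_matches_analytic_expectation(
        self, small_landscape, small_pool
    ):
        # Monte-Carlo over replicate assemblies vs direct averaging of the
        # occurrence probabilities at the sampled plots
        sp = small_pool[0]
        n_rep, n_plots = 200, 150
        totals = np.zeros(n_rep)
        for k in range(n_rep):
            plots = assemble_communities(
                small_landscape, [sp], n_plots, seed=500 + k
            )
            totals[k] = plots.presence[sp.species_id].sum()
        # expectation varies by plot sample; average it the same way
        expected = np.zeros(n_rep)
        for k in range(n_rep):
            plots = assemble_communities(
                small_landscape, [sp], n_plots, seed=500 + k
            )
            rows, cols = plots.plot_xy[:, 0], plots.plot_xy[:, 1]
            latent_at = {
                d: small_landscape.latent_layers[d][rows, cols]
                for d in sp.driving
            }
            expected[k] = expected_presence_count(sp, latent_at)
        mc_sd = totals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(totals.mean() - expected.mean()) < 3 * mc_sd

    def test_prevalence_scale_monotone_in_expectation(self, small_landscape):
        sp_lo = self._species(prevalence_scale=0.4)
        sp_hi = self._species(prevalence_scale=0.9)
        layer = small_landscape.latent_layers
        env = {d: layer[d].ravel() for d in sp_lo.driving}
        assert expected_presence_count(sp_hi, env) >= expected_presence_count(
            sp_lo, env
        )

    def test_plots_inside_grid_and_binary_presence(self, small_plots,
                                                   small_landscape):
        rows, cols = small_plots.plot_xy[:, 0], small_plots.plot_xy[:, 1]
        gr, gc = small_landscape.grid_shape
        assert rows.min() >= 0 and rows.max() < gr
        assert cols.min() >= 0 and cols.max() < gc
        vals = np.unique(small_plots.presence.to_numpy())
        assert set(vals).issubset({0, 1})

    def test_too_many_plots_raises(self, small_landscape, small_pool):
        with pytest.raises(ValueError, match="exceeds"):
            assemble_communities(
                small_landscape, small_pool, 40 * 40 + 1, seed=1
            )

    def test_zero_map_error_predictors_equal_latent_drivers(self):
        cfg = small_landscape_config(
            precipitation=MappedLayerConfig("moisture", 0.0),
            radiation=MappedLayerConfig("light", 0.0),
        )
        bundle = generate_landscape(cfg, seed=11)
        sp = self._species()
        plots = assemble_communities(bundle, [sp], 50, seed=12,
                                     include_latent=True)
        np.testing.assert_array_equal(
            plots.plot_predictors["precipitation"].to_numpy(),
            plots.plot_predictors["latent_moisture"].to_numpy(),
        )


class TestGroupsAndDetection:
    def test_group_labels_assigned_and_detection_thins_presences(
        self, small_landscape, small_pool
    ):
        full = assemble_communities(
            small_landscape, small_pool, 400, seed=9,
            group_fractions={"forest": 0.7, "grassland": 0.3},
        )
        assert full.group is not None
        assert set(full.group.unique()) <= {"forest", "grassland"}
        thinned = assemble_communities(
            small_landscape, small_pool, 400, seed=9,
            group_fractions={"forest": 0.7, "grassland": 0.3},
            detection={"forest": 0.2, "grassland": 0.2},
        )
        assert (
            thinned.presence.to_numpy().sum()
            < full.presence.to_numpy().sum()
        )


class TestPrevalenceFilter:
    def test_count_equal_to_threshold_is_excluded(self):
        plots = toy_plots(
            {f"p{i}": ["A", "B"] if i < 50 else ["B"] for i in range(100)}
        )
        assert plots.presence["A"].sum() == 50
        assert filter_species_by_prevalence(plots, 50) == ["B"]

    def test_ubiquitous_species_retained(self):
        plots = toy_plots({f"p{i}": ["A"] for i in range(60)})
        assert filter_species_by_prevalence(plots, 50) == ["A"]

    def test_empty_matrix_gives_empty_list(self):
        plots = toy_plots({"p1": []})
        assert filter_species_by_prevalence(plots, 1) == []
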