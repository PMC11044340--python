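"""Ground-truthed generators: trees, traits, spatial fields, scenes, bundles."""

import numpy as np
import pytest

import chromadapt as ca
from chromadapt.exceptions import ConditioningError, GamutError
from chromadapt.gls import haversine_km
from chromadapt.phylo import brownian_covariance, lambda_cov
from chromadapt.simulate import (
    SceneSpec,
    render_scene,
    simulate_dataset,
    simulate_lambda_traits,
    simulate_spatial_field,
    simulate_site_coords,
    simulate_tree,
    tree_to_newick,
)


class TestSimulateTree:
    def test_single_tip(self):
        t = simulate_tree(1, seed=0)
        leaves = t.leaf_nodes()
        assert len(leaves) == 1
        assert leaves[0].edge.length > 0

    def test_binary_node_count(self, tree27):
        assert len(tree27.leaf_nodes()) == 27
        assert len(tree27.internal_nodes()) == 26

    def test_unit_depth_and_positive_lengths(self, tree27):
        tree27.calc_node_root_distances(return_leaf_distances_only=False)
        depths = [lf.root_distance for lf in tree27.leaf_node_iter()]
        assert max(depths) == pytest.approx(1.0)
        assert all(
            e.length > 0 for e in tree27.preorder_edge_iter() if e.head_node.parent_node
        )

    def test_seed_determinism(self):
        a = tree_to_newick(simulate_tree(12, seed=5))
        b = tree_to_newick(simulate_tree(12, seed=5))
        assert a == b

    @pytest.mark.parametrize("n,rate", [(0, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_parameters(self, n, rate):
        with pytest.raises(ValueError):
            simulate_tree(n, birth_rate=rate, seed=0)


class TestSimulateLambdaTraits:
    def test_zero_intraspecific_sd_gives_identical_individuals(self, tree27):
        df = simulate_lambda_traits(tree27, 0.5, n_per_species=4, intraspecific_sd=0.0, seed=1)
        assert (df.groupby("species")["value"].nunique() == 1).all()

    def test_covariance_matches_lambda_transform(self):
        """Sample covariance of simulated tip values converges element-wise to
        sigma2 * V(lambda), within 3 Monte-Carlo SEs, for lambda 0 and 1."""
        tree = simulate_tree(8, seed=2)
        _, V = brownian_covariance(tree)
        for lam in (0.0, 1.0):
            target = lambda_cov(V, lam)
            draws = np.array(
                [
                    simulate_lambda_traits(tree, lam, sigma2=1.0, seed=1000 * int(lam) + r)[
                        "value"
                    ].to_numpy()
                    for r in range(1500)
                ]
            )
            S = np.cov(draws.T)
            # MC standard error of a covariance entry ~ sqrt((Vii*Vjj+Vij^2)/n)
            se = np.sqrt(
                (np.outer(np.diag(target), np.diag(target)) + target**2) / draws.shape[0]
            )
            assert np.all(np.abs(S - target) < 3.5 * se)

    def test_lambda_bounds(self, tree27):
        with pytest.raises(ValueError):
            simulate_lambda_traits(tree27, 1.2, seed=0)


class TestSimulateSpatialField:
    COORDS = simulate_site_coords(60, seed=3)

    def test_coincident_sites_identical_without_nugget(self):
        coords = np.array([[5.0, 40.0], [5.0, 40.0], [6.0, 41.0]])
        z = simulate_spatial_field(coords, "exponential", 100, nugget=0.0, seed=0)
        assert z[0] == pytest.approx(z[1], abs=1e-10)

    def test_exponential_correlation_at_range(self):
        """Empirical correlation at d = range matches e^-1 over replicates."""
        coords = np.array([[0.0, 40.0], [0.0, 40.0 + 100.0 / 111.195]])  # ~100 km apart
        d = haversine_km(coords)[0, 1]
        assert d == pytest.approx(100.0, rel=0.01)
        draws = np.array(
            [
                simulate_spatial_field(coords, "exponential", 100.0, 0.0, 1.0, seed=r)
                for r in range(2000)
            ]
        )
        r_emp = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert r_emp == pytest.approx(np.exp(-1.0), abs=3.0 / np.sqrt(2000))

    def test_pure_nugget_correlogram_flat(self):
        """nugget = 1: correlations vanish at every distance."""
        coords = self.COORDS[:20]
        draws = np.array(
            [
                simulate_spatial_field(coords, "exponential", 100.0, 1.0, 1.0, seed=r)
                for r in range(1500)
            ]
        )
        C = np.corrcoef(draws.T)
        off = C[np.triu_indices_from(C, k=1)]
        assert np.max(np.abs(off)) < 4.5 / np.sqrt(1500)

    def test_variogram_matches_family(self):
        """Empirical correlations track the requested family at test distances."""
        lat0 = 40.0
        dists = np.array([25.0, 50.0, 100.0, 200.0, 400.0])
        coords = np.vstack([[0.0, lat0]] + [[0.0, lat0 + d / 111.195] for d in dists])
        draws = np.array(
            [
                simulate_spatial_field(coords, "gaussian", 150.0, 0.0, 2.0, seed=10_000 + r)
                for r in range(2000)
            ]
        )
        C = np.corrcoef(draws.T)
        expected = np.exp(-((dists / 150.0) ** 2))
        got = C[0, 1:]
        assert np.all(np.abs(got - expected) < 4.0 / np.sqrt(2000) + 0.02)

    def test_seed_determinism(self):
        a = simulate_spatial_field(self.COORDS, "spherical", 80, 0.1, 1.0, seed=9)
        b = simulate_spatial_field(self.COORDS, "spherical", 80, 0.1, 1.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestRenderScene:
    def test_uniform_round_trip(self, uniform_scene):
        img, roi, truth = uniform_scene
        xs, ys = truth["roi_xy"]
        lab = ca.imaging.srgb_to_cielab(img[ys, xs])
        err = np.sqrt(((lab - np.asarray(truth["base_lab"])) ** 2).sum(axis=1))
        assert err.max() < 0.5

    def test_striped_coverage_exact(self, striped_scene):
        _, _, truth = striped_scene
        assert 0.48 <= truth["achieved_coverage"] <= 0.52

    def test_spotted_coverage(self):
        spec = SceneSpec(pattern="spotted", pattern_lab=(48.0, 18.0, 30.0), coverage=0.3, seed=1)
        _, _, truth = render_scene(spec)
        assert truth["achieved_coverage"] == pytest.approx(0.3, abs=0.02)

    def test_byte_identical_for_same_seed(self):
        spec = SceneSpec(pattern="spotted", pattern_lab=(48.0, 18.0, 30.0), coverage=0.4, noise_sd=2.0, seed=7)
        a, _, _ = render_scene(spec)
        b, _, _ = render_scene(spec)
        assert a.tobytes() == b.tobytes()

    def test_out_of_gamut_colour_rejected_with_colour(self):
        with pytest.raises(GamutError) as exc:
            SceneSpec(base_lab=(50.0, -120.0, 80.0))
        assert exc.value.lab == (50.0, -120.0, 80.0)

    def test_coverage_pattern_consistency(self):
        with pytest.raises(ValueError):
            SceneSpec(pattern="uniform", coverage=0.3)
        with pytest.raises(ValueError):
            SceneSpec(pattern="striped", pattern_lab=(48.0, 18.0, 30.0), coverage=0.0)


class TestSimulateDataset:
    def test_deterministic_bundle(self):
        a = simulate_dataset(seed=5)
        b = simulate_dataset(seed=5)
        assert a.individuals.equals(b.individuals)
        assert a.samples.equals(b.samples)
        assert a.env.equals(b.env)
        assert a.newick == b.newick

    def test_every_species_on_tree_and_sampled(self, small_bundle):
        ds, _ = small_bundle
        tips = {lf.taxon.label for lf in ds.tree.leaf_node_iter()}
        assert set(ds.individuals["species"]) == tips

    def test_mainland_convention_and_area_span(self, small_bundle):
        ds, _ = small_bundle
        mainland = ds.env[~ds.env["is_island"]]
        assert (mainland["dist_mainland"] == 0).all()
        assert (mainland["sea_depth"] == 0).all()
        islands = ds.env[ds.env["is_island"]]
        span = np.log10(islands["surface_area"].max() / islands["surface_area"].min())
        assert span >= 3.0

    def test_no_islands_all_null_isolation(self):
        ds = simulate_dataset(seed=2, island_fraction=0.0, n_individuals=60, n_sites=20)
        assert (ds.env["dist_mainland"] == 0).all()
        assert (ds.env["sea_depth"] == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_dataset(seed=0, true_lambda=1.5)
        with pytest.raises(ValueError):
            simulate_dataset(seed=0, n_species=10, n_individuals=5)

    def test_rendered_images_mode(self, tmp_path):
        ds = simulate_dataset(seed=8, n_individuals=12, n_species=6, n_sites=8, render_images=True)
        out = ds.write(tmp_path / "b")
        assert len(list((out / "images").glob("*.png"))) == 12
        assert len(list((out / "rois").glob("*.json"))) == 12

    def test_null_effect_gls_coverage(self):
        """With every planted log-area pathway zeroed (direct lightness effect
        and the atypicality channel, which also darkens), the GLS confidence
        interval for the log-area slope covers 0 in at least 93 of 100
        replicates at alpha = 0.05."""
        from chromadapt.gls import SpatialGLS

        covered = 0
        for rep in range(100):
            ds = simulate_dataset(
                seed=3000 + rep,
                beta_lightness=0.0,
                atypicality_slope=0.0,
                n_individuals=150,
                n_sites=40,
            )
            stats = (
                ds.samples.groupby(["individual_id", "species"])[["l"]].mean().reset_index()
            )
            merged = stats.merge(ds.env, on="individual_id")
            x = np.log10(merged["surface_area"].to_numpy())
            x = (x - x.mean()) / x.std(ddof=1)
            m = SpatialGLS("exponential", use_nugget=True).fit(
                x[:, None], merged["l"].to_numpy(), coords=merged[["lon", "lat"]].to_numpy()
            )
            lo, hi = m.conf_int(0.05)[1]
            covered += int(lo <= 0.0 <= hi)
        assert covered >= 93
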