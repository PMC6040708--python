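import numpy as np
import pandas as pd
import pytest

from llecorridor import circuit, rasterize, synth
from llecorridor.synth import CommunityConfig, LandscapeConfig


class TestLandscapeConfig:
    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(lle_density_range=(0.0, 0.1))
        with pytest.raises(ValueError):
            LandscapeConfig(lle_density_range=(0.5, 1.2))

    def test_invalid_plot_range_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(plots_per_area=(0, 5))
        with pytest.raises(ValueError):
            LandscapeConfig(plots_per_area=(8, 30))


class TestGenerateLandscape:
    def test_default_design_constraints(self):
        """Defaults: 8 areas, 5-8 plots each, pairwise spacing >= 100 m,
        every plot on an LLE segment of >= 2 m width."""
        geometry, plots = synth.generate_landscape(LandscapeConfig(seed=1))
        assert geometry["area_id"].nunique() == 8
        counts = plots.groupby("area_id").size()
        assert ((counts >= 5) & (counts <= 8)).all()
        for _, g in plots.groupby("area_id"):
            xy = g[["x", "y"]].to_numpy()
            d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 100.0
        assert set(plots["lle_type"]) <= {"margin", "ditch"}

    def test_reproducible_given_seed(self):
        g1, p1 = synth.generate_landscape(LandscapeConfig(seed=3, n_areas=2))
        g2, p2 = synth.generate_landscape(LandscapeConfig(seed=3, n_areas=2))
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(p1, p2)
        g3, _ = synth.generate_landscape(LandscapeConfig(seed=4, n_areas=2))
        assert not g1.equals(g3)

    def test_no_gaps_gives_connected_network(self, small_landscape):
        """With gap_rate=0 each area rasterises to one connected component."""
        cfg, _, _ = small_landscape
        cfg0 = LandscapeConfig(
            n_areas=2, area_side_m=400.0, buffer_m=100.0, gap_rate=0.0,
            plots_per_area=(4, 6), min_plot_spacing_m=60.0, seed=5,
        )
        geometry, _ = synth.generate_landscape(cfg0)
        for _, geom in geometry.groupby("area_id"):
            raster = rasterize.rasterize_lle(
                geom, cell_m=1.0, extent=(-100, -100, 500, 500)
            )
            g = circuit.raster_to_graph(raster, 8)
            assert len(set(g.component)) == 1

    def test_density_matches_target(self):
        """Pinned density range: rasterised LLE fraction within +/- 0.01."""
        cfg = LandscapeConfig(n_areas=3, lle_density_range=(0.05, 0.05), seed=9)
        geometry, _ = synth.generate_landscape(cfg)
        for _, geom in geometry.groupby("area_id"):
            raster = rasterize.rasterize_lle(geom, cell_m=1.0, extent=(0, 0, 1000, 1000))
            frac = float((raster.values == rasterize.R_LLE).mean())
            assert frac == pytest.approx(0.05, abs=0.01)

    def test_infeasible_placement_fails_with_area(self):
        cfg = LandscapeConfig(
            n_areas=1, area_side_m=300.0, buffer_m=50.0,
            plots_per_area=(8, 8), min_plot_spacing_m=290.0, seed=0,
        )
        with pytest.raises(RuntimeError, match="A1"):
            synth.generate_landscape(cfg)

    def test_geometry_extends_into_frame(self, small_landscape):
        cfg, geometry, _ = small_landscape
        xs = np.r_[geometry["x1"], geometry["x2"]]
        assert xs.min() < 0 or xs.max() > cfg.area_side_m


def toy_setup(n_plots=6):
    plots = pd.DataFrame(
        {
            "plot_id": [f"P{i}" for i in range(n_plots)],
            "area_id": "A1",
            "lle_type": "margin",
            "x": np.linspace(0, 500, n_plots),
            "y": 0.0,
        }
    )
    pool = pd.DataFrame(
        {
            "species": ["c1", "c2", "m1", "m2", "b1"],
            "group": ["meadows_pastures"] * 2 + ["none"] * 2 + ["none"],
            "dispersal_class": ["short", "medium", "long", "long", "short"],
            "aquatic": 0,
        }
    )
    resistance = lambda a, b: 0.02 * abs(int(a[1]) - int(b[1]))
    euclid = lambda a, b: 100.0 * abs(int(a[1]) - int(b[1]))
    return plots, pool, resistance, euclid


class TestSimulateCommunities:
    def test_zero_generations_equals_initial_draw(self):
        plots, pool, rfn, efn = toy_setup()
        cfg0 = CommunityConfig(species_pool=pool, n_generations=0, seed=2)
        rel0 = synth.simulate_communities(plots, cfg0, rfn, efn)
        # same seed, independent draw path
        cfg1 = CommunityConfig(species_pool=pool, n_generations=0, seed=2)
        rel1 = synth.simulate_communities(plots, cfg1, rfn, efn)
        pd.testing.assert_frame_equal(rel0, rel1)
        occ = rel0.to_numpy().mean()
        assert 0 <= occ <= 0.5  # Bernoulli(initial_occupancy) scale

    def test_infinite_corridor_scale_fills_connected_component(self):
        """lambda_corridor -> inf: a corridor species reaches every plot
        connected to an initially occupied one."""
        plots, pool, rfn, efn = toy_setup()
        cfg = CommunityConfig(
            species_pool=pool, n_generations=30, lambda_corridor=1e12,
            lambda_matrix=1e-6, initial_occupancy=0.3, seed=4,
        )
        rel = synth.simulate_communities(plots, cfg, rfn, efn)
        corr_species = ["c1", "c2", "b1"]  # short/medium -> corridor channel
        for s in corr_species:
            if rel[s].sum() > 0:
                assert rel[s].all(), s  # one connected network -> all plots

    def test_occupancy_monotone_in_generations(self):
        plots, pool, rfn, efn = toy_setup()
        rels = []
        for gen in (0, 2, 5):
            cfg = CommunityConfig(species_pool=pool, n_generations=gen, seed=6)
            rels.append(synth.simulate_communities(plots, cfg, rfn, efn).to_numpy())
        # same seed => same initial state; occupancy can only grow
        assert (rels[1] >= rels[0]).all()
        assert (rels[2].sum() >= rels[1].sum())

    def test_vanishing_matrix_scale_freezes_matrix_species(self):
        """lambda_matrix -> 0 removes colonisation for matrix-channel
        species: their occupancy stays at the initial draw, hence their
        similarity carries no Euclidean-distance signal."""
        plots, pool, rfn, efn = toy_setup()
        base = CommunityConfig(species_pool=pool, n_generations=0, seed=8)
        frozen = CommunityConfig(
            species_pool=pool, n_generations=10, lambda_matrix=1e-9,
            lambda_corridor=1e-9, seed=8,
        )
        rel0 = synth.simulate_communities(plots, base, rfn, efn)
        rel1 = synth.simulate_communities(plots, frozen, rfn, efn)
        pd.testing.assert_frame_equal(rel0, rel1)

    def test_unmapped_species_fails(self):
        plots, pool, rfn, efn = toy_setup()
        cfg = CommunityConfig(species_pool=pool, group_channel={"short": "corridor"},
                              seed=0)
        with pytest.raises(KeyError):
            synth.simulate_communities(plots, cfg, rfn, efn)

    def test_reproducible(self):
        plots, pool, rfn, efn = toy_setup()
        cfg = CommunityConfig(species_pool=pool, seed=12)
        rel1 = synth.simulate_communities(plots, cfg, rfn, efn)
        rel2 = synth.simulate_communities(plots, cfg, rfn, efn)
        pd.testing.assert_frame_equal(rel1, rel2)


class TestSpeciesPool:
    def test_default_pool_is_fully_classified(self):
        pool = synth.default_species_pool(seed=0)
        assert pool["species"].is_unique
        assert pool["dispersal_class"].isin(["short", "medium", "long"]).all()
        assert set(pool["group"]) <= set(synth.GROUPS)
        assert pool["aquatic"].isin([0, 1]).all()

    def test_write_tables_round_trip(self, tmp_path, toy_community):
        plots, releves, classification = toy_community
        geom = pd.DataFrame(
            [("A1", 0, 0, 10, 0, 2.0, "margin")], columns=rasterize.SEGMENT_COLUMNS
        )
        synth.write_tables(tmp_path / "t", geom, plots, releves, classification)
        back = pd.read_csv(tmp_path / "t_releves.csv", index_col=0)
        assert back.shape == releves.shape
        assert (back.to_numpy() == releves.to_numpy()).all()
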