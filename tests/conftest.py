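import numpy as np
import pandas as pd
import pytest

from llecorridor import rasterize, synth


@pytest.fixture(scope="session")
def small_landscape():
    """A reduced landscape (3 areas, 400-m squares, 150-m frame) that keeps
    every structural property of the full generator at desk-scale runtime."""
    cfg = synth.LandscapeConfig(
        n_areas=3,
        area_side_m=400.0,
        buffer_m=150.0,
        plots_per_area=(4, 6),
        min_plot_spacing_m=60.0,
        lle_density_range=(0.04, 0.08),
        seed=11,
    )
    geometry, plots = synth.generate_landscape(cfg)
    return cfg, geometry, plots


def _toy_plots():
    return pd.DataFrame(
        {
            "plot_id": ["P1", "P2", "P3", "P4"],
            "area_id": ["A1", "A1", "A1", "A1"],
            "lle_type": ["margin", "margin", "ditch", "ditch"],
            "x": [0.0, 100.0, 0.0, 100.0],
            "y": [0.0, 0.0, 100.0, 100.0],
        }
    )


@pytest.fixture
def toy_community():
    """Four plots, six species, hand-checkable relevés and classification."""
    plots = _toy_plots()
    releves = pd.DataFrame(
        [
            [1, 1, 0, 1, 0, 0],
            [1, 1, 1, 0, 0, 0],
            [0, 1, 0, 0, 1, 0],
            [0, 0, 0, 0, 1, 1],
        ],
        index=pd.Index(plots["plot_id"], name="plot_id"),
        columns=[f"s{i}" for i in range(1, 7)],
    )
    classification = pd.DataFrame(
        {
            "species": [f"s{i}" for i in range(1, 7)],
            "group": [
                "meadows_pastures",
                "meadows_pastures",
                "nitrophilous_tall_herb",
                "arable_weed_trackside_wasteland",
                "wet_grassland_dwarf_rush",
                "aquatic_fens_bogs",
            ],
            "dispersal_class": ["short", "medium", "long", "short", "medium", "short"],
            "aquatic": [0, 0, 0, 0, 1, 1],
        }
    )
    return plots, releves, classification


@pytest.fixture(scope="session")
def paired_glmm_data():
    """Pair-structured binomial data simulated from the model family itself
    (known fixed effects, known variance components)."""
    return simulate_pair_dataset(seed=5)


def simulate_pair_dataset(
    seed,
    n_areas=8,
    plots_per_area=6,
    beta=(-0.5, -0.8, 0.2, 0.1, 0.3, -0.1),
    sd_area=0.4,
    sd_plot=0.3,
    trials_range=(15, 40),
):
    """Generate within-area pair data with crossed plot random effects."""
    rng = np.random.default_rng(seed)
    rows = []
    u_area = rng.normal(0, sd_area, n_areas)
    plot_names = [
        f"A{a}P{p}" for a in range(n_areas) for p in range(plots_per_area)
    ]
    u_plot = dict(zip(plot_names, rng.normal(0, sd_plot, len(plot_names))))
    types = {p: ("margin" if rng.random() < 0.6 else "ditch") for p in plot_names}
    beta = np.asarray(beta, dtype=float)
    for a in range(n_areas):
        ids = [f"A{a}P{p}" for p in range(plots_per_area)]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pa, pb = ids[i], ids[j]
                iso = rng.normal()
                combo = sorted((types[pa], types[pb]), key=("margin", "ditch").index)
                d_md = float(combo == ["margin", "ditch"])
                d_dd = float(combo == ["ditch", "ditch"])
                x = np.array([1.0, iso, d_md, d_dd, iso * d_md, iso * d_dd])
                eta = x @ beta + u_area[a] + u_plot[pa] + u_plot[pb]
                n = int(rng.integers(*trials_range))
                y = rng.binomial(n, 1 / (1 + np.exp(-eta)))
                rows.append(
                    dict(area=f"A{a}", plot_a=pa, plot_b=pb, iso=iso,
                         d_md=d_md, d_dd=d_dd, y=y, n=n)
                )
    df = pd.DataFrame(rows)
    X = np.column_stack(
        [np.ones(len(df)), df.iso, df.d_md, df.d_dd,
         df.iso * df.d_md, df.iso * df.d_dd]
    )
    return df, X, beta


@pytest.fixture
def tiny_raster():
    """3x3 all-LLE raster (uniform 0.01 resistance)."""
    return rasterize.ResistanceRaster(np.full((3, 3), 0.01))
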