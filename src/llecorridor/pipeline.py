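"""End-to-end analysis runs: landscape -> rasters -> resistance -> pairs -> models.

`run_synthetic_analysis` drives the whole chain on generated data and is the
programmatic equivalent of the `report` CLI subcommand; `analyse_pair_table`
is the model/inference/prediction stage shared with file-based inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circuit, inference, rasterize, similarity, synth
from . import predict as predict_mod
from .models import IsolationModel


@dataclass
class AnalysisRun:
    """Everything a pipeline run produced."""

    geometry: pd.DataFrame
    plots: pd.DataFrame
    releves: pd.DataFrame
    classification: pd.DataFrame
    resistance: pd.DataFrame
    pair_table: pd.DataFrame
    fits: dict = field(default_factory=dict)       # species set -> measure -> results
    table1: pd.DataFrame | None = None
    table2: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


def compute_resistances(
    geometry: pd.DataFrame,
    plots: pd.DataFrame,
    config: synth.LandscapeConfig,
    neighborhood: int = 8,
) -> pd.DataFrame:
    """Rasterise each area (with gap buffers) and solve pairwise resistances."""
    frames = []
    extent = (
        -config.buffer_m,
        -config.buffer_m,
        config.area_side_m + config.buffer_m,
        config.area_side_m + config.buffer_m,
    )
    for area_id, area_geom in geometry.groupby("area_id", sort=True):
        raster = rasterize.rasterize_lle(area_geom, cell_m=config.cell_m, extent=extent)
        raster = rasterize.apply_gap_buffers(raster)
        area_plots = plots[plots["area_id"] == area_id]
        res = circuit.pairwise_resistance(raster, area_plots, neighborhood=neighborhood)
        res.insert(0, "area_id", area_id)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def analyse_pair_table(
    pair_table: pd.DataFrame,
    species_sets=("all",),
    measures=("euclidean", "resistance"),
    coding: str = "auto",
    olre: str = "auto",
    polish: bool = True,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Fit both isolation models per species set; build the slope and
    prediction reports."""
    fits: dict = {}
    t1_blocks = []
    for name in species_sets:
        fits[name] = {}
        for measure in measures:
            model = IsolationModel.from_pair_table(
                pair_table, species_set=name, measure=measure,
                coding=coding, olre=olre,
            )
            fits[name][measure] = model.fit(polish=polish)
        if set(measures) == {"euclidean", "resistance"}:
            block = inference.table1_report(
                {m: fits[name][m].simple_slopes() for m in measures}
            )
            block.insert(0, "species_set", name)
            t1_blocks.append(block)
    table1 = pd.concat(t1_blocks, ignore_index=True) if t1_blocks else pd.DataFrame()
    table2 = (
        predict_mod.table2_report(fits, pair_table)
        if set(measures) == {"euclidean", "resistance"}
        else pd.DataFrame()
    )
    return fits, table1, table2


def run_synthetic_analysis(
    seed: int = 0,
    landscape_config: synth.LandscapeConfig | None = None,
    community_config: synth.CommunityConfig | None = None,
    species_sets=("all", "short_dispersal", "long_dispersal"),
    neighborhood: int = 8,
    fit_models: bool = True,
    fit_polish: bool = True,
) -> AnalysisRun:
    """Generate a landscape and communities, then run the full analysis."""
    lconf = landscape_config or synth.LandscapeConfig(seed=seed)
    cconf = community_config or synth.CommunityConfig(seed=seed)
    geometry, plots = synth.generate_landscape(lconf)
    resistance = compute_resistances(geometry, plots, lconf, neighborhood)

    res_lookup = {
        frozenset((r.plot_a, r.plot_b)): r.resistance_ohm
        for r in resistance.itertuples(index=False)
    }
    coords = plots.set_index("plot_id")[["x", "y"]]

    def resistance_fn(pa, pb):
        return res_lookup.get(frozenset((pa, pb)), np.inf)

    def euclid_fn(pa, pb):
        dx = coords.at[pa, "x"] - coords.at[pb, "x"]
        dy = coords.at[pa, "y"] - coords.at[pb, "y"]
        return float(np.hypot(dx, dy))

    classification = cconf.species_pool
    if classification is None:
        classification = synth.default_species_pool(seed=cconf.seed)
        cconf.species_pool = classification
    releves = synth.simulate_communities(plots, cconf, resistance_fn, euclid_fn)

    pair_table = similarity.build_pair_table(releves, classification, plots, resistance)
    run = AnalysisRun(
        geometry=geometry,
        plots=plots,
        releves=releves,
        classification=classification,
        resistance=resistance,
        pair_table=pair_table,
    )
    run.log["n_disconnected_pairs"] = int((~pair_table["connected"]).sum())
    run.log["seed"] = seed
    if fit_models:
        run.fits, run.table1, run.table2 = analyse_pair_table(
            pair_table, species_sets=species_sets, polish=fit_polish
        )
        run.log["converged"] = {
            s: {m: r.converged for m, r in ms.items()} for s, ms in run.fits.items()
        }
    return run
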