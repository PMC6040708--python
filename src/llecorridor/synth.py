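"""Seeded synthetic landscapes, relevé plots, and plant communities.

The generator emulates the sampling frame of the field study the analysis is
designed for: eight 1-km² agricultural study areas whose networks of open
linear landscape elements (LLE: field margins and ditches, 2–5 m wide) cover
2.5–10 % of the area, with 5–8 vegetation plots per area placed on the LLE at
a minimum mutual spacing of 100 m, and a 500-m mapped frame around each area.

Landscapes are built as random rectangular field mosaics: Poisson-spaced
vertical and horizontal boundary lines partition the (extended) area into
fields, and LLE are grown along a connected subset of field boundaries until
the target areal density is reached.  Gaps (missing stretches of an element)
can be inserted at a configurable rate.

Plant communities are simulated as a pairwise colonisation process between
plots: each species starts with independent Bernoulli occupancy and then
spreads between plots with a distance-decay kernel, where "corridor" species
respond to circuit-theory resistance distance along the LLE network and
"matrix" species to Euclidean distance.  This encodes the causal structure
the statistical analysis is meant to detect, so recovery of the corridor
signal is a testable end-to-end property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasterize import SEGMENT_COLUMNS

MARGIN = "margin"
DITCH = "ditch"

SHORT = "short"
MEDIUM = "medium"
LONG = "long"

CORRIDOR = "corridor"
MATRIX = "matrix"
BOTH = "both"

#: phytosociological groups of the classification table
GROUPS = (
    "aquatic_fens_bogs",
    "arable_weed_trackside_wasteland",
    "meadows_pastures",
    "nitrophilous_tall_herb",
    "nutrient_poor_grassland_heath",
    "wet_grassland_dwarf_rush",
    "none",
)


@dataclass
class LandscapeConfig:
    """Geometry of the synthetic study areas.

    Defaults reproduce the study conditions: eight 1-km² areas, 1-m cells,
    LLE density between 2.5 and 10 %, margins 2–5 m wide, 5–8 plots per area
    at >= 100 m spacing, and a 500-m frame around each area.
    """

    area_side_m: float = 1000.0
    cell_m: float = 1.0
    n_areas: int = 8
    lle_density_range: tuple[float, float] = (0.025, 0.10)
    margin_width_range_m: tuple[float, float] = (2.0, 5.0)
    ditch_fraction: float = 0.35
    gap_rate: float = 0.3          # gaps per km of LLE
    gap_length_range_m: tuple[float, float] = (2.0, 12.0)
    plots_per_area: tuple[int, int] = (5, 8)
    min_plot_spacing_m: float = 100.0
    buffer_m: float = 500.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lle_density_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("lle_density_range must lie within (0, 1)")
        if self.min_plot_spacing_m < 0:
            raise ValueError("min_plot_spacing_m must be >= 0")
        plo, phi = self.plots_per_area
        if not (1 <= plo <= phi <= 20):
            raise ValueError("plots_per_area must lie within [1, 20]")


@dataclass
class CommunityConfig:
    """Colonisation process generating plot x species presence data.

    ``lambda_corridor`` is the decay scale of the corridor colonisation
    kernel on the resistance-distance scale (ohms, for the 0.01-per-cell
    raster parameterisation); ``lambda_matrix`` is the decay scale of the
    matrix kernel in metres of Euclidean distance.  ``group_channel`` maps a
    dispersal class or phytosociological group to its dispersal channel
    ({corridor, matrix, both}); dispersal-class keys take precedence.
    """

    species_pool: pd.DataFrame | None = None  # species, group, dispersal_class, aquatic
    initial_occupancy: float = 0.10
    n_generations: int = 4
    lambda_corridor: float = 0.015   # ohms
    lambda_matrix: float = 150.0     # metres
    group_channel: dict = field(
        default_factory=lambda: {SHORT: CORRIDOR, MEDIUM: CORRIDOR, LONG: MATRIX}
    )
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.initial_occupancy <= 1.0):
            raise ValueError("initial_occupancy must lie in [0, 1]")
        if self.lambda_corridor <= 0 or self.lambda_matrix <= 0:
            raise ValueError("decay scales must be positive")


def default_species_pool(n_species: int = 120, seed: int = 0) -> pd.DataFrame:
    """A plausible classified species pool.

    Group weights loosely follow the community composition on open LLE in
    intensive agricultural landscapes (meadow/pasture and nitrophilous
    tall-herb species dominant, nutrient-poor grassland species rare).
    Dispersal classes are drawn per group; aquatic-dispersal flags sit mainly
    on wetland species and overlap the terrestrial classes.
    """
    rng = np.random.default_rng(seed)
    group_w = {
        "meadows_pastures": 0.26,
        "nitrophilous_tall_herb": 0.17,
        "arable_weed_trackside_wasteland": 0.13,
        "wet_grassland_dwarf_rush": 0.09,
        "aquatic_fens_bogs": 0.07,
        "nutrient_poor_grassland_heath": 0.04,
        "none": 0.24,
    }
    class_w = {SHORT: 0.4, MEDIUM: 0.3, LONG: 0.3}
    groups = rng.choice(list(group_w), size=n_species, p=list(group_w.values()))
    classes = rng.choice(list(class_w), size=n_species, p=list(class_w.values()))
    aquatic_p = np.where(
        np.isin(groups, ["aquatic_fens_bogs", "wet_grassland_dwarf_rush"]), 0.7, 0.05
    )
    aquatic = (rng.random(n_species) < aquatic_p).astype(int)
    return pd.DataFrame(
        {
            "species": [f"sp{i:03d}" for i in range(n_species)],
            "group": groups,
            "dispersal_class": classes,
            "aquatic": aquatic,
        }
    )


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------


def _poisson_lines(rng, lo: float, hi: float, mean_spacing: float) -> np.ndarray:
    """Positions of mosaic boundary lines across [lo, hi]."""
    pos = [lo]
    while pos[-1] < hi:
        pos.append(pos[-1] + rng.exponential(mean_spacing))
    pos[-1] = hi
    return np.array(pos)


def _overlap_len(x1, y1, x2, y2, side: float) -> float:
    """Length of the part of an axis-aligned segment inside [0, side]²."""
    if x1 == x2:  # vertical
        if not (0.0 <= x1 <= side):
            return 0.0
        lo, hi = sorted((y1, y2))
        return max(0.0, min(hi, side) - max(lo, 0.0))
    if not (0.0 <= y1 <= side):
        return 0.0
    lo, hi = sorted((x1, x2))
    return max(0.0, min(hi, side) - max(lo, 0.0))


def _generate_area(rng, cfg: LandscapeConfig, area_id: str):
    """Mosaic boundaries, connected LLE subset, gap insertion for one area."""
    side = cfg.area_side_m
    lo, hi = -cfg.buffer_m, side + cfg.buffer_m
    target = rng.uniform(*cfg.lle_density_range)
    mean_w = np.mean(cfg.margin_width_range_m)
    # spacing chosen so the full mosaic holds ~1.4x the boundary length
    # needed to reach the target density inside the central square
    spacing = float(np.clip(1.4 * mean_w / target, 40.0, 250.0))
    xs = _poisson_lines(rng, lo, hi, spacing)
    ys = _poisson_lines(rng, lo, hi, spacing)

    # boundary segments between adjacent mosaic intersections
    segs = []  # (x1, y1, x2, y2), endpoints keyed on grid indices
    nodes_of = []
    for i, x in enumerate(xs):
        for j in range(len(ys) - 1):
            segs.append((x, ys[j], x, ys[j + 1]))
            nodes_of.append(((i, j), (i, j + 1)))
    nx = len(xs)
    for j, y in enumerate(ys):
        for i in range(len(xs) - 1):
            segs.append((xs[i], y, xs[i + 1], y))
            nodes_of.append(((i, j), (i + 1, j)))

    # adjacency: segments sharing an endpoint
    node_segs: dict[tuple, list[int]] = {}
    for k, (a, b) in enumerate(nodes_of):
        node_segs.setdefault(a, []).append(k)
        node_segs.setdefault(b, []).append(k)

    central = [k for k, s in enumerate(segs) if _overlap_len(*s, side) > 0]
    if not central:
        raise RuntimeError(f"area {area_id}: mosaic has no central boundary segments")
    start = int(rng.choice(central))
    chosen: dict[int, float] = {}  # seg index -> width
    frontier = [start]
    area_lle = 0.0
    target_area = target * side * side
    while frontier and area_lle < target_area:
        k = frontier.pop(int(rng.integers(len(frontier))))
        if k in chosen:
            continue
        w = rng.uniform(*cfg.margin_width_range_m)
        chosen[k] = w
        area_lle += _overlap_len(*segs[k], side) * w
        for node in nodes_of[k]:
            for k2 in node_segs[node]:
                if k2 not in chosen:
                    frontier.append(k2)

    rows = []
    for k, w in chosen.items():
        x1, y1, x2, y2 = segs[k]
        lle_type = DITCH if rng.random() < cfg.ditch_fraction else MARGIN
        rows.append((area_id, x1, y1, x2, y2, w, lle_type))
    geom = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return geom, target


def _place_plots(rng, geom: pd.DataFrame, cfg: LandscapeConfig, area_id: str):
    """Plots on >=2-m-wide LLE inside the central square, spaced >= 100 m."""
    side = cfg.area_side_m
    eligible = geom[geom["width_m"] >= 2.0]
    lengths = np.array([_overlap_len(s.x1, s.y1, s.x2, s.y2, side)
                        for s in eligible.itertuples(index=False)])
    if lengths.sum() == 0:
        raise RuntimeError(f"area {area_id}: no eligible LLE for plot placement")
    probs = lengths / lengths.sum()
    n_target = int(rng.integers(cfg.plots_per_area[0], cfg.plots_per_area[1] + 1))
    placed: list[tuple[float, float, str]] = []
    for _ in range(2000):
        if len(placed) >= n_target:
            break
        k = int(rng.choice(len(eligible), p=probs))
        seg = eligible.iloc[k]
        if seg.x1 == seg.x2:  # vertical
            lo, hi = max(0.0, min(seg.y1, seg.y2)), min(side, max(seg.y1, seg.y2))
            y = rng.uniform(lo, hi)
            x = seg.x1
        else:
            lo, hi = max(0.0, min(seg.x1, seg.x2)), min(side, max(seg.x1, seg.x2))
            x = rng.uniform(lo, hi)
            y = seg.y1
        if all(np.hypot(x - px, y - py) >= cfg.min_plot_spacing_m
               for px, py, _ in placed):
            placed.append((x, y, seg.lle_type))
    if len(placed) < cfg.plots_per_area[0]:
        raise RuntimeError(
            f"area {area_id}: could only place {len(placed)} plots "
            f"(needed >= {cfg.plots_per_area[0]}) under the spacing constraint"
        )
    return pd.DataFrame(
        {
            "plot_id": [f"{area_id}P{i + 1}" for i in range(len(placed))],
            "area_id": area_id,
            "lle_type": [t for _, _, t in placed],
            "x": [x for x, _, _ in placed],
            "y": [y for _, y, _ in placed],
        }
    )


def _insert_gaps(rng, geom: pd.DataFrame, plots: pd.DataFrame,
                 cfg: LandscapeConfig) -> pd.DataFrame:
    """Delete random stretches of LLE (gap_rate per km), avoiding plots."""
    if cfg.gap_rate <= 0 or len(geom) == 0:
        return geom
    seg_len = np.hypot(geom["x2"] - geom["x1"], geom["y2"] - geom["y1"]).to_numpy()
    n_gaps = rng.poisson(cfg.gap_rate * seg_len.sum() / 1000.0)
    out = geom.reset_index(drop=True).copy()
    px = plots["x"].to_numpy()
    py = plots["y"].to_numpy()
    for _ in range(n_gaps):
        lengths = np.hypot(out["x2"] - out["x1"], out["y2"] - out["y1"]).to_numpy()
        k = int(rng.choice(len(out), p=lengths / lengths.sum()))
        seg = out.iloc[k]
        glen = min(rng.uniform(*cfg.gap_length_range_m), lengths[k])
        t0 = rng.uniform(0, 1 - glen / lengths[k]) if glen < lengths[k] else 0.0
        t1 = t0 + glen / lengths[k]
        ux, uy = seg.x2 - seg.x1, seg.y2 - seg.y1
        gx0, gy0 = seg.x1 + t0 * ux, seg.y1 + t0 * uy
        gx1, gy1 = seg.x1 + t1 * ux, seg.y1 + t1 * uy
        # skip gaps that would swallow a plot (plots must stay on LLE)
        mid_near = (
            np.minimum(np.hypot(px - gx0, py - gy0), np.hypot(px - gx1, py - gy1))
            < glen + 8.0
        )
        if mid_near.any():
            continue
        pieces = []
        if t0 > 1e-9:
            pieces.append((seg.area_id, seg.x1, seg.y1, gx0, gy0, seg.width_m, seg.lle_type))
        if t1 < 1 - 1e-9:
            pieces.append((seg.area_id, gx1, gy1, seg.x2, seg.y2, seg.width_m, seg.lle_type))
        remaining = out.drop(index=k).reset_index(drop=True)
        if pieces:
            remaining = pd.concat(
                [remaining, pd.DataFrame(pieces, columns=SEGMENT_COLUMNS)],
                ignore_index=True,
            )
        out = remaining
    return out


def generate_landscape(config: LandscapeConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate LLE geometry and plot metadata for all study areas.

    Returns ``(geometry, plots)``: geometry has one row per LLE centreline
    segment (:data:`SEGMENT_COLUMNS`), plots one row per relevé plot
    (``plot_id, area_id, lle_type, x, y``).  Coordinates are metres local to
    each area (the central square is [0, area_side]²).  Deterministic in
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    geoms, plot_frames = [], []
    for a, child in enumerate(ss.spawn(config.n_areas)):
        rng = np.random.default_rng(child)
        area_id = f"A{a + 1}"
        geom, _ = _generate_area(rng, config, area_id)
        plots = _place_plots(rng, geom, config, area_id)
        geom = _insert_gaps(rng, geom, plots, config)
        geoms.append(geom)
        plot_frames.append(plots)
    return (
        pd.concat(geoms, ignore_index=True),
        pd.concat(plot_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------


def species_channel(species_row, group_channel: dict) -> str:
    """Dispersal channel of a species: dispersal-class key first, then
    group key; unknown species are an error."""
    cls = species_row["dispersal_class"]
    if cls in group_channel:
        return group_channel[cls]
    grp = species_row["group"]
    if grp in group_channel:
        return group_channel[grp]
    raise KeyError(
        f"species {species_row['species']}: no channel for class {cls!r} or group {grp!r}"
    )


def simulate_communities(
    plots: pd.DataFrame,
    cconf: CommunityConfig,
    resistance_fn,
    euclid_fn,
) -> pd.DataFrame:
    """Simulate presence/absence relevés by pairwise colonisation.

    ``resistance_fn(plot_a, plot_b)`` and ``euclid_fn(plot_a, plot_b)``
    return the two isolation measures for within-area plot pairs (resistance
    may be ``inf`` for disconnected pairs).  Per generation, species *s*
    colonises unoccupied plot *j* from occupied plot *i* with probability
    ``exp(-d_ij / lambda)`` where *d* is the channel's isolation measure;
    for channel ``both`` the larger of the two single-channel probabilities
    is used.  Occupancy is monotone non-decreasing (no extinction).

    Returns the relevé table: plots x species 0/1 DataFrame indexed by
    ``plot_id``.
    """
    pool = cconf.species_pool
    if pool is None:
        pool = default_species_pool(seed=cconf.seed)
    rng = np.random.default_rng(np.random.SeedSequence((cconf.seed, 911)))

    plot_ids = list(plots["plot_id"])
    areas = plots.set_index("plot_id")["area_id"]
    n_plots, n_species = len(plot_ids), len(pool)

    # per-channel colonisation probability matrices (zero across areas)
    p_corr = np.zeros((n_plots, n_plots))
    p_mat = np.zeros((n_plots, n_plots))
    for i in range(n_plots):
        for j in range(i + 1, n_plots):
            pa, pb = plot_ids[i], plot_ids[j]
            if areas[pa] != areas[pb]:
                continue
            r = resistance_fn(pa, pb)
            d = euclid_fn(pa, pb)
            pc = np.exp(-r / cconf.lambda_corridor) if np.isfinite(r) else 0.0
            pm = np.exp(-d / cconf.lambda_matrix)
            p_corr[i, j] = p_corr[j, i] = pc
            p_mat[i, j] = p_mat[j, i] = pm

    channels = np.array([species_channel(row, cconf.group_channel)
                         for _, row in pool.iterrows()])
    occ = rng.random((n_plots, n_species)) < cconf.initial_occupancy

    kernel = {CORRIDOR: p_corr, MATRIX: p_mat, BOTH: np.maximum(p_corr, p_mat)}
    for _ in range(cconf.n_generations):
        new_occ = occ.copy()
        for ch in (CORRIDOR, MATRIX, BOTH):
            cols = channels == ch
            if not cols.any():
                continue
            P = kernel[ch]
            # P(colonised) = 1 - prod over occupied sources of (1 - p_ij)
            log_miss = np.log1p(-np.minimum(P, 1 - 1e-12)) @ occ[:, cols]
            p_col = -np.expm1(log_miss)
            draws = rng.random(p_col.shape) < p_col
            new_occ[:, cols] |= draws & ~occ[:, cols]
        occ = new_occ

    return pd.DataFrame(occ.astype(int), index=pd.Index(plot_ids, name="plot_id"),
                        columns=list(pool["species"]))


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------


def write_tables(path_prefix, geometry, plots, releves, classification) -> None:
    """Write the four analysis inputs as CSV next to ``path_prefix``."""
    geometry.to_csv(f"{path_prefix}_geometry.csv", index=False)
    plots.to_csv(f"{path_prefix}_plots.csv", index=False)
    releves.to_csv(f"{path_prefix}_releves.csv")
    classification.to_csv(f"{path_prefix}_classification.csv", index=False)
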