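"""Within-area plot-pair table: isolation measures and floristic similarity.

Floristic similarity of two relevés is the unweighted Jaccard index
J = c / S, where c is the number of species present in both plots and S the
size of the species union.  J is computed for the full species list and for
subsets defined by phytosociological group, dispersal-distance class, and
the aquatic-dispersal flag; together with the Euclidean and circuit-theory
resistance distances between the plots this yields the observation table of
the analysis (one row per unordered within-area pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import GROUPS

#: species sets coded as binary presence of any shared species (many zeros)
DEFAULT_BINARY_SETS = ("arable_weed_trackside_wasteland", "aquatic_dispersal")

LLE_COMBOS = ("margin-margin", "margin-ditch", "ditch-ditch")


def jaccard(species_a, species_b) -> tuple[int, int, float]:
    """Jaccard similarity of two species sets.

    Returns ``(c, S, J)`` with c the common-species count, S the union size
    and J = c / S; J is NaN when both sets are empty (undefined similarity).
    """
    a, b = set(species_a), set(species_b)
    c = len(a & b)
    S = len(a | b)
    return c, S, (c / S if S else np.nan)


def validate_classification(releves: pd.DataFrame, classification: pd.DataFrame) -> None:
    """Every relevé species must be classified; dispersal class mandatory."""
    missing = set(releves.columns) - set(classification["species"])
    if missing:
        raise ValueError(f"unclassified species in relevé table: {sorted(missing)[:5]}...")
    bad = ~classification["dispersal_class"].isin(["short", "medium", "long"])
    if bad.any():
        raise ValueError("dispersal_class must be one of short/medium/long for all species")


def species_sets(classification: pd.DataFrame) -> dict[str, list[str]]:
    """Named species subsets: all, per group, per dispersal class, aquatic."""
    sets = {"all": list(classification["species"])}
    for grp in GROUPS:
        members = classification.loc[classification["group"] == grp, "species"]
        if grp != "none" and len(members):
            sets[grp] = list(members)
    for cls in ("short", "medium", "long"):
        members = classification.loc[classification["dispersal_class"] == cls, "species"]
        sets[f"{cls}_dispersal"] = list(members)
    aqua = classification.loc[classification["aquatic"] == 1, "species"]
    if len(aqua):
        sets["aquatic_dispersal"] = list(aqua)
    return sets


def lle_combo(type_a: str, type_b: str) -> str:
    """Symmetric LLE-type combination label of a pair."""
    return "-".join(sorted((type_a, type_b), key=("margin", "ditch").index))


def build_pair_table(
    releves: pd.DataFrame,
    classification: pd.DataFrame,
    plots: pd.DataFrame,
    resistance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per unordered within-area plot pair.

    Parameters
    ----------
    releves
        plots x species 0/1 table indexed by plot id.
    resistance
        Optional pair table with columns ``plot_a, plot_b, resistance_ohm,
        connected`` (as produced by :func:`llecorridor.circuit.
        pairwise_resistance`).  Pairs missing from it get NaN resistance.

    The output has ``area_id, plot_a, plot_b, lle_combo, euclid_m,
    resistance_ohm, connected`` plus, per species set *name*, columns
    ``c_<name>, S_<name>, J_<name>`` (J is NaN where the union is empty).
    """
    missing = set(releves.index) - set(plots["plot_id"])
    if missing:
        raise ValueError(f"plots in relevé table without coordinates: {sorted(missing)}")
    validate_classification(releves, classification)
    sets = species_sets(classification)
    meta = plots.set_index("plot_id")

    res_lookup = {}
    if resistance is not None:
        for rec in resistance.itertuples(index=False):
            key = frozenset((rec.plot_a, rec.plot_b))
            res_lookup[key] = (rec.resistance_ohm, bool(rec.connected))

    present = {pid: set(releves.columns[releves.loc[pid] > 0]) for pid in releves.index}

    rows = []
    for area_id, area_plots in plots.groupby("area_id", sort=True):
        ids = sorted(area_plots["plot_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pa, pb = ids[i], ids[j]
                ohm, conn = res_lookup.get(frozenset((pa, pb)), (np.nan, True))
                row = {
                    "area_id": area_id,
                    "plot_a": pa,
                    "plot_b": pb,
                    "lle_combo": lle_combo(meta.at[pa, "lle_type"], meta.at[pb, "lle_type"]),
                    "euclid_m": float(
                        np.hypot(meta.at[pa, "x"] - meta.at[pb, "x"],
                                 meta.at[pa, "y"] - meta.at[pb, "y"])
                    ),
                    "resistance_ohm": ohm,
                    "connected": conn,
                }
                for name, members in sets.items():
                    mset = set(members)
                    c, S, J = jaccard(present[pa] & mset, present[pb] & mset)
                    row[f"c_{name}"] = c
                    row[f"S_{name}"] = S
                    row[f"J_{name}"] = J
                rows.append(row)
    return pd.DataFrame(rows)


def code_response(
    pair_table: pd.DataFrame,
    species_set: str,
    coding: str = "auto",
    zero_threshold: float = 0.5,
) -> tuple[pd.DataFrame, str]:
    """Response coding for one species set.

    ``proportion`` returns (successes, trials) = (c, S), the only coding
    under which J = c/S is a binomial proportion; ``binary`` codes J > 0 as 1.
    ``auto`` selects binary for the conventionally sparse sets
    (:data:`DEFAULT_BINARY_SETS`) or when the fraction of zero J values
    among defined rows exceeds ``zero_threshold``.

    Rows with undefined J (empty union) are dropped.  Returns the coded
    frame (columns ``successes, trials``) indexed like the retained rows of
    ``pair_table``, and the coding used.
    """
    J = pair_table[f"J_{species_set}"]
    defined = J.notna()
    if coding == "auto":
        zero_frac = float((J[defined] == 0).mean()) if defined.any() else 1.0
        coding = (
            "binary"
            if species_set in DEFAULT_BINARY_SETS or zero_frac > zero_threshold
            else "proportion"
        )
    if coding == "binary":
        coded = pd.DataFrame(
            {"successes": (J[defined] > 0).astype(int), "trials": 1}, index=J[defined].index
        )
    elif coding == "proportion":
        coded = pd.DataFrame(
            {
                "successes": pair_table.loc[defined, f"c_{species_set}"].astype(int),
                "trials": pair_table.loc[defined, f"S_{species_set}"].astype(int),
            }
        )
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return coded, coding


@dataclass
class ZScaler:
    """Centre/scale transform with stored parameters for back-transformation."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, values) -> "ZScaler":
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2 or np.ptp(x) == 0:
            raise ValueError("z-transform needs >= 2 distinct finite values")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)))

    def transform(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def z_transform(values) -> tuple[np.ndarray, ZScaler]:
    """Centre and scale to sample SD 1; returns (z, scaler)."""
    scaler = ZScaler.fit(values)
    return scaler.transform(values), scaler


def correlation_check(pair_table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between resistance and Euclidean distance over
    connected pairs (the two isolation measures are expected to be only
    moderately correlated)."""
    ok = pair_table["connected"] & pair_table["resistance_ohm"].notna()
    sub = pair_table[ok]
    if len(sub) < 3:
        raise ValueError("need >= 3 connected pairs for the correlation check")
    r, p = stats.pearsonr(sub["resistance_ohm"], sub["euclid_m"])
    return float(r), float(p)
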