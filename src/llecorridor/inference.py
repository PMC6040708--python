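"""Post-fit statistics: simple slopes, degrees of freedom, slope contrasts.

The fitted models contain an isolation main effect (the slope for the
baseline margin-margin pair type) and its interactions with the other two
LLE-type combinations.  Simple slopes per combination are the main effect
plus the respective interaction, with standard error

    se_slope = sqrt(se_main^2 + 2 cov(main, int) + se_int^2)

taken from the fixed-effect covariance matrix.  Slopes are t-tested under
two degree-of-freedom conventions bracketing the truth for a GLMM,
df_max = N - p - g - 1 (N observations) and df_min = n - p - g - 1 (n plots);
the conservative df_min p-value is the headline one.  The resistance and
Euclidean slopes of a species set are compared with the normal-theory
contrast Z = (b1 - b2) / sqrt(se1^2 + se2^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import LLE_COMBOS


def dof(N: int, n: int, p: int, g: int) -> tuple[int, int]:
    """Bracketing degrees of freedom (df_max, df_min).

    ``N`` = number of observations (pairs), ``n`` = number of plots,
    ``p`` = number of fixed-effect parameters, ``g`` = number of study
    areas (levels of the main grouping factor).
    """
    df_max = N - p - g - 1
    df_min = n - p - g - 1
    if df_max < 1 or df_min < 1:
        raise ValueError(f"non-positive degrees of freedom: ({df_max}, {df_min})")
    return df_max, df_min


def slope_se(se_main: float, cov_main_int: float, se_int: float) -> float:
    """SE of (main effect + interaction) from the coefficient covariance."""
    var = se_main**2 + 2.0 * cov_main_int + se_int**2
    if var <= 0:
        raise ValueError("non-positive slope variance; check the covariance matrix")
    return float(np.sqrt(var))


@dataclass
class SlopeEstimate:
    lle_combo: str
    slope: float
    se: float
    t: float
    df_max: int
    df_min: int
    p_max: float
    p_min: float


def slope_t_test(slope: float, se: float, df_max: int, df_min: int,
                 lle_combo: str = "margin-margin") -> SlopeEstimate:
    """Two-tailed t-tests of a simple slope under both df conventions."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    t = slope / se
    return SlopeEstimate(
        lle_combo=lle_combo,
        slope=slope,
        se=se,
        t=t,
        df_max=df_max,
        df_min=df_min,
        p_max=float(2.0 * stats.t.sf(abs(t), df_max)),
        p_min=float(2.0 * stats.t.sf(abs(t), df_min)),
    )


def simple_slopes(params, cov, term_names, N: int, n: int, g: int) -> pd.DataFrame:
    """Simple isolation slopes per LLE-type combination from a fitted model.

    ``term_names`` must contain ``"iso"`` (the main effect, which is the
    margin-margin slope) and interaction terms ``"iso:<combo>"`` for the
    non-baseline combinations.  Returns one row per combination.
    """
    params = np.asarray(params, dtype=float)
    cov = np.asarray(cov, dtype=float)
    idx = {name: i for i, name in enumerate(term_names)}
    if "iso" not in idx:
        raise ValueError("model terms must include the isolation main effect 'iso'")
    i_main = idx["iso"]
    p = len(term_names)
    df_max, df_min = dof(N, n, p, g)
    rows = []
    for combo in LLE_COMBOS:
        if combo == "margin-margin":
            slope = params[i_main]
            se = float(np.sqrt(cov[i_main, i_main]))
        else:
            key = f"iso:{combo}"
            if key not in idx:
                continue
            j = idx[key]
            slope = params[i_main] + params[j]
            se = slope_se(
                np.sqrt(cov[i_main, i_main]), cov[i_main, j], np.sqrt(cov[j, j])
            )
        est = slope_t_test(float(slope), se, df_max, df_min, combo)
        rows.append(est.__dict__)
    return pd.DataFrame(rows)


@dataclass
class DeltaTest:
    """Normal-theory contrast between two independent slope estimates."""

    delta: float
    se_delta: float
    z: float
    pvalue: float


def delta_test(b1: float, se1: float, b2: float, se2: float) -> DeltaTest:
    """Z-test of the difference between the resistance slope ``b1`` and the
    Euclidean slope ``b2`` (two-tailed, standard normal reference)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    delta = b1 - b2
    se_delta = float(np.hypot(se1, se2))
    z = delta / se_delta
    return DeltaTest(delta=float(delta), se_delta=se_delta, z=float(z),
                     pvalue=float(2.0 * stats.norm.sf(abs(z))))


def table1_report(slopes_by_measure: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Side-by-side slope report for the two isolation measures of one
    species set, with the per-combination slope contrast columns.

    ``slopes_by_measure`` maps ``{"euclidean": ..., "resistance": ...}`` to
    the output of :func:`simple_slopes`.  Estimates and SEs are rounded to
    3 decimals (report convention).
    """
    eu = slopes_by_measure["euclidean"].set_index("lle_combo")
    re = slopes_by_measure["resistance"].set_index("lle_combo")
    rows = []
    for combo in eu.index:
        d = delta_test(re.at[combo, "slope"], re.at[combo, "se"],
                       eu.at[combo, "slope"], eu.at[combo, "se"])
        rows.append(
            {
                "lle_combo": combo,
                "b_euclid": round(eu.at[combo, "slope"], 3),
                "se_euclid": round(eu.at[combo, "se"], 3),
                "p_euclid": round(eu.at[combo, "p_min"], 3),
                "b_resist": round(re.at[combo, "slope"], 3),
                "se_resist": round(re.at[combo, "se"], 3),
                "p_resist": round(re.at[combo, "p_min"], 3),
                "delta": round(d.delta, 3),
                "se_delta": round(d.se_delta, 3),
                "p_delta": round(d.pvalue, 3),
            }
        )
    return pd.DataFrame(rows)
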