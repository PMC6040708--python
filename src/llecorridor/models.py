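"""Model/Results interface tying the pair table to the mixed-model machinery.

:class:`IsolationModel` is built from a pair table for one species set and
one isolation measure; :meth:`IsolationModel.fit` returns an
:class:`IsolationResults` carrying the estimates, their covariance, variance
components, and the derived statistics (simple slopes per LLE-type
combination, parametric-bootstrap test of the isolation effect, predictions
at isolation extremes, cumulative-residual linearity check).

The fixed-effect design is always the 6-parameter specification
``intercept + iso + margin-ditch + ditch-ditch + iso:margin-ditch +
iso:ditch-ditch`` with the isolation measure z-scored over the included rows
and margin-margin the baseline; random intercepts are study area and the two
plots of each pair, plus an observation-level effect when the Pearson
overdispersion test calls for one (proportion-coded responses only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glmm, inference, predict as predict_mod
from .similarity import ZScaler, code_response

TERM_NAMES = (
    "intercept",
    "iso",
    "margin-ditch",
    "ditch-ditch",
    "iso:margin-ditch",
    "iso:ditch-ditch",
)


@dataclass
class ModelSpec:
    """Configuration of one similarity-vs-isolation model."""

    species_set: str = "all"
    measure: str = "resistance"  # or "euclidean"
    coding: str = "auto"         # proportion | binary | auto
    olre: str = "auto"           # auto | on | off
    bootstrap_B: int = 999
    seed: int = 0


class IsolationModel:
    """Binomial GLMM of pairwise Jaccard similarity against one isolation
    measure, with LLE-type combination as moderator."""

    def __init__(self, pair_table: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.pair_table = pair_table
        iso_col = "euclid_m" if spec.measure == "euclidean" else "resistance_ohm"

        coded, self.coding = code_response(pair_table, spec.species_set, spec.coding)
        rows = coded.index
        # drop disconnected / missing-isolation rows (logged, not imputed)
        iso_ok = pair_table.loc[rows, iso_col].replace(np.inf, np.nan).notna()
        if spec.measure == "resistance":
            iso_ok &= pair_table.loc[rows, "connected"].astype(bool)
        self.n_dropped = int((~iso_ok).sum())
        rows = rows[iso_ok]
        if len(rows) < 30:
            raise ValueError(
                f"only {len(rows)} usable pairs for {spec.species_set}/{spec.measure}"
            )
        self.included_rows = rows
        sub = pair_table.loc[rows]

        iso_raw = sub[iso_col].to_numpy(dtype=float)
        self.scaler = ZScaler.fit(iso_raw)
        z = self.scaler.transform(iso_raw)
        d_md = (sub["lle_combo"] == "margin-ditch").to_numpy(dtype=float)
        d_dd = (sub["lle_combo"] == "ditch-ditch").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), z, d_md, d_dd, z * d_md, z * d_dd])
        keep = [0, 1]
        for k, dummy in ((2, d_md), (3, d_dd)):
            if dummy.any():
                keep += [k, k + 2]
        self.term_names = [TERM_NAMES[k] for k in sorted(keep)]
        X = X[:, sorted(keep)]

        self.groups = {
            "area": sub["area_id"].to_numpy(),
            "plot_a": sub["plot_a"].to_numpy(),
            "plot_b": sub["plot_b"].to_numpy(),
        }
        self.successes = coded.loc[rows, "successes"].to_numpy(dtype=float)
        self.trials = coded.loc[rows, "trials"].to_numpy(dtype=float)
        self.exog = X
        self.n_obs = len(rows)
        self.n_plots = len(set(sub["plot_a"]) | set(sub["plot_b"]))
        self.n_areas = sub["area_id"].nunique()

    @classmethod
    def from_pair_table(
        cls,
        pair_table: pd.DataFrame,
        species_set: str = "all",
        measure: str = "resistance",
        coding: str = "auto",
        olre: str = "auto",
    ) -> "IsolationModel":
        return cls(pair_table, ModelSpec(species_set, measure, coding, olre))

    def _mixed_model(self, with_olre: bool, drop_iso: bool = False
                     ) -> glmm.BinomialLogitMixed:
        groups = dict(self.groups)
        if with_olre:
            groups["obs"] = np.arange(self.n_obs)
        if drop_iso:
            cols = [i for i, t in enumerate(self.term_names) if not t.startswith("iso")]
            X = self.exog[:, cols]
            names = [self.term_names[i] for i in cols]
        else:
            X, names = self.exog, self.term_names
        return glmm.BinomialLogitMixed(
            self.successes, self.trials, X, groups, exog_names=names
        )

    def fit(self, polish: bool = True) -> "IsolationResults":
        """Fit the GLMM, applying the configured OLRE policy.

        ``polish=False`` skips the Nelder-Mead refinement of the outer
        variance optimum (simulation studies; ~1e-3 effect on estimates).
        """
        olre = self.spec.olre
        if self.coding == "binary" and olre == "auto":
            olre = "off"
        model = self._mixed_model(with_olre=(olre == "on"))
        result = model.fit(polish=polish)
        od = glmm.overdispersion_check(result)
        if olre == "auto" and od.add_olre:
            model = self._mixed_model(with_olre=True)
            result = model.fit(polish=polish)
            olre = "on"
        elif olre == "auto":
            olre = "off"
        return IsolationResults(self, model, result, od, olre_used=(olre == "on"))


@dataclass
class IsolationResults:
    """Fitted isolation model with its derived statistics."""

    isolation_model: IsolationModel
    mixed_model: glmm.BinomialLogitMixed
    raw: glmm.BinomialMixedResults
    overdispersion: glmm.OverdispersionResult
    olre_used: bool

    # -- pass-through ------------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        return self.raw.params

    @property
    def bse(self) -> np.ndarray:
        return self.raw.bse

    @property
    def llf(self) -> float:
        return self.raw.llf

    @property
    def vcomp(self) -> dict:
        return self.raw.vcomp

    @property
    def converged(self) -> bool:
        return self.raw.converged

    def cov_params(self) -> np.ndarray:
        return self.raw.cov_params()

    @property
    def term_names(self):
        return self.isolation_model.term_names

    @property
    def scaler(self) -> ZScaler:
        return self.isolation_model.scaler

    @property
    def included_rows(self):
        return self.isolation_model.included_rows

    # -- derived statistics ------------------------------------------------

    def simple_slopes(self) -> pd.DataFrame:
        """Isolation slope per LLE-type combination, with bracketing-df
        t-tests (conservative p based on df_min)."""
        return inference.simple_slopes(
            self.params,
            self.cov_params(),
            self.term_names,
            N=self.isolation_model.n_obs,
            n=self.isolation_model.n_plots,
            g=self.isolation_model.n_areas,
        )

    def bootstrap_isolation_test(self, B: int | None = None,
                                 seed: int | None = None) -> glmm.BootstrapTest:
        """Parametric-bootstrap LRT of the isolation main effect (the null
        drops the main effect together with its interactions)."""
        B = B if B is not None else self.isolation_model.spec.bootstrap_B
        seed = seed if seed is not None else self.isolation_model.spec.seed
        full = self.mixed_model
        null = self.isolation_model._mixed_model(with_olre=self.olre_used,
                                                 drop_iso=True)
        return glmm.bootstrap_lrt(full, null, B=B, seed=seed)

    def predict_jaccard(self, iso_value: float, combo: str = "margin-margin") -> float:
        """Predicted Jaccard similarity at a data-scale isolation value."""
        import warnings

        rows = self.included_rows
        col = "euclid_m" if self.isolation_model.spec.measure == "euclidean" \
            else "resistance_ohm"
        obs = self.isolation_model.pair_table.loc[rows, col]
        if not (obs.min() <= iso_value <= obs.max()):
            warnings.warn("isolation value outside the observed range")
        return predict_mod.predict_jaccard(self, iso_value, combo)

    def linearity_check(self, B: int = 1000, seed: int | None = None
                        ) -> glmm.LinearityCheck:
        """Cumulative-residual linearity check on the GLM variant of the
        model (study area as fixed effect, no random effects)."""
        import statsmodels.api as sm

        im = self.isolation_model
        areas = pd.get_dummies(
            pd.Series(im.groups["area"]), drop_first=True, dtype=float
        ).to_numpy()
        X = np.column_stack([im.exog, areas])
        y = np.column_stack([im.successes, im.trials - im.successes])
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        resid = np.asarray(fit.resid_pearson)
        iso = im.exog[:, im.term_names.index("iso")]
        return glmm.linearity_check(resid, iso, B=B, seed=seed)

    def summary(self) -> pd.DataFrame:
        """Coefficient table plus variance components and fit diagnostics."""
        tab = self.raw.summary()
        extras = pd.DataFrame(
            {
                "estimate": list(self.vcomp.values())
                + [self.overdispersion.ratio, float(self.converged)],
            },
            index=[f"var({k})" for k in self.vcomp] + ["pearson_ratio", "converged"],
        )
        return pd.concat([tab, extras])

    def plot_distance_decay(self, ax=None, combo: str = "margin-margin"):
        """Observed J against the isolation measure with the population-level
        prediction curve for one LLE-type combination."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = self.isolation_model
        col = "euclid_m" if im.spec.measure == "euclidean" else "resistance_ohm"
        sub = im.pair_table.loc[self.included_rows]
        sub = sub[sub["lle_combo"] == combo]
        j = sub[f"J_{im.spec.species_set}"]
        ax.scatter(sub[col], j, s=18, alpha=0.6, label="observed pairs")
        grid = np.linspace(sub[col].min(), sub[col].max(), 100)
        ax.plot(grid, [predict_mod.predict_jaccard(self, v, combo) for v in grid],
                color="crimson", label="model prediction")
        ax.set_xlabel(f"{im.spec.measure} distance")
        ax.set_ylabel(f"Jaccard similarity ({im.spec.species_set})")
        ax.set_title(combo)
        ax.legend()
        return ax
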