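"""Binomial-logit mixed models with crossed random intercepts.

The fitter maximises the Laplace-approximate marginal likelihood of a
binomial GLMM with logit link and independent random intercepts for an
arbitrary set of (possibly crossed) grouping factors — the model family used
to relate pairwise floristic similarity to isolation measures, with random
intercepts for study area and for the two plots of each pair, plus an
optional observation-level random effect (OLRE) absorbing overdispersion.

Estimation follows the standard two-level scheme: the inner loop is a
penalised iteratively reweighted least squares (Newton) solve for the fixed
effects and the conditional modes of the random effects jointly; the outer
loop is a bounded quasi-Newton search over the log standard deviations of
the random effects.  The Laplace log-likelihood is

    ll = loglik(y | eta_hat) - u_hat' D^-1 u_hat / 2
         - log det(D) / 2 - log det(Z' W Z + D^-1) / 2

with D the random-effect covariance and W the IRLS weights at the joint
mode.  Fixed-effect covariance is the beta block of the inverse joint
Hessian (conditional on the estimated variances, as is conventional).

Also here: the Pearson overdispersion check with the OLRE decision rule,
the parametric-bootstrap likelihood-ratio test of a fixed-effect term, and
a cumulative-residual linearity check for the GLM variant of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, special, stats
from scipy.sparse.linalg import splu

_ETA_CLIP = 30.0
_DENSE_LIMIT = 1200
_THETA_BOUNDS = (np.log(1e-3), np.log(30.0))


def _expit(eta):
    return special.expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


class BinomialLogitMixed:
    """Binomial GLMM with logit link and independent random intercepts.

    Parameters
    ----------
    successes, trials
        Response: ``successes[i] ~ Binomial(trials[i], p_i)``; binary data
        uses ``trials = 1``.
    exog
        Fixed-effect design matrix (N x p), full rank.
    groups
        Mapping factor name -> length-N label array; each factor contributes
        one random intercept per distinct label.  An empty mapping gives an
        ordinary GLM.
    """

    def __init__(self, successes, trials, exog, groups=None, exog_names=None):
        self.y = np.asarray(successes, dtype=float)
        self.trials = np.asarray(trials, dtype=float)
        if np.isscalar(trials) or self.trials.ndim == 0:
            self.trials = np.full_like(self.y, float(trials))
        self.X = np.asarray(exog, dtype=float)
        self.n_obs, self.k_fe = self.X.shape
        if self.y.shape[0] != self.n_obs or self.trials.shape[0] != self.n_obs:
            raise ValueError("response and design lengths differ")
        if np.any(self.y < 0) or np.any(self.y > self.trials):
            raise ValueError("successes must lie in [0, trials]")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.k_fe)
        ]
        groups = groups or {}
        self.group_names = list(groups)
        self.z_blocks = []
        self.group_levels = {}
        for name in self.group_names:
            labels = pd.Categorical(np.asarray(groups[name]))
            q = len(labels.categories)
            z = sparse.csr_matrix(
                (np.ones(self.n_obs), (np.arange(self.n_obs), labels.codes)),
                shape=(self.n_obs, q),
            )
            self.z_blocks.append(z)
            self.group_levels[name] = list(labels.categories)

    # -- helpers -----------------------------------------------------------

    def _design(self, active):
        """Augmented design [X, Z_active] and per-factor sizes; dense when
        small (cheaper than sparse overhead), sparse otherwise."""
        key = tuple(active)
        if not hasattr(self, "_design_cache"):
            self._design_cache = {}
        if key in self._design_cache:
            return self._design_cache[key]
        blocks = [self.z_blocks[i] for i in active]
        sizes = [b.shape[1] for b in blocks]
        dim = self.k_fe + sum(sizes)
        # dense only when the N x dim Hessian build stays cheap
        if self.n_obs * dim <= 200_000:
            A = np.hstack([self.X] + [b.toarray() for b in blocks]) if blocks else self.X
        elif blocks:
            A = sparse.hstack([sparse.csr_matrix(self.X)] + blocks, format="csr")
        else:
            A = sparse.csr_matrix(self.X)
        self._design_cache[key] = (A, sizes)
        return A, sizes

    def _loglik(self, eta):
        """Binomial log-likelihood up to the constant binomial coefficient."""
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return float(np.sum(self.y * eta - self.trials * np.logaddexp(0.0, eta)))

    def _pirls(self, A, sizes, sigmas, w_start=None, tol=1e-13, maxiter=100):
        """Joint Newton over (beta, u); returns mode, H factor info, loglik."""
        p = self.k_fe
        q = sum(sizes)
        dim = p + q
        pen = np.zeros(dim)
        off = p
        for s, sg in zip(sizes, sigmas):
            pen[off : off + s] = 1.0 / (sg * sg)
            off += s
        w = np.zeros(dim) if w_start is None else w_start.copy()

        def objective(wvec):
            eta = A @ wvec
            return self._loglik(eta) - 0.5 * float(np.sum(pen * wvec * wvec))

        f = objective(w)
        H = None
        for _ in range(maxiter):
            eta = A @ w
            mu = self.trials * _expit(eta)
            wts = np.maximum(self.trials * _expit(eta) * (1.0 - _expit(eta)), 1e-10)
            grad = A.T @ (self.y - mu) - pen * w
            if sparse.issparse(A):
                WA = A.multiply(wts[:, None])
                H = (A.T @ WA).tocsc()
                H = H + sparse.diags(pen + 1e-10)
                step = splu(H, permc_spec="COLAMD",
                            options={"SymmetricMode": True}).solve(grad)
            else:
                H = A.T @ (A * wts[:, None])
                H[np.diag_indices_from(H)] += pen + 1e-10
                try:
                    chol = np.linalg.cholesky(H)
                except np.linalg.LinAlgError:
                    H[np.diag_indices_from(H)] += 1e-6
                    chol = np.linalg.cholesky(H)
                step = np.linalg.solve(chol.T, np.linalg.solve(chol, grad))
            # step halving
            t = 1.0
            for _ in range(30):
                w_new = w + t * step
                f_new = objective(w_new)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            improved = f_new - f
            w, f = w_new, f_new
            if abs(improved) < tol * (abs(f) + 1.0):
                break
        return w, f, H, pen

    def _laplace(self, theta, active, sizes, w_start=None, inner_tol=1e-13):
        """Laplace marginal log-likelihood at log-SD vector theta."""
        sigmas = np.exp(theta)
        A, _ = self._design(active)
        w, f, H, pen = self._pirls(A, sizes, sigmas, w_start=w_start, tol=inner_tol)
        p = self.k_fe
        q = sum(sizes)
        ll = f
        if q:
            # -0.5 log det D
            off = 0
            for s, sg in zip(sizes, sigmas):
                ll -= s * np.log(sg)
                off += s
            if sparse.issparse(H):
                Huu = H[p:, p:].tocsc()
                lu = splu(Huu, permc_spec="COLAMD", options={"SymmetricMode": True})
                diag_u = lu.U.diagonal()
                if np.any(diag_u == 0):
                    return -np.inf, w
                # SPD matrix: |det| = prod |U_ii| and det > 0
                ll -= 0.5 * float(np.sum(np.log(np.abs(diag_u))))
            else:
                sign, logdet = np.linalg.slogdet(H[p:, p:])
                if sign <= 0:
                    return -np.inf, w
                ll -= 0.5 * logdet
        return ll, w

    # -- fitting -----------------------------------------------------------

    def fit(self, fixed_variances=None, maxiter=200, tol=1e-8,
            start_theta=None, polish=True, inner_tol=1e-13) -> "BinomialMixedResults":
        """Maximise the Laplace marginal likelihood.

        ``fixed_variances`` maps factor names to fixed variance values; a
        factor fixed at 0 is removed from the model (the GLM limit when all
        are 0).  Estimated variances are searched on the log-SD scale within
        wide bounds; a variance at the lower bound is reported as ~0 with
        the ``singular`` flag.
        """
        fixed_variances = fixed_variances or {}
        active = [
            i
            for i, name in enumerate(self.group_names)
            if fixed_variances.get(name) is None or fixed_variances[name] > 0
        ]
        est_idx = [i for i in active if self.group_names[i] not in fixed_variances]
        sizes = [self.z_blocks[i].shape[1] for i in active]

        warm = {"w": None}

        def theta_full(theta_est):
            th = np.empty(len(active))
            k = 0
            for slot, i in enumerate(active):
                name = self.group_names[i]
                if name in fixed_variances:
                    th[slot] = 0.5 * np.log(fixed_variances[name])
                else:
                    th[slot] = theta_est[k]
                    k += 1
            return th

        def negll(theta_est):
            ll, w = self._laplace(theta_full(theta_est), active, sizes,
                                  w_start=warm["w"], inner_tol=inner_tol)
            warm["w"] = w
            return -ll

        converged = True
        if len(est_idx) == 1 and not polish:
            # cheap path for single-variance refits (bootstrap replicates)
            res = optimize.minimize_scalar(
                lambda t: negll(np.array([t])),
                bounds=_THETA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-4},
            )
            theta_est = np.array([res.x])
        elif est_idx:
            x0 = (np.zeros(len(est_idx)) if start_theta is None
                  else np.asarray(start_theta, dtype=float))
            res = optimize.minimize(
                negll,
                x0,
                method="L-BFGS-B",
                bounds=[_THETA_BOUNDS] * len(est_idx),
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7,
                         "eps": 1e-5},
            )
            theta_est = res.x
            converged = bool(res.success) or res.status == 0
            if polish:
                res2 = optimize.minimize(
                    negll,
                    theta_est,
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
                )
                if res2.fun <= res.fun:
                    theta_est = np.clip(res2.x, *_THETA_BOUNDS)
        else:
            theta_est = np.empty(0)

        theta = theta_full(theta_est)
        sigmas = np.exp(theta)
        A, _ = self._design(active)
        w, f, H, pen = self._pirls(A, sizes, sigmas, w_start=warm["w"], tol=inner_tol)
        ll, _ = self._laplace(theta, active, sizes, w_start=w, inner_tol=inner_tol)

        p = self.k_fe
        beta = w[:p]
        u = w[p:]
        # fixed-effect covariance: beta block of the inverse joint Hessian
        if u.size:
            if sparse.issparse(H):
                Huu = H[p:, p:].tocsc()
                Hub = np.asarray(H[p:, :p].todense())
                sol = splu(Huu, permc_spec="COLAMD",
                           options={"SymmetricMode": True})
                schur = np.asarray(H[:p, :p].todense()) - Hub.T @ np.column_stack(
                    [sol.solve(Hub[:, k]) for k in range(p)]
                )
            else:
                schur = H[:p, :p] - H[p:, :p].T @ np.linalg.solve(H[p:, p:], H[p:, :p])
        else:
            schur = H[:p, :p] if not sparse.issparse(H) else np.asarray(H.todense())
        cov_beta = np.linalg.inv(schur)
        cov_beta = 0.5 * (cov_beta + cov_beta.T)

        vcomp = {}
        singular = False
        off = 0
        for slot, i in enumerate(active):
            name = self.group_names[i]
            vcomp[name] = float(sigmas[slot] ** 2)
            if name not in fixed_variances and theta[slot] <= _THETA_BOUNDS[0] + 1e-6:
                singular = True
            off += sizes[slot]
        for name in self.group_names:
            vcomp.setdefault(name, 0.0)

        eta = A @ w
        mu_p = _expit(eta)
        resid_pearson = (self.y - self.trials * mu_p) / np.sqrt(
            np.maximum(self.trials * mu_p * (1 - mu_p), 1e-12)
        )
        re_modes = {}
        off = p
        for slot, i in enumerate(active):
            name = self.group_names[i]
            re_modes[name] = w[off : off + sizes[slot]].copy()
            off += sizes[slot]

        return BinomialMixedResults(
            model=self,
            params=beta,
            cov_params_mat=cov_beta,
            vcomp=vcomp,
            llf=float(ll),
            converged=converged,
            singular=singular,
            fittedvalues=mu_p,
            resid_pearson=resid_pearson,
            re_modes=re_modes,
            theta=theta_est.copy(),
        )

    def clone_with(self, successes) -> "BinomialLogitMixed":
        """Same design, new response (for bootstrap refits)."""
        new = BinomialLogitMixed.__new__(BinomialLogitMixed)
        new.__dict__.update(self.__dict__)
        new.y = np.asarray(successes, dtype=float)
        return new

    def simulate(self, params, vcomp, rng) -> np.ndarray:
        """Draw a response vector from the model at (params, vcomp),
        re-drawing the random effects (unconditional parametric bootstrap)."""
        eta = self.X @ np.asarray(params, dtype=float)
        for name, z in zip(self.group_names, self.z_blocks):
            sd = np.sqrt(vcomp.get(name, 0.0))
            if sd > 0:
                eta = eta + z @ rng.normal(0.0, sd, size=z.shape[1])
        p = _expit(eta)
        return rng.binomial(self.trials.astype(int), p).astype(float)


@dataclass
class BinomialMixedResults:
    """Laplace fit of :class:`BinomialLogitMixed`."""

    model: BinomialLogitMixed
    params: np.ndarray
    cov_params_mat: np.ndarray
    vcomp: dict
    llf: float
    converged: bool
    singular: bool
    fittedvalues: np.ndarray
    resid_pearson: np.ndarray
    re_modes: dict
    theta: np.ndarray

    def cov_params(self) -> np.ndarray:
        return self.cov_params_mat

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params_mat))

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    def pearson_ratio(self) -> float:
        """Sum of squared Pearson residuals over residual df."""
        df = self.model.n_obs - self.model.k_fe
        return float(np.sum(self.resid_pearson**2) / df)

    def summary(self) -> pd.DataFrame:
        z = self.params / self.bse
        tab = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": z,
                "p>|z|": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.model.exog_names,
        )
        return tab


# ---------------------------------------------------------------------------
# overdispersion
# ---------------------------------------------------------------------------


@dataclass
class OverdispersionResult:
    ratio: float
    statistic: float
    df: int
    pvalue: float
    add_olre: bool


def overdispersion_check(result: BinomialMixedResults, alpha: float = 0.05
                         ) -> OverdispersionResult:
    """Pearson chi-square test for residual overdispersion.

    An observation-level random effect is indicated when the Pearson
    statistic is significantly large at level ``alpha``.  Binary responses
    (all trials 1) carry no information about overdispersion, so the OLRE
    is never added there.
    """
    df = result.model.n_obs - result.model.k_fe
    statistic = float(np.sum(result.resid_pearson**2))
    ratio = statistic / df
    pvalue = float(stats.chi2.sf(statistic, df))
    binary = bool(np.all(result.model.trials <= 1))
    return OverdispersionResult(
        ratio=ratio,
        statistic=statistic,
        df=df,
        pvalue=pvalue,
        add_olre=(not binary) and pvalue < alpha,
    )


# ---------------------------------------------------------------------------
# parametric bootstrap term test
# ---------------------------------------------------------------------------


@dataclass
class BootstrapTest:
    statistic: float
    pvalue: float
    n_boot: int
    n_failed: int
    null_stats: np.ndarray = field(repr=False)


def bootstrap_lrt(
    full_model: BinomialLogitMixed,
    null_model: BinomialLogitMixed,
    B: int = 999,
    seed: int | None = None,
    full_result: BinomialMixedResults | None = None,
    null_result: BinomialMixedResults | None = None,
) -> BootstrapTest:
    """Parametric-bootstrap likelihood-ratio test of nested binomial GLMMs.

    Responses are simulated from the fitted null model (re-drawing the
    random effects); both models are refitted to each simulated response and
    the observed likelihood-ratio statistic is referred to the simulated
    distribution, with the Monte-Carlo estimator p = (1 + k) / (B + 1).
    """
    rng = np.random.default_rng(seed)
    # observed and replicate statistics use identical fit settings so that
    # numerical-tolerance effects cancel in the comparison
    if full_result is None:
        full_result = full_model.fit(polish=False, inner_tol=1e-10)
    if null_result is None:
        null_result = null_model.fit(polish=False, inner_tol=1e-10)
    lrt_obs = max(0.0, 2.0 * (full_result.llf - null_result.llf))

    null_stats = np.empty(B)
    n_failed = 0
    for b in range(B):
        y_star = null_model.simulate(null_result.params, null_result.vcomp, rng)
        try:
            r_null = null_model.clone_with(y_star).fit(
                start_theta=null_result.theta, polish=False, inner_tol=1e-10)
            r_full = full_model.clone_with(y_star).fit(
                start_theta=full_result.theta, polish=False, inner_tol=1e-10)
            if not (r_null.converged and r_full.converged):
                n_failed += 1
            null_stats[b] = max(0.0, 2.0 * (r_full.llf - r_null.llf))
        except Exception:
            n_failed += 1
            null_stats[b] = np.nan
    ok = np.isfinite(null_stats)
    k = int(np.sum(null_stats[ok] >= lrt_obs - 1e-12))
    b_eff = int(ok.sum())
    if n_failed > 0.05 * B:
        import warnings

        warnings.warn(f"bootstrap: {n_failed} of {B} replicates failed/flagged; "
                      f"effective B = {b_eff}")
    pvalue = (1.0 + k) / (b_eff + 1.0)
    return BootstrapTest(lrt_obs, pvalue, b_eff, n_failed, null_stats[ok])


# ---------------------------------------------------------------------------
# cumulative-residual linearity check
# ---------------------------------------------------------------------------


@dataclass
class LinearityCheck:
    statistic: float
    pvalue: float
    process: np.ndarray = field(repr=False)
    order: np.ndarray = field(repr=False)


def linearity_check(resid_pearson, order_by, B: int = 1000,
                    seed: int | None = None) -> LinearityCheck:
    """Cumulative-residual check of linearity in a predictor.

    The Pearson residuals of a fitted GLM are ordered by the predictor and
    cumulated; the statistic is the supremum of the absolute cumulative
    process scaled by sqrt(N).  Its null distribution is approximated by a
    wild bootstrap with Rademacher signs on the residuals (a simplification
    of the Lin–Wei–Ying resampling that conditions on the fitted model and
    targets the same calibration).  A systematically curved relationship
    leaves same-sign residual runs along the predictor axis and inflates
    the supremum.
    """
    rng = np.random.default_rng(seed)
    resid = np.asarray(resid_pearson, dtype=float)
    order = np.argsort(np.asarray(order_by), kind="stable")
    r = resid[order]
    n = r.size
    process = np.cumsum(r) / np.sqrt(n)
    statistic = float(np.max(np.abs(process))) if n else 0.0
    exceed = 0
    for _ in range(B):
        e = rng.choice([-1.0, 1.0], size=n)
        stat_b = np.max(np.abs(np.cumsum(e * r))) / np.sqrt(n)
        if stat_b >= statistic - 1e-12:
            exceed += 1
    pvalue = (1.0 + exceed) / (B + 1.0)
    if statistic == 0.0:
        pvalue = 1.0
    return LinearityCheck(statistic, pvalue, process, order)
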