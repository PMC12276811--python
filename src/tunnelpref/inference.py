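"""Beta-binomial mixed models for preference, recruitment and activation.

The response is a (successes, trials) pair per record: for preference,
frames a trajectory spent in the test volume out of all frames spent in
either volume (so the frame counts implement time weighting of
trajectories exactly); for recruitment, recruited trajectories out of
active trajectories per run x period; for activation, recorded
trajectories out of the number of mosquitos released.

Model: logit(mu) = X beta + u_cluster, with u ~ N(0, sigma^2) and
observations beta-binomial around mu with precision phi (alpha = mu*phi,
beta = (1-mu)*phi).  The intraclass correlation rho = 1/(1+phi) goes to 0
in the binomial limit; ``dispersion="binomial"`` fits that limit exactly.
Preference models use one random intercept per run x stimulus pair;
activation and recruitment models use a single intercept per run.  The
marginal likelihood integrates the random intercepts by adaptive
Gauss-Hermite quadrature (default 20 nodes; 1 node = Laplace).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "BetaBinomFit",
    "ContrastResult",
    "fit_betabinom_mixed",
    "likelihood_ratio_test",
    "estimate_group_means",
    "pairwise_contrasts",
    "linear_contrast",
    "sidak_adjust",
    "predict_run_effects",
]

_MU_EPS = 1e-10

RESPONSES = ("preference", "recruitment", "activation")

#: Default (successes, trials) column pairs per response.
RESPONSE_COLUMNS = {
    "preference": ("frames_test", "frames_total"),
    "recruitment": ("n_recruited", "n_trajectories"),
    "activation": ("n_trajectories", "n_released"),
}


class ModelError(ValueError):
    pass


class NotConvergedError(RuntimeError):
    """Raised when a downstream operation is asked to use a flagged fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Which response to model, with which fixed factors and random structure.

    ``fixed`` lists factor terms; an interaction is written "a:b".
    ``random`` is resolved per response when "auto": preference models get
    an intercept per run x stimulus pair, activation/recruitment a single
    intercept per run; "none" disables random effects.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: str = "auto"

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ModelError(f"response must be one of {RESPONSES}")
        object.__setattr__(self, "fixed", tuple(self.fixed))
        if self.random not in ("auto", "intercept_per_run",
                               "intercept_per_run_by_stimulus_pair", "none"):
            raise ModelError(f"unknown random structure {self.random!r}")

    @property
    def resolved_random(self) -> str:
        if self.random != "auto":
            return self.random
        if self.response == "preference":
            return "intercept_per_run_by_stimulus_pair"
        return "intercept_per_run"

    def cluster_columns(self, df: pd.DataFrame) -> list[str]:
        if self.resolved_random == "none":
            return []
        if self.resolved_random == "intercept_per_run":
            return ["run_id"]
        cols = ["run_id"]
        for c in ("test_channel", "control_channel", "intensity", "period_id"):
            if c in df.columns and c in ("test_channel", "control_channel", "intensity"):
                cols.append(c)
        return cols


class DesignInfo:
    """Treatment-coded design matrix for factorial fixed effects."""

    def __init__(self, df: pd.DataFrame, terms: Sequence[str]):
        self.terms = list(terms)
        self.levels: dict[str, list] = {}
        for term in self.terms:
            for f in term.split(":"):
                if f not in df.columns:
                    raise ModelError(f"factor {f!r} absent from records")
                if f not in self.levels:
                    self.levels[f] = list(pd.unique(df[f]))
        self.columns: list[str] = ["(Intercept)"]
        self._builders: list[tuple[str, tuple]] = [("intercept", ())]
        for term in self.terms:
            factors = term.split(":")
            from itertools import product
            for combo in product(*[self.levels[f][1:] for f in factors]):
                name = ":".join(f"{f}[{lv}]" for f, lv in zip(factors, combo))
                self.columns.append(name)
                self._builders.append(("dummy", tuple(zip(factors, combo))))

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        X = np.empty((n, self.n_columns))
        for j, (kind, key) in enumerate(self._builders):
            if kind == "intercept":
                X[:, j] = 1.0
            else:
                col = np.ones(n, dtype=bool)
                for f, lv in key:
                    col &= (df[f] == lv).to_numpy()
                X[:, j] = col.astype(float)
        return X

    def row_for(self, levels: dict) -> np.ndarray:
        """Design row for a fully specified cell of the factor space."""
        x = np.empty(self.n_columns)
        for j, (kind, key) in enumerate(self._builders):
            if kind == "intercept":
                x[j] = 1.0
            else:
                x[j] = float(all(levels[f] == lv for f, lv in key))
        return x


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _bb_loglik(y, n, mu, phi):
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        special.gammaln(phi) - special.gammaln(n + phi)
        + special.gammaln(y + a) - special.gammaln(a)
        + special.gammaln(n - y + b) - special.gammaln(b)
    )


def _bb_d1_d2(y, n, mu, phi):
    """First and second derivatives of the beta-binomial loglik w.r.t. eta."""
    a = mu * phi
    b = (1.0 - mu) * phi
    D = special.digamma(y + a) - special.digamma(a) \
        - special.digamma(n - y + b) + special.digamma(b)
    Dp = special.polygamma(1, y + a) - special.polygamma(1, a) \
        + special.polygamma(1, n - y + b) - special.polygamma(1, b)
    m = mu * (1.0 - mu)
    g1 = phi * D * m
    g2 = phi * phi * Dp * m * m + phi * D * m * (1.0 - 2.0 * mu)
    return g1, g2


def _binom_loglik(y, n, mu, phi=None):
    return y * np.log(mu) + (n - y) * np.log1p(-mu)


def _binom_d1_d2(y, n, mu, phi=None):
    return y - n * mu, -n * mu * (1.0 - mu)


class _MarginalLik:
    """Marginal negative log-likelihood with adaptive GH quadrature.

    Parameter vector: [beta..., log(phi) if estimated, log(sigma) if random].
    Cluster modes are Newton-refined (vectorized across clusters, warm
    started between evaluations).
    """

    def __init__(self, y, n, X, cluster_idx, n_clusters, nodes, dispersion):
        self.y = np.asarray(y, float)
        self.n = np.asarray(n, float)
        self.X = np.asarray(X, float)
        self.ci = cluster_idx
        self.J = n_clusters
        self.dispersion = dispersion
        if dispersion == "betabinom":
            self._ll, self._d12 = _bb_loglik, _bb_d1_d2
        else:
            self._ll, self._d12 = _binom_loglik, _binom_d1_d2
        z, w = hermgauss(max(1, int(nodes)))
        self.z, self.logw = z, np.log(w)
        self.p = self.X.shape[1]
        self.has_random = cluster_idx is not None
        self._u = np.zeros(self.J) if self.has_random else None
        # binomial normalizing constant (parameter-free)
        self.const = float(np.sum(
            special.gammaln(self.n + 1) - special.gammaln(self.y + 1)
            - special.gammaln(self.n - self.y + 1)
        ))

    def unpack(self, theta):
        beta = theta[: self.p]
        k = self.p
        if self.dispersion == "betabinom":
            phi = math.exp(theta[k]); k += 1
        else:
            phi = None
        sigma = math.exp(theta[k]) if self.has_random else 0.0
        return beta, phi, sigma

    def _mu(self, eta):
        return np.clip(special.expit(eta), _MU_EPS, 1.0 - _MU_EPS)

    def _modes(self, eta0, phi, sigma):
        """Newton-solve the per-cluster conditional modes; return (u, curvature)."""
        sig2 = sigma * sigma
        u = self._u.copy()
        H = np.full(self.J, -1.0 / max(sig2, 1e-300))
        for _ in range(200):
            eta = eta0 + u[self.ci]
            mu = self._mu(eta)
            g1, g2 = self._d12(self.y, self.n, mu, phi)
            G = np.bincount(self.ci, weights=g1, minlength=self.J) - u / sig2
            H = np.bincount(self.ci, weights=g2, minlength=self.J) - 1.0 / sig2
            H = np.minimum(H, -1e-12)
            step = G / H
            np.clip(step, -4.0, 4.0, out=step)
            u -= step
            if np.max(np.abs(G)) < 1e-10:
                break
        self._u = u.copy()
        return u, H

    def nll(self, theta):
        beta, phi, sigma = self.unpack(theta)
        eta0 = self.X @ beta
        if not self.has_random:
            ll = float(np.sum(self._ll(self.y, self.n, self._mu(eta0), phi)))
            return -(ll + self.const)
        sig2 = sigma * sigma
        u_hat, H = self._modes(eta0, phi, sigma)
        s = 1.0 / np.sqrt(-H)
        # u_{jk} = u_hat_j + sqrt(2) s_j z_k
        u_nodes = u_hat[:, None] + math.sqrt(2.0) * s[:, None] * self.z[None, :]
        eta = eta0[:, None] + u_nodes[self.ci, :]
        llm = self._ll(self.y[:, None], self.n[:, None], self._mu(eta), phi)
        F = np.zeros((self.J, len(self.z)))
        np.add.at(F, self.ci, llm)
        F -= u_nodes * u_nodes / (2.0 * sig2)
        logI = (
            np.log(math.sqrt(2.0) * s)
            - 0.5 * math.log(2.0 * math.pi * sig2)
            + special.logsumexp(self.logw[None, :] + self.z[None, :] ** 2 + F, axis=1)
        )
        return -(float(np.sum(logI)) + self.const)

    def grad_fixed(self, theta):
        """Analytic gradient, only valid without random effects."""
        beta, phi, sigma = self.unpack(theta)
        eta = self.X @ beta
        mu = self._mu(eta)
        g1, _ = self._d12(self.y, self.n, mu, phi)
        g = [-(self.X.T @ g1)]
        if self.dispersion == "betabinom":
            a = mu * phi
            b = (1.0 - mu) * phi
            dphi = (
                special.digamma(phi) - special.digamma(self.n + phi)
                + mu * (special.digamma(self.y + a) - special.digamma(a))
                + (1.0 - mu) * (special.digamma(self.n - self.y + b) - special.digamma(b))
            )
            g.append([-phi * float(np.sum(dphi))])
        return np.concatenate([np.atleast_1d(v) for v in g])


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class BetaBinomFit:
    """A fitted beta-binomial (or binomial-limit) mixed model."""

    spec: ModelSpec
    coef: np.ndarray
    coef_names: list[str]
    phi: float  # np.inf in the binomial limit
    sigma2_run: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    quadrature_nodes: int
    dispersion: str
    design: DesignInfo = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    cluster_labels: list = field(repr=False, default_factory=list)
    cluster_cols: list = field(repr=False, default_factory=list)
    u_hat: np.ndarray | None = field(repr=False, default=None)
    theta_hat: np.ndarray = field(repr=False, default=None)
    _lik: _MarginalLik = field(repr=False, default=None)

    @property
    def rho(self) -> float:
        """Intraclass correlation 1/(1+phi); 0 in the binomial limit."""
        return 0.0 if math.isinf(self.phi) else 1.0 / (1.0 + self.phi)

    def require_converged(self) -> None:
        if not self.converged:
            raise NotConvergedError(
                "fit did not converge; refusing downstream inference"
            )

    @cached_property
    def cov_params(self) -> np.ndarray:
        """Covariance of [beta, log phi, log sigma] via numeric Hessian."""
        theta = self.theta_hat
        f = self._lik.nll
        k = len(theta)
        h = 1e-4 * (1.0 + np.abs(theta))
        H = np.empty((k, k))
        f0 = f(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / (h[i] ** 2)
                else:
                    H[i, j] = H[j, i] = (
                        f(theta + ei + ej) - f(theta + ei - ej)
                        - f(theta - ei + ej) + f(theta - ei - ej)
                    ) / (4.0 * h[i] * h[j])
        cov = np.linalg.pinv(H)
        return cov

    @property
    def cov_coef(self) -> np.ndarray:
        p = len(self.coef)
        return self.cov_params[:p, :p]

    def bse(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _prepare(records: pd.DataFrame, spec: ModelSpec,
             successes: str | None, trials: str | None):
    sc, tc = RESPONSE_COLUMNS[spec.response]
    sc = successes or (sc if sc in records.columns else "successes")
    tc = trials or (tc if tc in records.columns else "trials")
    for c in (sc, tc):
        if c not in records.columns:
            raise ModelError(f"records lack response column {c!r}")
    df = records.loc[records[tc] > 0].reset_index(drop=True)
    if df.empty:
        raise ModelError("all records have zero trials; nothing to fit")
    y = df[sc].to_numpy(float)
    n = df[tc].to_numpy(float)
    if np.any(y < 0) or np.any(y > n):
        raise ModelError("successes must lie in [0, trials]")
    return df, y, n


def _irls_start(y, n, X):
    """Binomial IRLS starting values for beta (cluster structure ignored)."""
    p = X.shape[1]
    pbar = (y.sum() + 0.5) / (n.sum() + 1.0)
    beta = np.zeros(p)
    beta[0] = special.logit(pbar)
    for _ in range(8):
        mu = np.clip(special.expit(X @ beta), 1e-8, 1 - 1e-8)
        W = n * mu * (1 - mu)
        A = X.T @ (X * W[:, None]) + 1e-8 * np.eye(p)
        beta = beta + np.linalg.solve(A, X.T @ (y - n * mu))
    return beta


def fit_betabinom_mixed(
    records: pd.DataFrame,
    spec: ModelSpec,
    quadrature_nodes: int = 20,
    dispersion: str = "betabinom",
    successes: str | None = None,
    trials: str | None = None,
    seed: int | None = None,
) -> BetaBinomFit:
    """Fit the mixed beta-binomial model by maximum marginal likelihood.

    Records with zero trials are dropped (they carry no information).
    ``dispersion="binomial"`` pins the overdispersion to the binomial limit;
    ``quadrature_nodes=1`` is the Laplace approximation.  ``seed`` is
    accepted for interface symmetry; the optimizer itself is deterministic.
    """
    del seed
    if dispersion not in ("betabinom", "binomial"):
        raise ModelError("dispersion must be 'betabinom' or 'binomial'")
    df, y, n = _prepare(records, spec, successes, trials)
    design = DesignInfo(df, spec.fixed)
    X = design.matrix(df)

    cluster_cols = spec.cluster_columns(df)
    if cluster_cols:
        keys = list(map(tuple, df[cluster_cols].itertuples(index=False, name=None)))
        labels = list(dict.fromkeys(keys))
        index = {k: i for i, k in enumerate(labels)}
        ci = np.fromiter((index[k] for k in keys), dtype=np.int64, count=len(keys))
        J = len(labels)
    else:
        ci, labels, J = None, [], 0

    lik = _MarginalLik(y, n, X, ci, J, quadrature_nodes, dispersion)

    beta0 = _irls_start(y, n, X)
    theta0 = list(beta0)
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * len(beta0)
    if dispersion == "betabinom":
        theta0.append(math.log(10.0))
        bounds.append((-4.0, 15.0))
    if ci is not None:
        theta0.append(math.log(0.3))
        bounds.append((-8.0, 3.0))
    theta0 = np.asarray(theta0)

    jac = lik.grad_fixed if ci is None else None
    res = optimize.minimize(
        lik.nll, theta0, method="L-BFGS-B", jac=jac, bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-8},
    )
    beta_hat, phi_hat, sigma_hat = lik.unpack(res.x)
    # refresh cached cluster modes at the optimum for EB prediction
    if ci is not None:
        lik.nll(res.x)
        u_hat = lik._u.copy()
    else:
        u_hat = None
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else 0.0
    converged = bool(res.success or grad_norm < 1e-3)
    # effective parameter count uses the design rank so that empty factor
    # cells (all-zero columns) do not inflate likelihood-ratio df
    rank = int(np.linalg.matrix_rank(X))
    n_params = rank + (len(res.x) - X.shape[1])
    return BetaBinomFit(
        spec=spec,
        coef=np.asarray(beta_hat, float),
        coef_names=list(design.columns),
        phi=(phi_hat if phi_hat is not None else math.inf),
        sigma2_run=float(sigma_hat ** 2) if ci is not None else 0.0,
        loglik=-float(res.fun),
        n_obs=len(df),
        n_params=n_params,
        converged=converged,
        quadrature_nodes=quadrature_nodes,
        dispersion=dispersion,
        design=design,
        data=df,
        cluster_labels=labels,
        cluster_cols=cluster_cols,
        u_hat=u_hat,
        theta_hat=np.asarray(res.x, float),
        _lik=lik,
    )


# ---------------------------------------------------------------------------
# Inference on fits
# ---------------------------------------------------------------------------

def likelihood_ratio_test(full: BetaBinomFit, reduced: BetaBinomFit):
    """Likelihood-ratio chi-square for nested fits on the same data.

    Returns ``(chi2, df, p)`` with ``chi2 = 2 * (ll_full - ll_reduced)``.
    """
    if full.spec.response != reduced.spec.response:
        raise ModelError("fits model different responses")
    if not set(reduced.spec.fixed) <= set(full.spec.fixed):
        raise ModelError("reduced model terms are not a subset of the full model")
    if full.n_obs != reduced.n_obs:
        raise ModelError("fits use different data")
    if (full.dispersion != reduced.dispersion
            or full.spec.resolved_random != reduced.spec.resolved_random):
        raise ModelError("fits differ in dispersion/random structure; not nested")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ModelError("full model has fewer parameters than reduced")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0 and chi2 < 1e-8:
        p = 1.0
    return chi2, df, p


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak family-wise adjustment: ``p_adj = 1 - (1 - p)^m``, clipped to [0,1]."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    with np.errstate(divide="ignore"):
        adj = -np.expm1(m * np.log1p(-p))
    return np.clip(adj, 0.0, 1.0)


def _group_rows(fit: BetaBinomFit, grouping: Sequence[str]):
    """Averaged design rows per cell of ``grouping`` (proportional weighting)."""
    grouping = [grouping] if isinstance(grouping, str) else list(grouping)
    for g in grouping:
        if g not in fit.data.columns:
            raise ModelError(f"grouping factor {g!r} absent from the fit's data")
    X = fit.design.matrix(fit.data)
    cells: dict[tuple, np.ndarray] = {}
    for key, idx in fit.data.groupby(grouping, sort=False).indices.items():
        key = key if isinstance(key, tuple) else (key,)
        cells[key] = X[idx].mean(axis=0)
    return grouping, cells


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adjusted: float
    adjustment: str


def estimate_group_means(
    fit: BetaBinomFit,
    grouping: Sequence[str] | str,
    level: float = 0.95,
) -> pd.DataFrame:
    """Response-scale estimated marginal means with delta-method CIs.

    Cells of the grouping are averaged over the remaining factors with
    proportional (observed-frequency) weighting.  For preference models the
    proportion p is rescaled to the preference index pi = 2p - 1; CI
    endpoints transform monotonically.
    """
    fit.require_converged()
    grouping, cells = _group_rows(fit, grouping)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    covb = fit.cov_coef
    rows = []
    for key, xbar in cells.items():
        est = float(xbar @ fit.coef)
        se = float(np.sqrt(max(xbar @ covb @ xbar, 0.0)))
        lo, hi = est - zcrit * se, est + zcrit * se
        p, plo, phi_ = special.expit([est, lo, hi])
        row = dict(zip(grouping, key))
        row.update(logit_mean=est, logit_se=se, prop=p, prop_lo=plo, prop_hi=phi_)
        if fit.spec.response == "preference":
            row.update(pi=2 * p - 1, pi_lo=2 * plo - 1, pi_hi=2 * phi_ - 1)
        rows.append(row)
    return pd.DataFrame(rows)


def linear_contrast(
    fit: BetaBinomFit,
    row_a: np.ndarray,
    row_b: np.ndarray,
    label: str = "a-b",
) -> ContrastResult:
    """z-test of a logit-scale difference between two averaged design rows."""
    fit.require_converged()
    d = np.asarray(row_a, float) - np.asarray(row_b, float)
    est = float(d @ fit.coef)
    se = float(np.sqrt(max(d @ fit.cov_coef @ d, 0.0)))
    z = est / se if se > 0 else math.inf * np.sign(est) if est else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ContrastResult(label, est, se, z, p, p, "none")


def pairwise_contrasts(
    fit: BetaBinomFit,
    grouping: Sequence[str] | str,
    pairs: Sequence[tuple] | None = None,
    adjust: str = "sidak",
) -> pd.DataFrame:
    """Logit-scale contrasts between grouping cells.

    The Sidak family is exactly the set of contrasts requested in this
    call; ``adjust="none"`` serves a priori contrasts, which bypass
    adjustment.
    """
    fit.require_converged()
    grouping, cells = _group_rows(fit, grouping)
    keys = list(cells)
    if pairs is None:
        pairs = [(keys[i], keys[j]) for i in range(len(keys))
                 for j in range(i + 1, len(keys))]
    results = []
    for a, b in pairs:
        a = a if isinstance(a, tuple) else (a,)
        b = b if isinstance(b, tuple) else (b,)
        if a not in cells or b not in cells:
            raise ModelError(f"contrast cell {a or b} not present in the data")
        c = linear_contrast(fit, cells[a], cells[b], label=f"{a} - {b}")
        results.append(c)
    p_raw = np.array([c.p_raw for c in results])
    p_adj = sidak_adjust(p_raw, m=len(results)) if adjust == "sidak" else p_raw
    out = pd.DataFrame(
        {
            "contrast": [c.label for c in results],
            "estimate": [c.estimate for c in results],
            "se": [c.se for c in results],
            "z": [c.z for c in results],
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "adjustment": adjust,
        }
    )
    return out


def predict_run_effects(fit: BetaBinomFit) -> pd.DataFrame:
    """Per-run empirical-Bayes predictions on the response scale.

    Combines the conditional modes of the run intercepts with the fixed
    effects: one prediction per cluster (run, or run x stimulus pair) and
    distinct fixed-effect cell observed within it.  With sigma^2 -> 0 the
    modes shrink to zero and every prediction equals its group mean.
    """
    fit.require_converged()
    if fit.u_hat is None:
        raise ModelError("fit has no random effects; nothing to predict")
    df = fit.data
    X = fit.design.matrix(df)
    keys = list(map(tuple, df[fit.cluster_cols].itertuples(index=False, name=None)))
    index = {k: i for i, k in enumerate(fit.cluster_labels)}
    factors = sorted({f for t in fit.spec.fixed for f in t.split(":")})
    rows = []
    seen = set()
    for i in range(len(df)):
        j = index[keys[i]]
        cell = tuple(df.iloc[i][f] for f in factors)
        sig = (j, cell)
        if sig in seen:
            continue
        seen.add(sig)
        eta = float(X[i] @ fit.coef + fit.u_hat[j])
        p = float(special.expit(eta))
        row = dict(zip(fit.cluster_cols, keys[i]))
        row.update(dict(zip(factors, cell)))
        row.update(u=float(fit.u_hat[j]), eta=eta, prop=p)
        if fit.spec.response == "preference":
            row["pi"] = 2 * p - 1
        rows.append(row)
    return pd.DataFrame(rows)
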