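"""Four-parameter log-logistic intensity-preference curves and potency comparison.

Estimation is two-stage, mirroring the upstream pipeline: stage 1 produces
run-level preference predictions from the mixed beta-binomial models; stage
2 fits the sigmoid ``f(x) = c + (d - c) / (1 + exp(b (ln x - ln e)))`` to
those predictions against relative intensity x.  Intensity is measured
relative to the unilluminated black tulle target, which reflects ambient
light, so x is strictly positive.  The lower and upper asymptotes (c, d)
are estimated once from the gray intensity ramp — the series with the
widest relative-intensity range — and held fixed for every wavelength x
odor group; only the steepness b and the inflection intensity e are free.
Curves are compared by relative potency, the ratio of inflection
intensities e1/e2, with a delta-method z-test on the log ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LL4Params",
    "LL4Fit",
    "PotencyComparison",
    "ll4",
    "fit_asymptotes_from_gray",
    "fit_ll4_fixed_cd",
    "compare_potency",
]


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class LL4Params:
    """b: steepness at inflection; c/d: lower/upper asymptotes (preference
    index scale); e: relative intensity at the inflection point."""

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("inflection intensity e must be > 0")
        if self.c > self.d:
            raise ValueError("lower asymptote c must be <= upper asymptote d")


@dataclass
class LL4Fit:
    params: LL4Params
    fixed: tuple[str, ...]  # which of b,c,d,e were held fixed
    cov: np.ndarray  # covariance of the free parameters, in `free` order
    free: tuple[str, ...]
    residual_scale: float
    n_obs: int
    converged: bool
    group: str = ""
    flags: list = field(default_factory=list)
    run_effects: pd.DataFrame | None = None  # per-run (b, e) deviations

    def se(self, name: str) -> float:
        i = self.free.index(name)
        return float(np.sqrt(max(self.cov[i, i], 0.0)))


@dataclass(frozen=True)
class PotencyComparison:
    """Relative potency e1/e2 with a z-test on the log ratio."""

    ratio: float
    se_log_ratio: float
    z: float
    p: float


def ll4(x, params: LL4Params) -> np.ndarray | float:
    """Evaluate the four-parameter log-logistic at relative intensity x > 0.

    At ``x = e`` the value is exactly ``(c + d) / 2``, midway between the
    asymptotes; for b > 0 the curve falls from d (x -> 0) to c (x -> inf).
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0):
        raise ValueError("relative intensity x must be > 0")
    val = params.c + (params.d - params.c) / (
        1.0 + np.exp(np.clip(params.b * (np.log(xa) - math.log(params.e)),
                             -700.0, 700.0))
    )
    return float(val) if np.isscalar(x) else val


def _ll4_raw(x, b, c, d, e):
    z = np.clip(b * (np.log(x) - np.log(e)), -700.0, 700.0)
    return c + (d - c) / (1.0 + np.exp(z))


def _nls(x, y, p0, free_bce, c=None, d=None):
    """Least-squares over the free parameters; returns (params, cov, sse, ok)."""

    def unpack(theta):
        i = 0
        vals = {}
        for name in free_bce:
            vals[name] = theta[i]
            i += 1
        vals.setdefault("c", c)
        vals.setdefault("d", d)
        # e optimized on log scale for positivity
        return vals["b"], vals["c"], vals["d"], math.exp(vals["log_e"])

    def resid(theta):
        b_, c_, d_, e_ = unpack(theta)
        return _ll4_raw(x, b_, c_, d_, e_) - y

    res = optimize.least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14,
                                 max_nfev=5000)
    b_, c_, d_, e_ = unpack(res.x)
    sse = float(2.0 * res.cost)
    dof = max(len(x) - len(res.x), 1)
    s2 = sse / dof
    JtJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)
    return (b_, c_, d_, e_), cov, sse, res.status > 0


def _start_grid(x, y, n_b=5, n_e=5):
    """Multistart (b, log e) grid: b log-spaced both signs, e at x quantiles."""
    es = np.quantile(x, np.linspace(0.1, 0.9, n_e))
    bs = [-4.0, -1.0, 0.5, 2.0, 6.0][:n_b]
    return [(b, math.log(max(e, 1e-6))) for b, e in product(bs, es)]


def fit_asymptotes_from_gray(
    x: Sequence[float],
    y: Sequence[float],
    min_span: float = 4.0,
) -> LL4Fit:
    """Full 4-parameter fit to the gray-ramp predictions; (c, d) to be frozen.

    ``x`` are relative intensities (against the black tulle target), ``y``
    run-level preference predictions.  Errors out when the intensity range
    is too narrow (max/min < ``min_span``) to pin both asymptotes.
    Constant y yields a degenerate fit flagged ``c == d``.  When ``run_id``
    is given, (b, log e) covariance is cluster-robust by run.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0):
        raise ValueError("relative intensities must be > 0")
    if x.max() / x.min() < min_span:
        raise FitError(
            f"gray-ramp intensity span {x.max() / x.min():.2f} < {min_span}: "
            "too narrow to pin both asymptotes; widen the ramp"
        )
    flags = []
    if np.ptp(y) < 1e-12:
        yc = float(y[0])
        params = LL4Params(b=0.0, c=yc, d=yc, e=float(np.median(x)))
        flags.append("degenerate: constant response, c == d")
        return LL4Fit(params, fixed=(), cov=np.zeros((4, 4)),
                      free=("b", "c", "d", "log_e"), residual_scale=0.0,
                      n_obs=len(x), converged=True, group="gray",
                      flags=flags)
    best = None
    for b0, loge0 in _start_grid(x, y):
        p0 = [b0, float(y.min()), float(y.max()), loge0]
        try:
            fitted, cov, sse, ok = _nls(x, y, p0, ("b", "c", "d", "log_e"))
        except Exception:
            continue
        if ok and (best is None or sse < best[2] - 1e-10):
            best = (fitted, cov, sse)
    if best is None:
        raise FitError("gray-ramp asymptote fit failed from every start value")
    (b_, c_, d_, e_), cov, sse = best
    if c_ > d_:  # orient so c is the lower asymptote (flip sign of b)
        c_, d_, b_ = d_, c_, -b_
    params = LL4Params(b=b_, c=c_, d=d_, e=e_)
    return LL4Fit(
        params, fixed=(), cov=cov, free=("b", "c", "d", "log_e"),
        residual_scale=math.sqrt(sse / max(len(x) - 4, 1)),
        n_obs=len(x), converged=True, group="gray", flags=flags,
    )


def fit_ll4_fixed_cd(
    x: Sequence[float],
    y: Sequence[float],
    c: float,
    d: float,
    run_id: Sequence | None = None,
    group: str = "",
    per_run: bool = False,
) -> LL4Fit:
    """Fit (b, e) with the asymptotes (c, d) frozen from the gray ramp.

    With ``per_run=True`` and run ids supplied, per-run (b, e) fits are
    pooled by precision weighting as a two-stage approximation to a mixed
    sigmoid; per-run deviations are reported in ``run_effects``.
    Requires at least 4 distinct intensities; a near-flat fitted slope
    leaves e unidentifiable and flags the fit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0):
        raise ValueError("relative intensities must be > 0")
    if len(np.unique(x)) < 4:
        raise FitError("need >= 4 distinct intensities to fit (b, e)")
    best = None
    for b0, loge0 in _start_grid(x, y):
        try:
            fitted, cov, sse, ok = _nls(x, y, [b0, loge0], ("b", "log_e"), c=c, d=d)
        except Exception:
            continue
        if ok and (best is None or sse < best[2] - 1e-10):
            best = (fitted, cov, sse)
    if best is None:
        raise FitError(f"LL4 fit failed for group {group!r} from every start value")
    (b_, _, _, e_), cov, sse = best
    flags = []
    converged = True
    if abs(b_) < 1e-3:
        flags.append("flat response: b ~ 0, inflection e unidentifiable")
        converged = False
    if run_id is not None:
        # run-level predictions are correlated within a run: sandwich
        # covariance clustered by run replaces the iid least-squares one
        cov = _cluster_robust_cov(x, y, np.asarray(run_id), b_, c, d, e_)
    params = LL4Params(b=b_, c=min(c, d), d=max(c, d), e=e_)
    fit = LL4Fit(
        params, fixed=("c", "d"), cov=cov, free=("b", "log_e"),
        residual_scale=math.sqrt(sse / max(len(x) - 2, 1)),
        n_obs=len(x), converged=converged, group=group, flags=flags,
    )
    if per_run and run_id is not None:
        fit.run_effects = _per_run_effects(x, y, np.asarray(run_id), c, d, b_, e_)
    return fit


def _cluster_robust_cov(x, y, run_id, b, c, d, e):
    """Sandwich covariance of (b, log e) with residuals clustered by run."""
    z = np.clip(b * (np.log(x) - math.log(e)), -700.0, 700.0)
    s = 1.0 / (1.0 + np.exp(z))          # fitted = c + (d - c) * s
    ds = s * (1.0 - s)
    J = np.column_stack([
        -(d - c) * ds * (np.log(x) - math.log(e)),  # d f / d b
        (d - c) * ds * b,                            # d f / d log e
    ])
    r = y - (c + (d - c) * s)
    A = J.T @ J
    B = np.zeros((2, 2))
    for rid in pd.unique(run_id):
        m = run_id == rid
        g = J[m].T @ r[m]
        B += np.outer(g, g)
    n_g = len(pd.unique(run_id))
    B *= n_g / max(n_g - 1, 1)  # small-sample cluster correction
    Ainv = np.linalg.pinv(A)
    return Ainv @ B @ Ainv


def _per_run_effects(x, y, run_id, c, d, b_pop, e_pop):
    """Two-stage per-run (b, e): individual fits pooled toward the population."""
    rows = []
    for rid in pd.unique(run_id):
        m = run_id == rid
        if len(np.unique(x[m])) < 4:
            rows.append({"run_id": rid, "b": np.nan, "e": np.nan,
                         "db": np.nan, "dloge": np.nan, "pooled": False})
            continue
        try:
            (b_r, _, _, e_r), cov_r, _, ok = _nls(
                x[m], y[m], [b_pop, math.log(e_pop)], ("b", "log_e"), c=c, d=d
            )
        except Exception:
            ok = False
        if not ok:
            rows.append({"run_id": rid, "b": np.nan, "e": np.nan,
                         "db": np.nan, "dloge": np.nan, "pooled": False})
            continue
        # precision-weighted shrinkage of the per-run estimate to the pool
        var_b = max(cov_r[0, 0], 1e-12)
        var_le = max(cov_r[1, 1], 1e-12)
        w_b = 1.0 / (1.0 + var_b)
        w_le = 1.0 / (1.0 + var_le)
        b_shr = b_pop + w_b * (b_r - b_pop)
        loge_shr = math.log(e_pop) + w_le * (math.log(e_r) - math.log(e_pop))
        rows.append({
            "run_id": rid, "b": b_shr, "e": math.exp(loge_shr),
            "db": b_shr - b_pop, "dloge": loge_shr - math.log(e_pop),
            "pooled": True,
        })
    return pd.DataFrame(rows)


def compare_potency(fit1: LL4Fit, fit2: LL4Fit) -> PotencyComparison:
    """Relative potency at the inflection point: z-test on log(e1) - log(e2).

    Both fits must share the frozen asymptotes and be converged.  SEs of
    log e come from each fit's covariance (e is profiled on the log scale).
    """
    for f in (fit1, fit2):
        if not f.converged:
            raise FitError(f"fit for group {f.group!r} is flagged; refusing comparison")
        if "log_e" not in f.free:
            raise FitError("fit does not expose a free inflection parameter")
    if not np.allclose(
        [fit1.params.c, fit1.params.d], [fit2.params.c, fit2.params.d], atol=1e-9
    ):
        raise FitError("fits do not share frozen asymptotes (c, d)")
    le1, le2 = math.log(fit1.params.e), math.log(fit2.params.e)
    v1 = fit1.cov[fit1.free.index("log_e"), fit1.free.index("log_e")]
    v2 = fit2.cov[fit2.free.index("log_e"), fit2.free.index("log_e")]
    se = math.sqrt(max(v1 + v2, 0.0))
    diff = le1 - le2
    if se == 0.0:
        z = 0.0 if abs(diff) < 1e-12 else math.copysign(math.inf, diff)
    else:
        z = diff / se
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(abs(z)))
    return PotencyComparison(ratio=math.exp(diff), se_log_ratio=se, z=z, p=p)
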