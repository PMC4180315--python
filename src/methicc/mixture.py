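"""Two-component mixture models for the ICC distribution.

Probe-level ICC values live in [0, 1] with a point mass at 0 produced by
negative-estimate truncation.  Two models accommodate the boundary:

* **Censored normal mixture** — every probe comes from one of two normal
  components (low / high reliability); an observation at 0 is a censored draw
  (true value <= 0).  The likelihood contribution of component k is
  Phi(-mu_k/sigma_k) for a censored point and the normal density otherwise.
  Both components are censored at 0, giving a single coherent likelihood
  (the high component's sub-zero mass is negligible at fitted scales).

* **Truncated normal mixture** — probes at exactly 0 form their own cluster
  with sample proportion p0; non-zero ICCs follow a mixture of a normal
  truncated below at 0 (low reliability) and a plain normal (high
  reliability).  For model comparison the log likelihood is extended to the
  full data:  n0*log(p0) + sum log[p1*f_TN(x) + p2*phi_2(x)]  with
  p1 = p*(1-p0), p2 = (1-p)*(1-p0).

Throughout, ``p`` is the mixing proportion of the FIRST (low-reliability)
component among modeled observations.  Published tables sometimes caption the
same number as the high-reliability proportion; reports emit both readings.

Both models are fitted by EM.  The censored M-step replaces censored points by
the conditional moments of a normal truncated above 0 (inverse-Mills-ratio
corrections); the truncated component's M-step solves its weighted likelihood
equations numerically (an ECM step, accepted only when it improves the
objective, preserving EM ascent).  The likelihood equations here are
reconstructed from the model definitions; the source formulas they mirror
were not machine-readable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "MixtureFit",
    "censored_mixture_loglik",
    "fit_censored_mixture",
    "truncated_mixture_loglik",
    "fit_truncated_mixture",
    "posterior_high",
    "icc_threshold_for_posterior",
    "classify_sites",
    "compare_models",
]

_MIN_SIGMA = 1e-4
_MIN_N = 100


@dataclass
class MixtureFit:
    """Fitted two-component mixture for the ICC distribution.

    ``p`` is the component-1 (low-reliability) mixing proportion among the
    modeled observations; ``p0`` (truncated model) is the sample proportion of
    exact zeros, so the unconditional cluster weights are p0, p1 = p(1-p0),
    p2 = (1-p)(1-p0).  ``loglik`` is the maximized log likelihood on the full
    data, zeros included, for both models.
    """

    model_kind: str  # "censored" | "truncated"
    p: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    p0: float = 0.0
    n_obs: int = 0
    degenerate: bool = False
    loglik_trace: list = field(default_factory=list, repr=False)

    @property
    def p1(self) -> float:
        return self.p * (1.0 - self.p0)

    @property
    def p2(self) -> float:
        return (1.0 - self.p) * (1.0 - self.p0)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d.pop("loglik_trace", None)
        d["p_high_reading"] = 1.0 - self.p  # the alternative caption convention
        return json.dumps(d, indent=2, default=float)

    def validate(self) -> None:
        if not 0.0 <= self.p <= 1.0 or not 0.0 <= self.p0 <= 1.0:
            raise ValueError("mixing proportions must be in [0, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component scales must be positive")


# ---------------------------------------------------------------------------
# censored normal mixture
# ---------------------------------------------------------------------------


def _censored_component_logdens(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """log c_k(x): normal log-density for x > 0, log Phi(-mu/sigma) at x = 0."""
    out = stats.norm.logpdf(x, mu, sigma)
    at_zero = x == 0.0
    if np.any(at_zero):
        out = np.where(at_zero, stats.norm.logcdf(0.0, mu, sigma), out)
    return out


def censored_mixture_loglik(fit: MixtureFit, iccs: np.ndarray) -> float:
    """Log likelihood of the censored normal mixture on the full data."""
    fit.validate()
    x = np.asarray(iccs, dtype=float)
    l1 = _censored_component_logdens(x, fit.mu1, fit.sigma1)
    l2 = _censored_component_logdens(x, fit.mu2, fit.sigma2)
    with np.errstate(divide="ignore"):
        terms = logsumexp(
            np.stack([l1 + math.log(fit.p) if fit.p > 0 else l1 - np.inf,
                      l2 + math.log(1 - fit.p) if fit.p < 1 else l2 - np.inf]),
            axis=0,
        )
    return float(terms.sum())


def _upper_trunc_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and variance of N(mu, sigma^2) truncated above at 0."""
    alpha = (0.0 - mu) / sigma
    # lambda = phi(alpha)/Phi(alpha), computed in log space for stability
    lam = math.exp(stats.norm.logpdf(alpha) - stats.norm.logcdf(alpha))
    mean = mu - sigma * lam
    var = sigma**2 * (1.0 - lam * (lam + alpha))
    return mean, max(var, 0.0)


def _percentile_init(nonzero: np.ndarray, rng: np.random.Generator | None = None) -> tuple[float, ...]:
    q25, q75 = np.percentile(nonzero, [25, 75])
    s = max((q75 - q25) / 2.0, 0.02)
    init = [0.5, q25, s, q75, s]
    if rng is not None:
        init = [
            min(max(0.5 + rng.normal(0, 0.1), 0.05), 0.95),
            q25 + rng.normal(0, s / 2),
            s * math.exp(rng.normal(0, 0.3)),
            q75 + rng.normal(0, s / 2),
            s * math.exp(rng.normal(0, 0.3)),
        ]
    return tuple(init)


def fit_censored_mixture(
    iccs: np.ndarray,
    init: tuple[float, float, float, float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 5,
    seed: int = 0,
    min_n: int = _MIN_N,
) -> MixtureFit:
    """EM fit of the censored normal mixture to ICC values in [0, 1].

    ``init`` is (p, mu1, sigma1, mu2, sigma2); by default component means
    start at the 25th/75th percentiles of the non-zero values with
    ``n_restarts`` jittered restarts, keeping the best log likelihood.
    """
    x = np.asarray(iccs, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("ICC values must lie in [0, 1]")
    nonzero = x[x > 0]
    if nonzero.size < 2:
        raise ValueError("censored fit requires at least 2 non-zero observations")

    rng = np.random.default_rng(seed)
    inits = [init or _percentile_init(nonzero)]
    inits += [_percentile_init(nonzero, rng) for _ in range(n_restarts)]

    best: MixtureFit | None = None
    errors = []
    for start in inits:
        try:
            fit = _em_censored(x, start, tol, max_iter)
        except RuntimeError as exc:  # component collapse
            errors.append(exc)
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise RuntimeError(f"all EM starts collapsed: {errors[-1]}")
    return best


def _em_censored(
    x: np.ndarray, start: tuple[float, ...], tol: float, max_iter: int
) -> MixtureFit:
    p, mu1, s1, mu2, s2 = start
    at_zero = x == 0.0
    ll_old = -np.inf
    n_iter = 0
    converged = False
    trace: list[float] = []
    for n_iter in range(1, max_iter + 1):
        # E-step
        l1 = _censored_component_logdens(x, mu1, s1) + math.log(max(p, 1e-300))
        l2 = _censored_component_logdens(x, mu2, s2) + math.log(max(1 - p, 1e-300))
        denom = np.logaddexp(l1, l2)
        r1 = np.exp(l1 - denom)
        r2 = 1.0 - r1
        ll = float(denom.sum())
        trace.append(ll)

        # M-step: censored points contribute conditional truncated moments
        xt1 = x.copy()
        xt2 = x.copy()
        v1 = np.zeros_like(x)
        v2 = np.zeros_like(x)
        if at_zero.any():
            m1, var1 = _upper_trunc_moments(mu1, s1)
            m2, var2 = _upper_trunc_moments(mu2, s2)
            xt1[at_zero] = m1
            xt2[at_zero] = m2
            v1[at_zero] = var1
            v2[at_zero] = var2

        w1 = r1.sum()
        w2 = r2.sum()
        p = w1 / x.size
        mu1 = float((r1 * xt1).sum() / w1)
        mu2 = float((r2 * xt2).sum() / w2)
        s1 = math.sqrt(float((r1 * ((xt1 - mu1) ** 2 + v1)).sum() / w1))
        s2 = math.sqrt(float((r2 * ((xt2 - mu2) ** 2 + v2)).sum() / w2))
        if s1 < _MIN_SIGMA or s2 < _MIN_SIGMA:
            raise RuntimeError("component collapse (sigma -> 0)")

        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll

    fit = MixtureFit(
        model_kind="censored",
        p=float(p),
        mu1=mu1,
        sigma1=s1,
        mu2=mu2,
        sigma2=s2,
        loglik=0.0,
        n_iter=n_iter,
        converged=converged,
        p0=0.0,
        n_obs=int(x.size),
        loglik_trace=trace,
    )
    fit.loglik = censored_mixture_loglik(fit, x)
    return fit


# ---------------------------------------------------------------------------
# truncated normal mixture
# ---------------------------------------------------------------------------


def _log_truncnorm_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Density of N(mu, sigma^2) truncated below at 0, in log space."""
    lognorm = stats.norm.logpdf(x, mu, sigma)
    logmass = stats.norm.logsf(0.0, mu, sigma)  # 1 - Phi(-mu/sigma)
    return lognorm - logmass


def truncated_mixture_loglik(fit: MixtureFit, nonzero_iccs: np.ndarray, n0: int) -> float:
    """Revised full-data log likelihood of the truncated model.

    n0*log(p0) + sum over non-zero x of log[p1 f_TN(x) + p2 phi_2(x)], with p0
    the zero proportion carried by the fit.  When n0 = 0 the zero term is
    omitted (0 * log 0 := 0).
    """
    fit.validate()
    x = np.asarray(nonzero_iccs, dtype=float)
    if np.any(x <= 0):
        raise ValueError("nonzero_iccs must be strictly positive")
    l1 = _log_truncnorm_pdf(x, fit.mu1, fit.sigma1)
    l2 = stats.norm.logpdf(x, fit.mu2, fit.sigma2)
    lp1 = math.log(fit.p1) if fit.p1 > 0 else -np.inf
    lp2 = math.log(fit.p2) if fit.p2 > 0 else -np.inf
    ll = float(np.logaddexp(l1 + lp1, l2 + lp2).sum())
    if n0 > 0:
        if fit.p0 <= 0:
            raise ValueError("n0 > 0 but fitted p0 is 0")
        ll += n0 * math.log(fit.p0)
    return ll


def _weighted_truncnorm_negll_stats(params: np.ndarray, W: float, S1: float, S2: float) -> float:
    """Weighted negative log likelihood of the zero-truncated normal.

    Depends on the data only through W = sum(w), S1 = sum(w x), S2 = sum(w x^2):
    sum_i w_i log f_TN(x_i) = -W log sigma - (S2 - 2 mu S1 + mu^2 W)/(2 sigma^2)
                              - W log(1 - Phi(-mu/sigma)) - W log(sqrt(2 pi)).
    """
    mu, logs = params
    sigma = math.exp(logs)
    quad = (S2 - 2.0 * mu * S1 + mu * mu * W) / (2.0 * sigma * sigma)
    logmass = stats.norm.logsf(0.0, mu, sigma)
    return float(W * logs + quad + W * logmass + 0.5 * W * math.log(2.0 * math.pi))


def fit_truncated_mixture(
    iccs: np.ndarray,
    init: tuple[float, float, float, float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 5,
    seed: int = 0,
    min_n: int = _MIN_N,
) -> MixtureFit:
    """EM fit of the zero-inflated truncated-normal / normal mixture.

    p0 is set to the sample proportion of exact zeros; EM runs on the non-zero
    values.  The truncated component's M-step maximizes its weighted log
    likelihood numerically, accepted only when it improves the objective.
    """
    x = np.asarray(iccs, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("ICC values must lie in [0, 1]")
    n0 = int((x == 0).sum())
    nonzero = x[x > 0]
    p0 = n0 / x.size
    if nonzero.size == 0:
        return MixtureFit(
            model_kind="truncated", p=float("nan"), mu1=float("nan"), sigma1=float("nan"),
            mu2=float("nan"), sigma2=float("nan"), loglik=0.0, n_iter=0,
            converged=False, p0=1.0, n_obs=int(x.size), degenerate=True,
        )
    if nonzero.size < 10:
        raise ValueError("too few non-zero observations for a two-component fit")

    rng = np.random.default_rng(seed)
    inits = [init or _percentile_init(nonzero)]
    inits += [_percentile_init(nonzero, rng) for _ in range(n_restarts)]

    best: MixtureFit | None = None
    errors = []
    for start in inits:
        try:
            fit = _em_truncated(nonzero, n0, p0, start, tol, max_iter)
        except RuntimeError as exc:
            errors.append(exc)
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise RuntimeError(f"all EM starts collapsed: {errors[-1]}")
    return best


def _em_truncated(
    nonzero: np.ndarray, n0: int, p0: float, start: tuple[float, ...], tol: float, max_iter: int
) -> MixtureFit:
    p, mu1, s1, mu2, s2 = start
    x = nonzero
    ll_old = -np.inf
    n_iter = 0
    converged = False
    trace: list[float] = []
    for n_iter in range(1, max_iter + 1):
        l1 = _log_truncnorm_pdf(x, mu1, s1) + math.log(max(p, 1e-300))
        l2 = stats.norm.logpdf(x, mu2, s2) + math.log(max(1 - p, 1e-300))
        denom = np.logaddexp(l1, l2)
        r1 = np.exp(l1 - denom)
        r2 = 1.0 - r1
        ll = float(denom.sum())
        trace.append(ll)

        w1 = r1.sum()
        w2 = r2.sum()
        p = w1 / x.size
        # component 2: plain weighted normal updates
        mu2 = float((r2 * x).sum() / w2)
        s2 = math.sqrt(float((r2 * (x - mu2) ** 2).sum() / w2))
        # component 1: numeric weighted truncated-normal MLE (ECM step),
        # O(1) per evaluation via sufficient statistics
        W, S1, S2 = float(w1), float((r1 * x).sum()), float((r1 * x * x).sum())
        q_old = -_weighted_truncnorm_negll_stats(np.array([mu1, math.log(s1)]), W, S1, S2)
        res = optimize.minimize(
            _weighted_truncnorm_negll_stats,
            x0=np.array([mu1, math.log(s1)]),
            args=(W, S1, S2),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 400},
        )
        if -res.fun > q_old and math.exp(res.x[1]) > _MIN_SIGMA / 2:
            mu1 = float(res.x[0])
            s1 = float(math.exp(res.x[1]))
        if s1 < _MIN_SIGMA or s2 < _MIN_SIGMA:
            raise RuntimeError("component collapse (sigma -> 0)")

        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll

    fit = MixtureFit(
        model_kind="truncated",
        p=float(p),
        mu1=mu1,
        sigma1=s1,
        mu2=mu2,
        sigma2=s2,
        loglik=0.0,
        n_iter=n_iter,
        converged=converged,
        p0=float(p0),
        n_obs=int(x.size + n0),
        loglik_trace=trace,
    )
    fit.loglik = truncated_mixture_loglik(fit, x, n0)
    return fit


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def posterior_high(fit: MixtureFit, icc: float | np.ndarray) -> float | np.ndarray:
    """Posterior probability that a non-zero ICC came from the high component.

    pi(x) = p2 g2(x) / (p1 g1(x) + p2 g2(x)) with g1, g2 the fitted component
    densities.  Undefined at x = 0 (the zero cluster is handled separately).
    """
    fit.validate()
    x = np.asarray(icc, dtype=float)
    if np.any(x <= 0):
        raise ValueError("posterior_high is defined for ICC > 0 only; zeros form their own cluster")
    if fit.model_kind == "truncated":
        l1 = _log_truncnorm_pdf(x, fit.mu1, fit.sigma1)
    else:
        l1 = stats.norm.logpdf(x, fit.mu1, fit.sigma1)
    l2 = stats.norm.logpdf(x, fit.mu2, fit.sigma2)
    # p0 cancels between p1 and p2; use conditional weights for stability
    lp1 = math.log(fit.p) if fit.p > 0 else -np.inf
    lp2 = math.log(1 - fit.p) if fit.p < 1 else -np.inf
    with np.errstate(invalid="ignore"):
        pi = np.exp(l2 + lp2 - np.logaddexp(l1 + lp1, l2 + lp2))
    return float(pi) if np.isscalar(icc) else pi


def icc_threshold_for_posterior(
    fit: MixtureFit, pi_cutoff: float, xtol: float = 1e-6
) -> float:
    """ICC value at which the high-reliability posterior equals the cutoff.

    Verifies that pi(x) - cutoff changes sign exactly once on (0, 1) before
    solving by bracketed root finding.
    """
    if not 0.0 < pi_cutoff < 1.0:
        raise ValueError("pi_cutoff must be in (0, 1)")
    grid = np.linspace(1e-6, 1.0 - 1e-6, 2001)
    f = np.asarray(posterior_high(fit, grid)) - pi_cutoff
    signs = np.sign(f)
    nonzero_signs = signs[signs != 0]
    crossings = int((np.diff(nonzero_signs) != 0).sum())
    if crossings == 0:
        raise ValueError(
            f"posterior never crosses {pi_cutoff} on (0, 1); degenerate fit "
            f"(p={fit.p:.3f}, mu1={fit.mu1:.3f}, mu2={fit.mu2:.3f})"
        )
    if crossings > 1:
        raise ValueError(f"posterior crosses {pi_cutoff} {crossings} times; threshold is ambiguous")
    i = int(np.flatnonzero(np.diff(np.sign(f)) != 0)[0])
    return float(optimize.brentq(lambda x: posterior_high(fit, x) - pi_cutoff, grid[i], grid[i + 1], xtol=xtol))


def classify_sites(icc_table, fit: MixtureFit, pi_cutoff: float = 0.01):
    """Assign each probe to the zero / low / high reliability cluster.

    Probes with ICC = 0 are the zero cluster regardless of the fit; non-zero
    probes are high when their posterior is >= the cutoff (boundary assigned
    to high, maximizing the high-reliability cluster) and low otherwise.
    Probes with unestimable (NaN) ICC are labeled ``unestimable``.
    """
    import pandas as pd

    icc = icc_table["icc"] if hasattr(icc_table, "columns") else pd.Series(np.asarray(icc_table))
    out = pd.DataFrame(index=icc.index)
    out["icc"] = icc
    post = np.full(len(icc), np.nan)
    nz = icc.to_numpy() > 0
    post[nz] = np.asarray(posterior_high(fit, icc.to_numpy()[nz]))
    out["posterior"] = post
    cluster = np.where(np.isnan(icc.to_numpy()), "unestimable", np.where(~nz, "zero", np.where(post >= pi_cutoff, "high", "low")))
    out["cluster"] = cluster
    out.attrs["pi_cutoff"] = pi_cutoff
    out.attrs["counts"] = out["cluster"].value_counts().to_dict()
    return out


def compare_models(fit_censored: MixtureFit, fit_truncated: MixtureFit) -> tuple[MixtureFit, float]:
    """Pick the model with the larger maximized full-data log likelihood.

    Returns (winner, loglik difference = truncated - censored).  Ties go to
    the truncated model.  Both fits must be computed on the same data size.
    """
    if fit_censored.n_obs != fit_truncated.n_obs:
        raise ValueError(
            f"fits computed on different data sizes: {fit_censored.n_obs} vs {fit_truncated.n_obs}"
        )
    diff = fit_truncated.loglik - fit_censored.loglik
    winner = fit_truncated if diff >= 0 else fit_censored
    return winner, float(diff)
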