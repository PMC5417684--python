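"""Generalised Gamma (GG) speckle statistics.

The intensity of fully and partially developed OCT speckle is modelled with the
three-parameter Generalised Gamma (Stacy) family,

    f(x; a, v, p) = p * x**(p*v - 1) * exp(-(x/a)**p) / (a**(p*v) * Gamma(v)),

with scale ``a`` (intensity units, arbitrary for OCT) and shapes ``v`` and ``p``
(dimensionless).  The family contains the exponential (v = p = 1), gamma
(p = 1), Weibull (v = 1) and Rayleigh (v = 1, p = 2) laws as special cases.
The ratio v/p ("scatter density") tracks the effective density of
sub-resolution scatterers in the tissue.

Parameters are estimated from raw (unbinned) linear-intensity samples by
maximum likelihood; histograms are presentation only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import FitFailureError, InsufficientDataError, ParameterDomainError

logger = logging.getLogger(__name__)

__all__ = [
    "GGParams",
    "GGFitResult",
    "HistogramModel",
    "gg_pdf",
    "gg_logpdf",
    "gg_cdf",
    "gg_quantile",
    "gg_mean",
    "fit_gg_mle",
    "scatter_density",
    "intensity_histogram",
]


@dataclass(frozen=True)
class GGParams:
    """Generalised Gamma parameters: scale ``a``, shapes ``v`` and ``p``.

    All three must be finite and strictly positive.  The Stacy family also
    admits p < 0; that branch is deliberately excluded here because corneal
    speckle estimates live well inside p > 0.
    """

    a: float
    v: float
    p: float

    def __post_init__(self):
        for name in ("a", "v", "p"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ParameterDomainError(
                    f"GG parameter {name} must be finite and > 0, got {val!r}"
                )

    @property
    def v_over_p(self) -> float:
        """Shape-parameter ratio v/p (scatter density)."""
        return self.v / self.p

    def as_dict(self) -> dict:
        return {"a": self.a, "v": self.v, "p": self.p, "v_over_p": self.v_over_p}


def _as_params(params) -> GGParams:
    if isinstance(params, GGParams):
        return params
    return GGParams(*params)


def gg_logpdf(x, params) -> np.ndarray:
    """Log-density of the GG law, computed in log space for stability.

    x = 0 is allowed when p*v >= 1 (the density limit there is 0 for
    p*v > 1 and p/(a*Gamma(v)) for p*v == 1); negative x has density 0.
    """
    pr = _as_params(params)
    x = np.asarray(x, dtype=float)
    a, v, p = pr.a, pr.v, pr.p
    with np.errstate(divide="ignore", invalid="ignore"):
        logx = np.log(x)
        out = (
            math.log(p)
            + (p * v - 1.0) * logx
            - np.exp(p * (logx - math.log(a)))
            - p * v * math.log(a)
            - special.gammaln(v)
        )
    out = np.where(x > 0, out, -np.inf)
    if np.any(x == 0):
        if p * v < 1:
            raise ParameterDomainError(
                "gg_pdf at x=0 diverges for p*v < 1; x must be strictly positive"
            )
        if p * v == 1:
            out = np.where(x == 0, math.log(p) - math.log(a) - special.gammaln(v), out)
    return out


def gg_pdf(x, params) -> np.ndarray:
    """Probability density of the GG law at intensity ``x``."""
    return np.exp(gg_logpdf(x, params))


def gg_cdf(x, params) -> np.ndarray:
    """Distribution function: regularised lower incomplete gamma at (x/a)**p."""
    pr = _as_params(params)
    x = np.asarray(x, dtype=float)
    t = np.where(x > 0, (x / pr.a) ** pr.p, 0.0)
    return special.gammainc(pr.v, t)


def gg_quantile(q, params) -> np.ndarray:
    """Inverse CDF: a * (gammaincinv(v, q))**(1/p)."""
    pr = _as_params(params)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ParameterDomainError("quantile levels must lie in [0, 1]")
    return pr.a * special.gammaincinv(pr.v, q) ** (1.0 / pr.p)


def gg_mean(params) -> float:
    """E[X] = a * Gamma(v + 1/p) / Gamma(v)."""
    pr = _as_params(params)
    return pr.a * math.exp(special.gammaln(pr.v + 1.0 / pr.p) - special.gammaln(pr.v))


def scatter_density(params) -> float:
    """Shape-parameter ratio v/p, the scatter-density descriptor."""
    return _as_params(params).v_over_p


@dataclass
class GGFitResult:
    """Outcome of a maximum-likelihood GG fit."""

    params: GGParams
    log_likelihood: float
    n: int
    converged: bool
    ks_gof: float
    n_zeros_dropped: int = 0

    def as_dict(self) -> dict:
        d = self.params.as_dict()
        d.update(
            loglik=self.log_likelihood,
            n=self.n,
            ks_gof=self.ks_gof,
            converged=self.converged,
        )
        return d


def _neg_loglik_per_sample(theta, logx, mean_logx):
    """Mean negative log-likelihood over log-parameters (log a, log v, log p)."""
    la, lv, lp = theta
    a = math.exp(la)
    v = math.exp(lv)
    p = math.exp(lp)
    # mean of (x/a)^p without forming x^p at extreme scales
    t = np.exp(p * (logx - la))
    return -(
        lp
        + (p * v - 1.0) * mean_logx
        - float(np.mean(t))
        - p * v * la
        - special.gammaln(v)
    )


def _moment_start(logx, p0):
    """Method-of-moments start: X**p0 ~ Gamma(v, a**p0)."""
    y = np.exp(p0 * (logx - np.max(logx)))  # rescaled to avoid overflow
    m, s2 = float(np.mean(y)), float(np.var(y))
    if s2 <= 0 or m <= 0:
        return None
    v0 = min(max(m * m / s2, 1e-3), 1e3)
    scale0 = m / v0  # = (a / exp(max logx))**p0
    la0 = math.log(scale0) / p0 + float(np.max(logx))
    return np.array([la0, math.log(v0), math.log(p0)])


DEFAULT_P_STARTS = (0.5, 1.0, 2.0, 3.0)


def fit_gg_mle(
    samples,
    *,
    min_samples: int = 500,
    p_starts=DEFAULT_P_STARTS,
    gtol: float = 1e-8,
) -> GGFitResult:
    """Fit the GG law to raw intensity samples by maximum likelihood.

    The likelihood is maximised over (log a, log v, log p) by quasi-Newton
    (L-BFGS-B) search from a small multi-start grid of method-of-moments
    initialisations over ``p_starts``; the best local optimum is kept.
    Optimising in log parameters enforces positivity without constraints,
    and internally the data are rescaled by their median so the estimate of
    ``a`` is exactly scale-equivariant.

    Samples equal to 0 are dropped (the GG support is (0, inf)) with a logged
    count; negative samples raise.  At least ``min_samples`` strictly positive
    values are required.

    Returns a :class:`GGFitResult` whose ``ks_gof`` is the Kolmogorov-Smirnov
    distance between the empirical CDF and the fitted CDF.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size and np.any(x < 0):
        raise ParameterDomainError("intensity samples must be non-negative")
    n_zero = int(np.count_nonzero(x == 0))
    if n_zero:
        logger.info("fit_gg_mle: dropped %d zero-valued samples", n_zero)
        x = x[x > 0]
    if x.size < min_samples:
        raise InsufficientDataError(
            f"need at least {min_samples} positive samples, got {x.size}"
        )

    med = float(np.median(x))
    z = x / med
    logz = np.log(z)
    mean_logz = float(np.mean(logz))

    best = None
    for p0 in p_starts:
        theta0 = _moment_start(logz, p0)
        if theta0 is None:
            continue
        res = optimize.minimize(
            _neg_loglik_per_sample,
            theta0,
            args=(logz, mean_logz),
            method="L-BFGS-B",
            options={"gtol": gtol, "ftol": 1e-14, "maxiter": 500},
        )
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitFailureError("GG fit failed from every start; data degenerate?")

    la, lv, lp = best.x
    params = GGParams(a=math.exp(la) * med, v=math.exp(lv), p=math.exp(lp))
    # total log-likelihood on the original scale: ll_x = ll_z - n*log(med)
    loglik = -best.fun * z.size - z.size * math.log(med)
    ks = float(stats.kstest(x, lambda q: gg_cdf(q, params)).statistic)
    converged = bool(best.success)
    if not converged:
        logger.warning("fit_gg_mle: best start did not report convergence: %s", best.message)
    return GGFitResult(
        params=params,
        log_likelihood=float(loglik),
        n=int(z.size),
        converged=converged,
        ks_gof=ks,
        n_zeros_dropped=n_zero,
    )


@dataclass
class HistogramModel:
    """Density-normalised intensity histogram with a fitted-pdf overlay."""

    edges: np.ndarray
    heights: np.ndarray
    centres: np.ndarray = field(repr=False)
    pdf_values: np.ndarray = field(repr=False)
    params: GGParams | None = None


def intensity_histogram(samples, n_bins: int = 20, params=None) -> HistogramModel:
    """Histogram ROI intensities (default 20 bins) with a GG-pdf overlay.

    Heights are density normalised (the bar areas sum to 1).  If ``params`` is
    None the overlay uses a fresh maximum-likelihood fit to the samples.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise InsufficientDataError("cannot histogram an empty sample")
    if n_bins < 2:
        raise ParameterDomainError("n_bins must be >= 2")
    if np.ptp(x) == 0:
        # degenerate constant sample: a single occupied bin around the value
        edges = np.linspace(x[0] - 0.5, x[0] + 0.5, n_bins + 1)
        heights, edges = np.histogram(x, bins=edges, density=True)
    else:
        heights, edges = np.histogram(x, bins=n_bins, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    if params is not None:
        pr = _as_params(params)
    elif np.ptp(x) > 0:
        pr = fit_gg_mle(x).params
    else:
        pr = None  # constant sample: no meaningful fit, overlay suppressed
    if pr is None:
        pdf_values = np.zeros_like(centres)
    else:
        pdf_values = np.where(centres > 0, gg_pdf(np.maximum(centres, 1e-300), pr), 0.0)
    return HistogramModel(
        edges=edges, heights=heights, centres=centres, pdf_values=pdf_values, params=pr
    )
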