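"""Characterizing a codon's NFC sample vector.

Empirical histograms and features (mean, median, histogram mode), maximum-
likelihood fits over a panel of candidate distribution families with
best-family selection by attained log-likelihood, and closed-form features of
the log-normal law

    f(x) = 1/(x sigma sqrt(2 pi)) exp(-(ln x - mu)^2 / (2 sigma^2)),  x > 0

whose mean is e^(mu + sigma^2/2), median e^mu and skewness
(e^(sigma^2) + 2) sqrt(e^(sigma^2) - 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: candidate families for NFC distribution fitting (registry is extensible:
#: register_family adds a 14th and later entries)
FAMILIES = [
    "beta",
    "birnbaum_saunders",
    "extreme_value",
    "generalized_extreme_value",
    "inverse_gaussian",
    "logistic",
    "log_logistic",
    "log_normal",
    "nakagami",
    "normal",
    "rayleigh",
    "rician",
    "t_location_scale",
]


@dataclass
class EmpiricalDistribution:
    """Histogram on uniform bins over [0, upper] plus one overflow bin."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size != self.bin_edges.size - 1:
            raise ValueError("probabilities must have one entry per bin")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.probabilities < 0) or abs(self.probabilities.sum() - 1) > 1e-9:
            raise ValueError("probabilities must be >= 0 and sum to 1")


@dataclass
class FitResult:
    """One fitted family: parameters, attained log-likelihood, sample size."""

    family: str
    params: tuple
    param_names: tuple
    loglik: float
    n: int
    success: bool = True
    message: str = ""

    def param(self, name: str) -> float:
        return self.params[self.param_names.index(name)]


@dataclass
class NfcFeatures:
    """Per-codon NFC summary features.

    Empirical mean/median/mode plus the log-normal-fit features: fitted mean
    ``ln_mean`` = e^(mu+sigma^2/2), fitted median ``ln_median`` = e^mu and
    fitted skewness ``ln_skewness`` (dimensionless).
    """

    mean: float
    median: float
    mode: float
    ln_mean: float
    ln_median: float
    ln_skewness: float
    mu: float
    sigma: float
    n: int


def histogram(samples, bin_width: float = 0.05, upper: float = 5.0) -> EmpiricalDistribution:
    """Bin samples on uniform [0, upper] bins plus one overflow bin."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("histogram requires at least one sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample passed to histogram")
    if np.any(x < 0):
        raise ValueError("negative sample passed to histogram")
    nb = int(round(upper / bin_width))
    edges = np.concatenate([np.linspace(0.0, upper, nb + 1), [np.inf]])
    counts, _ = np.histogram(x, bins=edges)
    return EmpiricalDistribution(edges, counts / x.size, x.size)


def _finite(params, ll) -> bool:
    return np.all(np.isfinite(params)) and np.isfinite(ll)


def _fit_scipy(dist, x, names, **kw):
    params = dist.fit(x, **kw)
    ll = float(np.sum(dist.logpdf(x, *params)))
    return tuple(float(p) for p in params), tuple(names), ll


def _fit_beta(x):
    # Beta needs support [0, 1]: scale by 1/max and correct the likelihood by
    # the Jacobian n*log(M) so it stays comparable with the other families.
    M = float(x.max()) * (1 + 1e-9)
    y = x / M
    a, b, loc, scale = stats.beta.fit(y, floc=0, fscale=1)
    ll = float(np.sum(stats.beta.logpdf(y, a, b)) - x.size * math.log(M))
    return (float(a), float(b), M), ("a", "b", "scale"), ll


def _fit_lognormal(x):
    # closed-form MLE: mu = mean(ln x), sigma^2 = variance(ln x)
    lx = np.log(x)
    mu = float(lx.mean())
    sigma = float(lx.std())
    if sigma <= 0:
        raise ValueError("degenerate sample (sigma -> 0 boundary)")
    ll = float(
        -x.size * math.log(sigma * math.sqrt(2 * math.pi))
        - lx.sum()
        - np.sum((lx - mu) ** 2) / (2 * sigma**2)
    )
    return (mu, sigma), ("mu", "sigma"), ll


def _fit_normal(x):
    mu = float(x.mean())
    sigma = float(x.std())
    if sigma <= 0:
        raise ValueError("degenerate sample")
    ll = float(np.sum(stats.norm.logpdf(x, mu, sigma)))
    return (mu, sigma), ("mu", "sigma"), ll


def _fit_rayleigh(x):
    # MLE with loc fixed at 0: sigma^2 = mean(x^2)/2
    sigma = float(np.sqrt(np.mean(x**2) / 2))
    if sigma <= 0:
        raise ValueError("degenerate sample")
    ll = float(np.sum(stats.rayleigh.logpdf(x, 0, sigma)))
    return (sigma,), ("sigma",), ll


_FITTERS = {
    "beta": (True, _fit_beta),
    "birnbaum_saunders": (True, lambda x: _fit_scipy(stats.fatiguelife, x, ("c", "loc", "scale"), floc=0)),
    "extreme_value": (False, lambda x: _fit_scipy(stats.gumbel_l, x, ("loc", "scale"))),
    "generalized_extreme_value": (False, lambda x: _fit_scipy(stats.genextreme, x, ("c", "loc", "scale"))),
    "inverse_gaussian": (True, lambda x: _fit_scipy(stats.invgauss, x, ("mu", "loc", "scale"), floc=0)),
    "logistic": (False, lambda x: _fit_scipy(stats.logistic, x, ("loc", "scale"))),
    "log_logistic": (True, lambda x: _fit_scipy(stats.fisk, x, ("c", "loc", "scale"), floc=0)),
    "log_normal": (True, _fit_lognormal),
    "nakagami": (True, lambda x: _fit_scipy(stats.nakagami, x, ("nu", "loc", "scale"), floc=0)),
    "normal": (False, _fit_normal),
    "rayleigh": (True, _fit_rayleigh),
    "rician": (True, lambda x: _fit_scipy(stats.rice, x, ("b", "loc", "scale"), floc=0)),
    "t_location_scale": (False, lambda x: _fit_scipy(stats.t, x, ("df", "loc", "scale"))),
}


def register_family(name: str, positive_support: bool, fitter) -> None:
    """Register an extra candidate family.

    ``fitter(x) -> (params, param_names, loglik)`` receives a 1-D float
    array and must return the MLE and the attained log-likelihood.
    """
    _FITTERS[name] = (positive_support, fitter)
    if name not in FAMILIES:
        FAMILIES.append(name)


def fit_family(samples, family: str, min_samples: int = 30) -> FitResult:
    """Maximum-likelihood fit of one candidate family.

    For positive-support families, samples at 0 (or below) are dropped with
    the count logged.  Optimizer failure or a non-finite likelihood yields a
    ``FitResult`` flagged ``success=False`` rather than an exception, so
    :func:`best_fit` can skip it.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}; known: {sorted(_FITTERS)}")
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample passed to fit_family")
    if x.size < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {x.size}")
    positive, fitter = _FITTERS[family]
    if positive:
        n0 = x.size
        x = x[x > 0]
        if x.size < n0:
            logger.info("fit_family(%s): dropped %d non-positive samples", family, n0 - x.size)
        if x.size < min_samples:
            return FitResult(family, (), (), -np.inf, x.size, False, "too few positive samples")
    if x.size and np.ptp(x) == 0:
        return FitResult(family, (), (), -np.inf, x.size, False, "degenerate (constant) sample")
    try:
        params, names, ll = fitter(x)
    except Exception as e:  # noqa: BLE001 - optimizer failures become flagged results
        return FitResult(family, (), (), -np.inf, x.size, False, f"fit failed: {e}")
    if not _finite(params, ll):
        return FitResult(family, params, names, -np.inf, x.size, False, "non-finite fit")
    return FitResult(family, params, names, ll, x.size)


def best_fit(samples, families=None, min_samples: int = 30) -> tuple[FitResult, list[FitResult]]:
    """Fit all candidate families and select the maximal log-likelihood.

    Returns the winning :class:`FitResult` and the full table ranked by
    log-likelihood (failed fits last).  Raises if every fit failed.

    Selection uses the raw maximized log-likelihood with no parameter-count
    penalty.  Note the likelihoods are only comparable when every family saw
    the same samples; with zeros present the positive-support families drop
    them, which is logged.
    """
    if families is None:
        families = FAMILIES
    results = [fit_family(samples, f, min_samples=min_samples) for f in families]
    ok = [r for r in results if r.success]
    if not ok:
        raise ValueError("all candidate-family fits failed")
    table = sorted(results, key=lambda r: (-r.success, -r.loglik))
    return table[0], table


def lognormal_features(mu: float, sigma: float) -> tuple[float, float, float]:
    """Closed-form (mean, median, skewness) of a log-normal(mu, sigma) law."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s2 = sigma**2
    ln_mean = math.exp(mu + s2 / 2)
    ln_median = math.exp(mu)
    ln_skewness = (math.exp(s2) + 2) * math.sqrt(math.exp(s2) - 1)
    return ln_mean, ln_median, ln_skewness


def empirical_features(
    samples, bin_width: float = 0.05, upper: float = 5.0
) -> tuple[float, float, float]:
    """Sample mean, sample median, and histogram-mode of an NFC sample.

    The mode is the midpoint of the tallest finite histogram bin; ties go to
    the lowest-value bin (logged).
    """
    x = np.asarray(samples, dtype=float)
    h = histogram(x, bin_width=bin_width, upper=upper)
    finite_p = h.probabilities[:-1]
    top = finite_p.max()
    tied = np.flatnonzero(finite_p == top)
    if tied.size > 1:
        logger.info("empirical_features: %d tied mode bins; using the lowest", tied.size)
    if h.probabilities[-1] > top:
        logger.warning("empirical_features: overflow bin is the tallest; mode uses finite bins only")
    i = int(tied[0])
    mode = float((h.bin_edges[i] + h.bin_edges[i + 1]) / 2)
    return float(x.mean()), float(np.median(x)), mode


def nfc_features(samples, bin_width: float = 0.05, upper: float = 5.0, min_samples: int = 30) -> NfcFeatures:
    """All per-codon NFC features: empirical plus log-normal-fit ones."""
    mean, median, mode = empirical_features(samples, bin_width=bin_width, upper=upper)
    fit = fit_family(samples, "log_normal", min_samples=min_samples)
    if not fit.success:
        raise ValueError(f"log-normal fit failed: {fit.message}")
    mu, sigma = fit.params
    ln_mean, ln_median, ln_skew = lognormal_features(mu, sigma)
    return NfcFeatures(mean, median, mode, ln_mean, ln_median, ln_skew, mu, sigma, fit.n)
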