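"""The dichotomized Gaussian population model and correlation estimators.

The input current of neuron ``i`` during a stationary period is modelled as

    s_i = mu_s + sigma_s * (sqrt(1 - alpha) * nu_i + sqrt(alpha) * eps),

with ``nu_i`` independent standard normals (private fluctuations) and
``eps`` a standard normal shared by the whole population.  The shared
factor induces a pairwise covariance ``cov(s_i, s_j) = sigma_s**2 * alpha``,
which is the correlation-code observable.  A neuron "fires" in a bin when
``s_i >= h``; the fraction ``r`` of the population firing in a bin then has,
for large N, the closed-form density obtained by transforming the common
factor:

    r = q(eps) = Phi((mu_s + sigma_s*sqrt(alpha)*eps - h) / (sigma_s*sqrt(1-alpha)))
    p(r) = phi(eps(r)) / q'(eps(r))
         = phi(eps(r)) * sqrt((1-alpha)/alpha) / phi(Phi^{-1}(r)),

where ``eps(r) = (sigma_s*sqrt(1-alpha)*Phi^{-1}(r) + h - mu_s) /
(sigma_s*sqrt(alpha))``.  The density is derived from first principles by
this change of variables (and validated against the Monte-Carlo sampler),
and is normalised by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DGParams", "estimate_sigma_s", "mean_pairwise_covariance",
    "mean_pairwise_covariance_pairs", "dg_sample", "dg_rate_density",
    "fit_threshold", "fit_dg_params", "survival_curve", "RateDistribution",
    "rate_distribution",
]


@dataclass(frozen=True)
class DGParams:
    """Parameters of the dichotomized Gaussian population model."""

    mu_s: float       # uA, mean input current
    sigma_s: float    # uA, per-neuron SD of the input current
    alpha: float      # shared-variance fraction, in [0, 1)
    h: float          # uA, firing threshold on the current

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")

    @property
    def pairwise_covariance(self) -> float:
        """cov(s_i, s_j) = sigma_s^2 * alpha, the correlation-code quantity."""
        return self.sigma_s ** 2 * self.alpha

    @property
    def mean_rate(self) -> float:
        """Expected population firing fraction, Phi((mu_s - h)/sigma_s)."""
        return float(sps.norm.cdf((self.mu_s - self.h) / self.sigma_s))


# --------------------------------------------------------------------------
# estimators on current traces (samples x neurons)
# --------------------------------------------------------------------------

def estimate_sigma_s(traces: np.ndarray) -> float:
    """Mean over neurons of the per-neuron sample SD of the input current."""
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 samples per neuron (samples x neurons)")
    return float(traces.std(axis=0, ddof=1).mean())


def mean_pairwise_covariance(traces: np.ndarray) -> float:
    """Average sample covariance over all unordered neuron pairs.

    Computed with the variance-of-sum identity
    ``[Var(sum_i s_i) - sum_i Var(s_i)] / (N (N - 1))``, which is O(N*T)
    instead of O(N^2 * T) and equals the explicit all-pairs average exactly.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] < 2:
        raise ValueError("need >= 2 neurons (samples x neurons)")
    n = traces.shape[1]
    var_sum = traces.sum(axis=1).var(ddof=1)
    sum_var = traces.var(axis=0, ddof=1).sum()
    return float((var_sum - sum_var) / (n * (n - 1)))


def mean_pairwise_covariance_pairs(traces: np.ndarray) -> float:
    """Explicit all-pairs loop; O(N^2) oracle for the identity above."""
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[1]
    c = np.cov(traces, rowvar=False, ddof=1)
    off = c[~np.eye(n, dtype=bool)]
    return float(off.mean())


# --------------------------------------------------------------------------
# the model itself
# --------------------------------------------------------------------------

def dg_sample(params: DGParams, n_neurons: int, n_bins: int,
              seed: int | np.random.Generator = 0,
              method: str = "explicit") -> np.ndarray:
    """Monte-Carlo population firing fractions; brute-force density oracle.

    Per bin one shared normal and ``n_neurons`` private normals are drawn,
    currents thresholded at ``h``, and the firing fraction returned.
    ``method="binomial"`` draws the per-bin firing count directly from
    Binomial(n, Phi(...)) — distributionally identical (the neurons are
    conditionally independent given the shared factor) and O(n_bins)
    instead of O(n_bins * n_neurons), for large-population oracles.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eps = rng.standard_normal(n_bins)
    priv = params.sigma_s * np.sqrt(1.0 - params.alpha)
    # per-bin threshold on the private normal, conditioned on the shared factor
    thr = (params.h - params.mu_s - params.sigma_s * np.sqrt(params.alpha) * eps) / priv
    if method == "binomial":
        return rng.binomial(n_neurons, sps.norm.sf(thr)) / n_neurons
    if method != "explicit":
        raise ValueError("method must be 'explicit' or 'binomial'")
    # fraction of nu_i >= thr; drawing per neuron, vectorised over bins
    nu = rng.standard_normal((n_bins, n_neurons))
    return (nu >= thr[:, None]).mean(axis=1)


def dg_rate_density(params: DGParams, r: np.ndarray | float) -> np.ndarray:
    """Large-N closed-form density of the population firing fraction.

    Valid for ``r`` strictly inside (0, 1) and ``alpha > 0``; integrates to
    one analytically (change of variables from the shared factor).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r <= 0.0) | (r >= 1.0)):
        raise ValueError("r must lie strictly inside (0, 1)")
    if params.alpha == 0.0:
        raise ValueError("alpha must be positive for a non-degenerate density")
    a = params.alpha
    z = sps.norm.ppf(r)
    eps = (params.sigma_s * np.sqrt(1.0 - a) * z + params.h - params.mu_s) \
        / (params.sigma_s * np.sqrt(a))
    dens = sps.norm.pdf(eps) * np.sqrt((1.0 - a) / a) / sps.norm.pdf(z)
    return dens


def fit_threshold(mean_rate: float, mu_s: float, sigma_s: float) -> float:
    """Threshold h matching an observed mean firing fraction.

    ``E[r] = Phi((mu_s - h)/sigma_s)`` inverts uniquely to
    ``h = mu_s - sigma_s * Phi^{-1}(mean_rate)``.
    """
    if not 0.0 < mean_rate < 1.0:
        raise ValueError("mean_rate must lie strictly inside (0, 1)")
    return float(mu_s - sigma_s * sps.norm.ppf(mean_rate))


def fit_dg_params(traces: np.ndarray, mean_rate: float) -> DGParams:
    """Moment-match DG parameters from current traces plus the observed rate.

    ``mu_s`` and ``sigma_s`` come from the traces, ``alpha`` from the mean
    pairwise covariance, and ``h`` from the mean firing fraction; nothing is
    fitted to the shape of the synchrony histogram itself.
    """
    mu = float(np.mean(traces))
    sigma = estimate_sigma_s(traces)
    cov = mean_pairwise_covariance(traces)
    alpha = min(max(cov / sigma ** 2, 0.0), 1.0 - 1e-12)
    return DGParams(mu_s=mu, sigma_s=sigma, alpha=alpha,
                    h=fit_threshold(mean_rate, mu, sigma))


# --------------------------------------------------------------------------
# synchrony histograms
# --------------------------------------------------------------------------

def survival_curve(hist: np.ndarray) -> np.ndarray:
    """Right-tail cumulative P(rate >= bin) of a normalized histogram."""
    hist = np.asarray(hist, dtype=float)
    return np.cumsum(hist[::-1])[::-1]


@dataclass
class RateDistribution:
    """Synchrony histogram of a period with its DG description."""

    bin_edges: np.ndarray      # on [0, 1]
    hist: np.ndarray           # probability mass per bin (sums to 1)
    survival: np.ndarray       # P(r >= left edge of bin)
    params: DGParams | None    # moment-matched model, if traces were given
    density_grid: np.ndarray | None   # model density on bin centers
    n_samples: int


def rate_distribution(fractions: np.ndarray, *, n_e: int,
                      traces: np.ndarray | None = None) -> RateDistribution:
    """Histogram the observed firing fractions; attach the fitted DG model.

    Bins have width ``1/n_e`` (one neuron), so the histogram resolves the
    discrete support of the observed fractions.
    """
    fractions = np.asarray(fractions, dtype=float).ravel()
    upper = max(float(fractions.max()) if fractions.size else 0.0, 2.0 / n_e)
    edges = np.arange(0.0, upper + 2.0 / n_e, 1.0 / n_e)
    hist, _ = np.histogram(fractions, edges)
    hist = hist / hist.sum()
    params = None
    dens = None
    mean_rate = float(fractions.mean())
    if traces is not None and 0.0 < mean_rate < 1.0:
        params = fit_dg_params(traces, mean_rate)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = (centers > 0) & (centers < 1)
        dens = np.zeros_like(centers)
        if params.alpha > 0:
            dens[ok] = dg_rate_density(params, centers[ok])
    return RateDistribution(bin_edges=edges, hist=hist,
                            survival=survival_curve(hist), params=params,
                            density_grid=dens, n_samples=fractions.size)
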