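"""Two-component Gaussian mixture fits to log(|N|) per |REMpre| bin.

The distribution of the log of accumulated inter-REM NREM duration is
modelled as k_l*N(mu_l, sigma_l) + (1-k_l)*N(mu_s, sigma_s) with
mu_l > mu_s: the long component captures "single" REM cycles, the short
component "sequential" ones. Fitting is expectation-maximization from 20
random initializations, keeping the fit with the lowest Kolmogorov-Smirnov
statistic; goodness of fit is assessed with a Monte-Carlo corrected
(Lilliefors-like) KS test, which accounts for the parameters having been
estimated from the same sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.stats import norm

__all__ = [
    "GmmParams",
    "FitResult",
    "ComponentCollapse",
    "gmm_density",
    "mixture_cdf",
    "mixture_sf",
    "em_fit",
    "fit_with_restarts",
    "ks_statistic",
    "sample_mixture",
    "lilliefors_p",
]

#: Lower bound on component standard deviations (log-seconds); an EM run
#: pushing a sigma below this is treated as collapsed and redrawn.
SIGMA_FLOOR = 1e-3

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000
DEFAULT_N_RESTARTS = 20


class ComponentCollapse(RuntimeError):
    """EM drove one component's variance to (near) zero."""


@dataclass(frozen=True)
class GmmParams:
    """Parameters (k_l, mu_l, sigma_l, mu_s, sigma_s) with mu_l > mu_s."""

    k_l: float
    mu_l: float
    sigma_l: float
    mu_s: float
    sigma_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_l <= 1.0:
            raise ValueError("k_l must lie in [0, 1]")
        if self.sigma_l <= 0 or self.sigma_s <= 0:
            raise ValueError("component standard deviations must be positive")
        if self.mu_l < self.mu_s:
            raise ValueError("mu_l must be >= mu_s (relabel components first)")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.k_l, self.mu_l, self.sigma_l, self.mu_s, self.sigma_s]
        )

    @staticmethod
    def canonical(
        k1: float, mu1: float, s1: float, mu2: float, s2: float
    ) -> "GmmParams":
        """Build params relabelled so the first component has the larger mean."""
        if mu1 >= mu2:
            return GmmParams(k1, mu1, s1, mu2, s2)
        return GmmParams(1.0 - k1, mu2, s2, mu1, s1)


@dataclass(frozen=True)
class FitResult:
    """Selected mixture fit for one bin, with goodness of fit."""

    params: GmmParams
    ks_stat: float
    ks_p: float | None
    n: int
    n_restarts_used: int
    converged: bool
    iterations: int


def gmm_density(
    params: GmmParams, x: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Mixture density k_l*phi(x; mu_l, sigma_l) + (1-k_l)*phi(x; mu_s, sigma_s)."""
    x = np.asarray(x, dtype=float)
    out = params.k_l * norm.pdf(
        x, params.mu_l, params.sigma_l
    ) + (1.0 - params.k_l) * norm.pdf(x, params.mu_s, params.sigma_s)
    return out if out.ndim else float(out)


def mixture_cdf(
    params: GmmParams, x: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Mixture CDF at *x* (log-seconds)."""
    x = np.asarray(x, dtype=float)
    out = params.k_l * norm.cdf(
        x, params.mu_l, params.sigma_l
    ) + (1.0 - params.k_l) * norm.cdf(x, params.mu_s, params.sigma_s)
    return out if out.ndim else float(out)


def mixture_sf(
    params: GmmParams, x: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Mixture survival function 1 - CDF, accurate deep in the upper tail."""
    x = np.asarray(x, dtype=float)
    out = params.k_l * norm.sf(
        x, params.mu_l, params.sigma_l
    ) + (1.0 - params.k_l) * norm.sf(x, params.mu_s, params.sigma_s)
    return out if out.ndim else float(out)


def _log_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * math.log(2.0 * math.pi)


def em_fit(
    logN: np.ndarray,
    init: GmmParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_loglik: bool = False,
) -> tuple[GmmParams, int, bool] | tuple[GmmParams, int, bool, np.ndarray]:
    """Run 2-component EM from *init* until parameter convergence.

    Stops when the squared Euclidean distance between successive parameter
    vectors (k_l, mu_l, sigma_l, mu_s, sigma_s) drops below *tol*, or after
    *max_iter* iterations (flagged, not fatal). Components are relabelled so
    mu_l > mu_s before returning. Raises :class:`ComponentCollapse` if a
    component sigma falls below the floor — a restart signal, not a crash.
    """
    x = np.asarray(logN, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ValueError("need a 1-d sample of at least 5 points")
    if not np.isfinite(x).all():
        raise ValueError("sample must be finite")

    k, mu1, s1, mu2, s2 = init.as_vector()
    prev = init.as_vector()
    converged = False
    iterations = 0
    loglik_trace = [] if track_loglik else None

    for iterations in range(1, max_iter + 1):
        # E step via log densities (robust to far outliers).
        la = math.log(k) + _log_pdf(x, mu1, s1) if k > 0 else np.full_like(x, -np.inf)
        lb = (
            math.log(1.0 - k) + _log_pdf(x, mu2, s2)
            if k < 1
            else np.full_like(x, -np.inf)
        )
        m = np.maximum(la, lb)
        log_mix = m + np.log(np.exp(la - m) + np.exp(lb - m))
        if track_loglik:
            loglik_trace.append(float(np.sum(log_mix)))
        r = np.exp(la - log_mix)  # responsibility of the first component

        # M step.
        w = float(np.sum(r))
        n = x.size
        if w < 1e-12 or n - w < 1e-12:
            raise ComponentCollapse("a component lost all responsibility")
        k = w / n
        mu1 = float(np.dot(r, x) / w)
        s1 = math.sqrt(float(np.dot(r, (x - mu1) ** 2) / w))
        mu2 = float(np.dot(1.0 - r, x) / (n - w))
        s2 = math.sqrt(float(np.dot(1.0 - r, (x - mu2) ** 2) / (n - w)))
        if s1 < SIGMA_FLOOR or s2 < SIGMA_FLOOR:
            raise ComponentCollapse(
                f"component sigma below floor {SIGMA_FLOOR:g} log-seconds"
            )

        vec = np.array([k, mu1, s1, mu2, s2])
        if float(np.sum((vec - prev) ** 2)) < tol:
            converged = True
            prev = vec
            break
        prev = vec

    params = GmmParams.canonical(k, mu1, s1, mu2, s2)
    if track_loglik:
        return params, iterations, converged, np.asarray(loglik_trace)
    return params, iterations, converged


def _draw_init(x: np.ndarray, rng: np.random.Generator) -> GmmParams:
    """Random initialization: means within the sample's central range,
    sigmas scaled to the sample sd, weight away from the degenerate edges."""
    q10, q90 = np.quantile(x, [0.10, 0.90])
    s = float(np.std(x))
    if s < SIGMA_FLOOR:
        s = SIGMA_FLOOR * 10
    mu1, mu2 = rng.uniform(q10, q90, size=2)
    s1, s2 = rng.uniform(0.25 * s, 1.5 * s, size=2)
    k = rng.uniform(0.1, 0.9)
    if mu1 < mu2:
        mu1, mu2 = mu2, mu1
        s1, s2 = s2, s1
        k = 1.0 - k
    return GmmParams(k, mu1, s1, mu2, s2)


def ks_statistic(logN: np.ndarray, params: GmmParams) -> float:
    """Sup distance between the sample ECDF and the mixture CDF."""
    x = np.sort(np.asarray(logN, dtype=float))
    if x.size == 0:
        raise ValueError("sample must be nonempty")
    n = x.size
    cdf = np.asarray(mixture_cdf(params, x))
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def fit_with_restarts(
    logN: np.ndarray,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: Union[int, np.random.Generator, np.random.SeedSequence, None] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """EM from *n_restarts* random initializations; keep the lowest-KS fit.

    Collapsed restarts are discarded and redrawn (up to 10x the requested
    count); converged fits are preferred over non-converged ones. The result
    is deterministic given the seed. ``ks_p`` is left ``None`` — compute it
    with :func:`lilliefors_p` when needed.
    """
    x = np.asarray(logN, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points to fit")
    rng = np.random.default_rng(seed)
    best: tuple[bool, float] | None = None  # (converged, ks) ranking key
    best_fit: FitResult | None = None
    completed = 0
    attempts = 0
    while completed < n_restarts and attempts < 10 * n_restarts:
        attempts += 1
        init = _draw_init(x, rng)
        try:
            params, iters, conv = em_fit(x, init, tol=tol, max_iter=max_iter)
        except ComponentCollapse:
            continue
        completed += 1
        ks = ks_statistic(x, params)
        key = (not conv, ks)  # converged fits sort first, then by KS
        if best is None or key < best:
            best = key
            best_fit = FitResult(
                params=params,
                ks_stat=ks,
                ks_p=None,
                n=int(x.size),
                n_restarts_used=completed,
                converged=conv,
                iterations=iters,
            )
    if best_fit is None:
        raise RuntimeError(
            f"all {attempts} EM restarts collapsed on a sample of {x.size} points"
        )
    # record how many restarts actually completed
    return FitResult(
        params=best_fit.params,
        ks_stat=best_fit.ks_stat,
        ks_p=best_fit.ks_p,
        n=best_fit.n,
        n_restarts_used=completed,
        converged=best_fit.converged,
        iterations=best_fit.iterations,
    )


def _sample_mixture(
    params: GmmParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    long = rng.random(n) < params.k_l
    out = np.where(
        long,
        rng.normal(params.mu_l, params.sigma_l, size=n),
        rng.normal(params.mu_s, params.sigma_s, size=n),
    )
    return out


def sample_mixture(
    params: GmmParams,
    n: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Draw *n* points from the mixture (log-second scale)."""
    return _sample_mixture(params, n, np.random.default_rng(seed))


def lilliefors_p(
    logN: np.ndarray,
    n_restarts: int = DEFAULT_N_RESTARTS,
    n_mc: int = 1000,
    seed: Union[int, np.random.Generator, np.random.SeedSequence, None] = None,
    fast_init: GmmParams | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[float, FitResult]:
    """Monte-Carlo corrected KS p-value (parametric bootstrap).

    Fit the sample, then repeatedly draw samples of the same size from the
    fitted mixture, refit each with the same protocol, and report the
    fraction of replicate KS statistics at least as large as the observed
    one. With *fast_init* given, the observed fit and every replicate refit
    use a single EM start (at *fast_init* and at the fitted parameters,
    respectively) instead of the full restart protocol — a documented fast
    mode for calibration studies.

    Returns ``(p, fit)`` where ``fit`` carries the corrected p in ``ks_p``.
    """
    x = np.asarray(logN, dtype=float)
    rng = np.random.default_rng(seed)

    def _fit(sample: np.ndarray, init: GmmParams | None) -> FitResult:
        if init is not None:
            try:
                params, iters, conv = em_fit(
                    sample, init, tol=tol, max_iter=max_iter
                )
            except ComponentCollapse:
                # fall back to one random start
                return fit_with_restarts(
                    sample, n_restarts=1, seed=rng, tol=tol, max_iter=max_iter
                )
            return FitResult(
                params=params,
                ks_stat=ks_statistic(sample, params),
                ks_p=None,
                n=int(sample.size),
                n_restarts_used=1,
                converged=conv,
                iterations=iters,
            )
        return fit_with_restarts(
            sample, n_restarts=n_restarts, seed=rng, tol=tol, max_iter=max_iter
        )

    observed = _fit(x, fast_init)
    d0 = observed.ks_stat
    exceed = 0
    for _ in range(n_mc):
        rep = _sample_mixture(observed.params, x.size, rng)
        rep_fit = _fit(rep, observed.params if fast_init is not None else None)
        if rep_fit.ks_stat >= d0:
            exceed += 1
    p = exceed / n_mc
    out = FitResult(
        params=observed.params,
        ks_stat=observed.ks_stat,
        ks_p=p,
        n=observed.n,
        n_restarts_used=observed.n_restarts_used,
        converged=observed.converged,
        iterations=observed.iterations,
    )
    return p, out
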