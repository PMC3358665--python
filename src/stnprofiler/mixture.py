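"""Finite mixtures of skew t-Normal components, fitted by ECM/ECME.

A g-component STN mixture has density

    f(y | Theta) = sum_i w_i psi(y | xi_i, sigma2_i, lam_i, nu_i),

with positive mixing weights summing to one. Fitting alternates an E-step
computing four conditional expectations per event and component
(responsibility z, precision tau, log-precision kappa, and the truncated
first moment gamma1 of the skewing latent) with closed-form conditional
M-step updates; the degrees of freedom are updated either per component
(a one-dimensional concave maximization) or, when shared across
components, by directly maximizing the observed log-likelihood (the CML
step, making the algorithm ECME). Iteration stops by Aitken acceleration:
the run terminates once the current log-likelihood is within ``tol`` of
its Aitken-extrapolated asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special
from scipy.special import logsumexp

from .stn import STNParams, stn_cdf, stn_logpdf, stn_sample

__all__ = ["STNMixture", "EStepResult", "FitOptions", "FitResult",
           "DegenerateFitError", "mixture_pdf", "mixture_logpdf",
           "mixture_cdf", "e_step", "cm_step", "fit_ecme", "bic",
           "sample_mixture"]

_NU_BOUNDS = (0.5, 200.0)


class DegenerateFitError(RuntimeError):
    """A component collapsed (vanishing scale or empty responsibility)."""


@dataclass(frozen=True)
class STNMixture:
    """Mixing weights plus component parameters; the fitted "profile"."""

    weights: np.ndarray
    components: tuple[STNParams, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "components", tuple(self.components))
        if w.ndim != 1 or len(self.components) != w.size or w.size < 1:
            raise ValueError("weights and components must be matching "
                             "nonempty 1-d collections")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must be positive and sum to 1, got {w}")

    @property
    def g(self) -> int:
        return len(self.components)

    def pdf(self, y):
        return mixture_pdf(y, self)

    def logpdf(self, y):
        return mixture_logpdf(y, self)

    def cdf(self, y):
        return mixture_cdf(y, self)


@dataclass
class EStepResult:
    """Per-event, per-component conditional expectations (all n x g).

    ``z_hat`` are responsibilities; ``tau_hat`` the expected latent
    precisions; ``kappa_hat`` the expected log precisions; ``gamma1_hat``
    the expected truncated skewing variables; ``u`` the standardized
    residuals (y_j - xi_i) / sigma_i.
    """

    z_hat: np.ndarray
    tau_hat: np.ndarray
    kappa_hat: np.ndarray
    gamma1_hat: np.ndarray
    u: np.ndarray
    loglik: float


@dataclass
class FitOptions:
    """Controls for the ECM/ECME iteration.

    ``tol`` is the Aitken tolerance epsilon (default 1e-6). ``equal_df``
    shares one nu across components and updates it by the CML step.
    ``fixed_lam`` / ``fixed_nu`` pin those parameters (e.g. ``fixed_lam=0``
    fits a t mixture; additionally ``fixed_nu=1e6`` an effectively normal
    one) for constrained-family baselines.
    """

    equal_df: bool = False
    tol: float = 1e-6
    max_iter: int = 10000
    fixed_lam: Optional[float] = None
    fixed_nu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class FitResult:
    model: STNMixture
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    posterior: np.ndarray
    n: int
    options: FitOptions = field(default_factory=FitOptions)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def mixture_logpdf(y, m: STNMixture):
    """Log mixture density via log-sum-exp over components."""
    scalar = np.ndim(y) == 0
    y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
    logs = np.log(m.weights)[None, :] + _batch_stn_logpdf(
        y,
        np.array([c.xi for c in m.components]),
        np.array([c.sigma for c in m.components]),
        np.array([c.lam for c in m.components]),
        np.array([c.nu for c in m.components]))
    out = logsumexp(logs, axis=1)
    return float(out[0]) if scalar else out


def mixture_pdf(y, m: STNMixture):
    """Mixture density sum_i w_i psi(y | theta_i); vectorized over y."""
    return np.exp(mixture_logpdf(y, m))


def mixture_cdf(y, m: STNMixture):
    """Mixture cdf as the weight-combination of component cdfs."""
    parts = [w * np.asarray(stn_cdf(y, c))
             for w, c in zip(m.weights, m.components)]
    out = np.sum(parts, axis=0)
    return float(out) if np.ndim(y) == 0 else out


def _batch_stn_logpdf(y: np.ndarray, xi: np.ndarray, sigma: np.ndarray,
                      lam: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """n x g matrix of STN log densities, one gamma-function call per
    component instead of per evaluation."""
    u = (y[:, None] - xi[None, :]) / sigma[None, :]
    lognorm = (np.log(2.0) + special.gammaln((nu + 1.0) / 2.0)
               - special.gammaln(nu / 2.0) - 0.5 * np.log(np.pi * nu)
               - np.log(sigma))
    kernel = -0.5 * (nu + 1.0)[None, :] * np.log1p(u ** 2 / nu[None, :])
    return lognorm[None, :] + kernel + special.log_ndtr(lam[None, :] * u)


def _phi_over_Phi(x: np.ndarray) -> np.ndarray:
    # exp(log phi - log Phi) is stable down to the deep left tail,
    # where the ratio behaves like -x
    return np.exp(-0.5 * x ** 2 - 0.5 * np.log(2 * np.pi)
                  - special.log_ndtr(x))


def e_step(y: np.ndarray, m: STNMixture) -> EStepResult:
    """Conditional expectations of the latent variables given the data.

    All quantities are computed in log space; responsibilities are floored
    at 1e-300 before normalization so numerically empty rows never NaN.
    """
    y = np.asarray(y, dtype=float)
    n, g = y.size, m.g
    xi = np.array([c.xi for c in m.components])
    sigma = np.array([c.sigma for c in m.components])
    lam = np.array([c.lam for c in m.components])
    nu = np.array([c.nu for c in m.components])

    u = (y[:, None] - xi[None, :]) / sigma[None, :]
    logcomp = _batch_stn_logpdf(y, xi, sigma, lam, nu)
    a = logcomp
    a += np.log(m.weights)[None, :]
    amax = a.max(axis=1)
    z = np.exp(a - amax[:, None])
    rowsum = z.sum(axis=1)
    logf = amax + np.log(rowsum)
    z = np.maximum(z / rowsum[:, None], 1e-300)
    z /= z.sum(axis=1, keepdims=True)

    u2 = u ** 2
    tau = (nu[None, :] + 1.0) / (nu[None, :] + u2)
    kappa = special.digamma((nu[None, :] + 1.0) / 2.0) \
        - np.log((nu[None, :] + u2) / 2.0)
    lu = lam[None, :] * u
    gamma1 = lu + _phi_over_Phi(lu)
    return EStepResult(z_hat=z, tau_hat=tau, kappa_hat=kappa,
                       gamma1_hat=gamma1, u=u, loglik=float(logf.sum()))


def _nu_profile_max(b4: float) -> float:
    """argmax over nu of (nu/2)log(nu/2) - logGamma(nu/2) + (nu/2)*b4.

    The stationarity condition log(nu/2) + 1 - digamma(nu/2) + b4 = 0 has a
    strictly decreasing left side, so the root (when bracketed by the nu
    bounds) is the unique maximizer.
    """
    lo, hi = _NU_BOUNDS

    def grad(nu):
        return np.log(nu / 2.0) + 1.0 - special.digamma(nu / 2.0) + b4

    if grad(lo) <= 0:
        return lo
    if grad(hi) >= 0:
        return hi
    return float(optimize.brentq(grad, lo, hi, xtol=1e-8))


def _equal_df_cml(y: np.ndarray, weights: np.ndarray,
                  comps: Sequence[STNParams]) -> float:
    """Shared-nu update maximizing the actual observed log-likelihood."""
    def negll(log_nu):
        nu = float(np.exp(log_nu))
        m = STNMixture(weights, tuple(replace(c, nu=nu) for c in comps))
        return -mixture_logpdf(y, m).sum()

    res = optimize.minimize_scalar(
        negll, bounds=(np.log(_NU_BOUNDS[0]), np.log(_NU_BOUNDS[1])),
        method="bounded", options={"xatol": 1e-6})
    return float(np.exp(res.x))


def cm_step(y: np.ndarray, es: EStepResult, m: STNMixture,
            opts: FitOptions = FitOptions()) -> STNMixture:
    """One pass of conditional-maximization updates.

    Applies, in order, the weight, location, scale, skewness and df updates
    built from the E-step statistics; the skewness and df updates use
    residuals re-standardized at the freshly updated location and scale.
    With ``equal_df`` the shared nu is instead updated by maximizing the
    observed log-likelihood over nu (CML).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    z, tau, kappa, gamma1 = es.z_hat, es.tau_hat, es.kappa_hat, es.gamma1_hat
    sigma_old = np.array([c.sigma for c in m.components])
    lam_old = np.array([c.lam for c in m.components])

    n_i = z.sum(axis=0)
    if np.any(n_i < 2.0):
        raise DegenerateFitError(
            f"effective component sizes {n_i} include an (almost) empty one")
    w_new = n_i / n

    zt = z * tau
    b1 = (zt * y[:, None]).sum(axis=0)
    b2 = z.T @ y
    b3 = (z * gamma1).sum(axis=0)
    xi_new = (b1 + lam_old ** 2 * b2 - sigma_old * lam_old * b3) \
        / (zt.sum(axis=0) + lam_old ** 2 * n_i)

    dev2 = (y[:, None] - xi_new[None, :]) ** 2
    sigma2_new = (zt * dev2).sum(axis=0) / n_i
    if np.any(sigma2_new < 1e-10 * np.var(y)):
        raise DegenerateFitError(
            f"component scale collapsed: sigma2 = {sigma2_new}")

    u_new = (y[:, None] - xi_new[None, :]) / np.sqrt(sigma2_new)[None, :]
    if opts.fixed_lam is not None:
        lam_new = np.full(m.g, float(opts.fixed_lam))
    else:
        lam_new = (z * gamma1 * u_new).sum(axis=0) / (z * u_new ** 2).sum(axis=0)

    if opts.fixed_nu is not None:
        nu_new = np.full(m.g, float(opts.fixed_nu))
        comps = tuple(STNParams(x, s2, l, v) for x, s2, l, v
                      in zip(xi_new, sigma2_new, lam_new, nu_new))
    elif opts.equal_df:
        comps0 = tuple(STNParams(x, s2, l, m.components[0].nu)
                       for x, s2, l in zip(xi_new, sigma2_new, lam_new))
        nu_shared = _equal_df_cml(y, w_new, comps0)
        comps = tuple(replace(c, nu=nu_shared) for c in comps0)
    else:
        b4 = (z * (kappa - tau)).sum(axis=0) / n_i
        nu_new = np.array([_nu_profile_max(b) for b in b4])
        comps = tuple(STNParams(x, s2, l, v) for x, s2, l, v
                      in zip(xi_new, sigma2_new, lam_new, nu_new))
    return STNMixture(w_new, comps)


def _quantile_moment_init(y: np.ndarray, g: int,
                          opts: FitOptions) -> STNMixture:
    """Deterministic start: slice sorted data into g equal blocks and take
    block moments for location and scale; skewness 0, df 10 (unless pinned).
    """
    ys = np.sort(y)
    blocks = np.array_split(ys, g)
    lam0 = 0.0 if opts.fixed_lam is None else float(opts.fixed_lam)
    nu0 = 10.0 if opts.fixed_nu is None else float(opts.fixed_nu)
    var_floor = max(1e-6 * np.var(y), 1e-12)
    comps = tuple(
        STNParams(float(np.mean(b)), float(max(np.var(b), var_floor)),
                  lam0, nu0)
        for b in blocks)
    return STNMixture(np.full(g, 1.0 / g), comps)


def fit_ecme(y: np.ndarray, g: int, opts: FitOptions = None,
             init: STNMixture = None) -> FitResult:
    """Fit a g-component STN mixture by alternating E and CM/CML steps.

    Stops by the Aitken criterion: with a_h = (l_{h+1} - l_h)/(l_h - l_{h-1})
    and l_inf = l_h + (l_{h+1} - l_h)/(1 - a_h), the run terminates when
    |l_{h+1} - l_inf| < tol (skipped for the first two iterations). Failure
    to converge within ``max_iter`` is reported via ``converged=False``,
    never an exception; component collapse raises
    :class:`DegenerateFitError`.
    """
    opts = opts or FitOptions()
    y = np.asarray(y, dtype=float).ravel()
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    if y.size <= 5 * g:
        raise ValueError(f"need n > 5 g = {5 * g} events, got {y.size}")

    model = init if init is not None else _quantile_moment_init(y, g, opts)
    trace = []
    converged = False
    es = e_step(y, model)
    trace.append(es.loglik)
    it = 0
    for it in range(1, opts.max_iter + 1):
        model = cm_step(y, es, model, opts)
        es = e_step(y, model)
        trace.append(es.loglik)
        if len(trace) >= 3:
            l0, l1, l2 = trace[-3], trace[-2], trace[-1]
            d10, d21 = l1 - l0, l2 - l1
            if abs(d21) < 1e-14:  # flat: fully converged
                converged = True
                break
            if abs(d10) > 1e-14:
                a = d21 / d10
                if a < 1.0:
                    l_inf = l1 + d21 / (1.0 - a)
                    if abs(l2 - l_inf) < opts.tol:
                        converged = True
                        break
    return FitResult(model=model, loglik_trace=np.array(trace),
                     converged=converged, n_iter=it, posterior=es.z_hat,
                     n=y.size, options=opts)


def n_free_parameters(g: int, opts: FitOptions) -> int:
    """Free parameters: (g-1) weights + 2g location/scale + skewness + df."""
    d = (g - 1) + 2 * g
    d += 0 if opts.fixed_lam is not None else g
    if opts.fixed_nu is not None:
        pass
    elif opts.equal_df:
        d += 1
    else:
        d += g
    return d


def bic(fit: FitResult) -> float:
    """Bayesian information criterion -2 l_max + d log n; smaller is better."""
    d = n_free_parameters(fit.model.g, fit.options)
    return float(-2.0 * fit.loglik + d * np.log(fit.n))


def sample_mixture(m: STNMixture, n: int, seed) -> np.ndarray:
    """Draw ``n`` events: component labels from the weights, then the STN
    sampler per label. Seeded and reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rng.choice(m.g, size=n, p=m.weights)
    out = np.empty(n)
    for i, c in enumerate(m.components):
        idx = np.flatnonzero(labels == i)
        if idx.size:
            out[idx] = stn_sample(c, idx.size, rng)
    return out
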