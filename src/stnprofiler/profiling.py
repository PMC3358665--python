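"""Quantitative comparison of fitted profiles within and across time.

A "profile" here is the fitted STN mixture for one sample. This module
measures how well a profile fits its data (the Kolmogorov-Smirnov distance
D_n between empirical and fitted cdf), how dispersed the hard-assigned
clusters are (the Gap statistic against uniform references), and how far
two profiles are from each other (the Kullback-Leibler divergence between
the fitted densities), and assembles these per time point into comparison
tables for temporal profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .merging import ClusterPosteriors, MergePath
from .mixture import FitResult, STNMixture, bic, mixture_cdf, mixture_logpdf

__all__ = ["TimePoint", "TemporalProfile", "ks_distance", "kl_distance",
           "gap_statistic", "compare_profiles", "profile_table"]


@dataclass
class TimePoint:
    """One time point of a temporal profile."""

    t: float
    data: np.ndarray
    fit: FitResult
    merge: Optional[MergePath] = None
    summaries: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float).ravel()
        if self.fit.n != self.data.size:
            raise ValueError("fit sample size does not match the data")


@dataclass
class TemporalProfile:
    """Ordered (time, sample, fitted mixture) records for one time course."""

    label: str
    timepoints: list[TimePoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [tp.t for tp in self.timepoints]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("time points must be strictly increasing in t")

    @property
    def times(self) -> np.ndarray:
        return np.array([tp.t for tp in self.timepoints])


def ks_distance(y: np.ndarray, m: STNMixture) -> float:
    """Kolmogorov-Smirnov distance between data and fitted mixture.

    D_n = sup_x |F_n(x) - F(x)|, computed exactly at the order statistics:
    max over i of |i/n - F(y_(i))| and |(i-1)/n - F(y_(i))|.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("need at least one event")
    ys = np.sort(y)
    n = ys.size
    F = np.asarray(mixture_cdf(ys, m))
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(np.abs(i / n - F),
                                   np.abs((i - 1) / n - F))))


def _mixture_ppf(q: float, m: STNMixture) -> float:
    # geometric bracket expansion copes with arbitrarily heavy tails
    scale = max(c.sigma for c in m.components)
    lo = min(c.xi for c in m.components) - 10 * scale
    hi = max(c.xi for c in m.components) + 10 * scale
    step = 10 * scale
    for _ in range(200):
        if mixture_cdf(lo, m) < q:
            break
        lo -= step
        step *= 2
    step = 10 * scale
    for _ in range(200):
        if mixture_cdf(hi, m) > q:
            break
        hi += step
        step *= 2
    return float(optimize.brentq(lambda x: mixture_cdf(x, m) - q, lo, hi,
                                 xtol=1e-8))


def kl_distance(p: STNMixture, q: STNMixture,
                tail_prob: float = 1e-4) -> float:
    """Kullback-Leibler divergence KL(p || q) between fitted mixtures.

    Integrates p log(p/q) by adaptive quadrature over the union of the two
    mixtures' central [tail_prob, 1 - tail_prob] quantile intervals,
    extended by 10% on each side; log densities are floored at -690
    (density 1e-300) so a vanishing q yields a large finite value rather
    than NaN.
    """
    lo = min(_mixture_ppf(tail_prob, p), _mixture_ppf(tail_prob, q))
    hi = max(_mixture_ppf(1 - tail_prob, p), _mixture_ppf(1 - tail_prob, q))
    pad = 0.1 * (hi - lo)
    lo, hi = lo - pad, hi + pad
    floor = np.log(1e-300)

    def integrand(x):
        lp = np.maximum(mixture_logpdf(x, p), floor)
        lq = np.maximum(mixture_logpdf(x, q), floor)
        return np.exp(lp) * (lp - lq)

    # split at the component locations, where skewed densities kink
    knots = sorted({c.xi for c in p.components + q.components
                    if lo < c.xi < hi})
    pts = [lo, *knots, hi]
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        val, _ = integrate.quad(integrand, a, b, epsabs=1e-10, limit=200)
        total += val
    return float(total)


def _within_ss(y: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        yc = y[labels == c]
        w += float(((yc - yc.mean()) ** 2).sum())
    return w


def gap_statistic(y: np.ndarray, cp: ClusterPosteriors,
                  k: Optional[int] = None, B: int = 100,
                  seed=0) -> tuple[float, float]:
    """Gap statistic of the hard clustering induced by the posteriors.

    Events are assigned to their maximum-posterior cluster; W_k is the sum
    of within-cluster squared deviations from cluster means. ``B`` uniform
    reference sets on [min y, max y] are each clustered into ``k``
    quantile-sliced blocks (exact 1-d k-means up to boundaries), and

        Gap(k) = mean_b log W_k(reference_b) - log W_k(y),
        se = sd_b(log W_k(reference)) * sqrt(1 + 1/B).
    """
    y = np.asarray(y, dtype=float).ravel()
    if B < 2:
        raise ValueError(f"need B >= 2 reference sets, got {B}")
    if k is None:
        k = cp.k
    labels = np.argmax(cp.z, axis=1)
    used = np.unique(labels)
    if used.size < cp.k:
        warnings.warn(f"{cp.k - used.size} cluster(s) empty after hard "
                      "assignment; dropped from W_k", stacklevel=2)
    w_obs = _within_ss(y, labels)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logw_ref = np.empty(B)
    for b in range(B):
        ref = rng.uniform(y.min(), y.max(), size=y.size)
        blocks = np.array_split(np.sort(ref), k)
        logw_ref[b] = np.log(sum(float(((blk - blk.mean()) ** 2).sum())
                                 for blk in blocks))
    gap = float(logw_ref.mean() - np.log(w_obs))
    se = float(logw_ref.std(ddof=1) * np.sqrt(1.0 + 1.0 / B))
    return gap, se


def profile_table(profile: TemporalProfile) -> pd.DataFrame:
    """Per-time summary rows: g, weights, locations, skewness, D_n, BIC."""
    rows = []
    for tp in profile.timepoints:
        m = tp.fit.model
        rows.append({
            "t": tp.t,
            "g": m.g,
            "weights": tuple(np.round(m.weights, 4)),
            "locations": tuple(round(c.xi, 4) for c in m.components),
            "skewness": tuple(round(c.lam, 4) for c in m.components),
            "df": tuple(round(c.nu, 4) for c in m.components),
            "D_n": ks_distance(tp.data, m),
            "BIC": bic(tp.fit),
        })
    return pd.DataFrame(rows)


def compare_profiles(a: TemporalProfile, b: TemporalProfile,
                     gap_B: int = 100, seed=0) -> pd.DataFrame:
    """Tabulate profile ``a`` against profile ``b`` time point by time point.

    One row per time point of ``a`` with its model order, weights,
    locations, skewness, D_n, BIC and Gap statistic; for times present in
    both profiles, the KL divergence KL(a_t || b_t) of the fitted
    densities (first argument relative to the second).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b_by_t = {tp.t: tp for tp in b.timepoints}
    tab = profile_table(a)
    gaps, ses, kls = [], [], []
    for tp in a.timepoints:
        cp = ClusterPosteriors(
            z=tp.fit.posterior,
            members=tuple((i,) for i in range(tp.fit.model.g)))
        gap, se = gap_statistic(tp.data, cp, B=gap_B, seed=rng)
        gaps.append(gap)
        ses.append(se)
        other = b_by_t.get(tp.t)
        kls.append(kl_distance(tp.fit.model, other.fit.model)
                   if other is not None else np.nan)
    tab["Gap"] = gaps
    tab["Gap_se"] = ses
    tab["KL_vs_other"] = kls
    return tab
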