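"""Synthetic flow-cytometry time courses with known generating mixtures.

Two scenarios mimic the data classes the profiling pipeline is built for:

``cell-cycle``
    DNA-content histograms with two dominant peaks (1C pre-replication and
    2C post-replication) and a transient, positively skewed S-phase
    subpopulation between them whose weight rises and falls over the
    course (zero at both endpoints by default). Units are arbitrary
    linear fluorescence with the 1C peak near 200 and the 2C peak near
    400, the shape of a typical DNA-stain channel.

``clonal``
    A clonal population dominated by one median state plus an asymmetric
    heavy-tailed outlier subpopulation whose weight decays exponentially
    over time as the outliers relax back toward the median state.

Every generated sample carries its exact generating mixture, so parameter-
and model-order-recovery tests can score fits against the truth. What the
generator does not emulate: instrument measurement floors/saturation,
autofluorescence baselines, debris and doublet events, or correlations
between channels — conclusions from these fixtures speak to the
statistical machinery, not to acquisition artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .mixture import STNMixture, sample_mixture
from .stn import STNParams

__all__ = ["FixtureConfig", "TimecourseSample", "Timecourse",
           "generate_timecourse"]


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic time course.

    ``peak_low``/``peak_high`` are the two persistent endpoints (the
    1C/2C-like peaks, or in the clonal scenario the median state and the
    outlier tail). ``transient`` is the intermediate S-phase-like
    component of the cell-cycle scenario; its weight follows a sinusoidal
    rise-and-fall peaking at ``transient_peak_weight`` mid-course and
    vanishing at both ends. ``decay_rate`` (per unit time) controls how
    fast the clonal outlier weight shrinks from ``outlier_weight0``.
    """

    scenario: Literal["cell-cycle", "clonal"] = "cell-cycle"
    n_times: int = 9
    n_events: int = 2000
    times: np.ndarray | None = None  # defaults to 0..n_times-1 (hours)

    # cell-cycle scenario
    peak_low: STNParams = field(
        default_factory=lambda: STNParams(200.0, 400.0, 1.5, 15.0))
    peak_high: STNParams = field(
        default_factory=lambda: STNParams(400.0, 900.0, -1.5, 15.0))
    transient: STNParams = field(
        default_factory=lambda: STNParams(290.0, 900.0, 3.0, 8.0))
    transient_peak_weight: float = 0.35
    low_fraction: float = 0.55  # share of the non-transient weight on 1C

    # clonal scenario
    median_state: STNParams = field(
        default_factory=lambda: STNParams(100.0, 225.0, 0.0, 25.0))
    outlier_tail: STNParams = field(
        default_factory=lambda: STNParams(160.0, 2500.0, 4.0, 3.0))
    outlier_weight0: float = 0.25
    decay_rate: float = 0.35

    seed: int = 0

    def time_grid(self) -> np.ndarray:
        if self.times is not None:
            return np.asarray(self.times, dtype=float)
        return np.arange(self.n_times, dtype=float)


@dataclass
class TimecourseSample:
    t: float
    y: np.ndarray
    truth: STNMixture


@dataclass
class Timecourse:
    scenario: str
    samples: list[TimecourseSample]

    def __iter__(self):
        return iter(self.samples)


def _cellcycle_mixture(cfg: FixtureConfig, frac: float) -> STNMixture:
    """Generating mixture at relative course position frac in [0, 1]."""
    w_mid = cfg.transient_peak_weight * np.sin(np.pi * frac)
    w_mid = float(np.clip(w_mid, 0.0, 0.95))
    w_low = (1.0 - w_mid) * cfg.low_fraction
    w_high = 1.0 - w_mid - w_low
    if w_mid <= 1e-12:
        return STNMixture([w_low, w_high], (cfg.peak_low, cfg.peak_high))
    return STNMixture([w_low, w_high, w_mid],
                      (cfg.peak_low, cfg.peak_high, cfg.transient))


def _clonal_mixture(cfg: FixtureConfig, t: float) -> STNMixture:
    w_out = cfg.outlier_weight0 * np.exp(-cfg.decay_rate * t)
    if w_out <= 1e-12:
        return STNMixture([1.0], (cfg.median_state,))
    return STNMixture([1.0 - w_out, w_out],
                      (cfg.median_state, cfg.outlier_tail))


def generate_timecourse(cfg: FixtureConfig) -> Timecourse:
    """Sample every time point and record its exact generating mixture.

    Deterministic for a fixed config+seed; each time point gets an
    independent child stream so adding time points never reshuffles
    earlier samples.
    """
    times = cfg.time_grid()
    span = times[-1] - times[0] if times.size > 1 else 1.0
    children = np.random.SeedSequence(cfg.seed).spawn(times.size)
    samples = []
    for t, child in zip(times, children):
        frac = (t - times[0]) / span
        if cfg.scenario == "cell-cycle":
            truth = _cellcycle_mixture(cfg, float(frac))
        elif cfg.scenario == "clonal":
            truth = _clonal_mixture(cfg, float(t - times[0]))
        else:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        y = sample_mixture(truth, cfg.n_events,
                           np.random.default_rng(child))
        samples.append(TimecourseSample(t=float(t), y=y, truth=truth))
    return Timecourse(scenario=cfg.scenario, samples=samples)
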