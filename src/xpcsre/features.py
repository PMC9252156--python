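"""Quantitative extraction of two-time-correlation features.

Four signatures of non-equilibrium dynamics are quantified:

* **tails / modulation** — local maxima of the near-diagonal contrast
  profile.  For a growing system the contrast revives whenever the
  characteristic length crosses an integer multiple of 2*pi/q, so the
  k-th detected tail maps to xi_XPCS = (n0 + k) * 2*pi/q; the spacing
  between adjacent maxima encodes the growth speed (uniform spacing ⇔
  constant speed).
* **square feature** — frozen-in correlation between the epochs before
  and after a split time, measured as the mean of G over the
  off-diagonal block {t1 < t_split < t2}.  Its strength tracks the
  ratio of the early growth rate to the later dissolution rate.
* **coarsening power law** — least-squares exponent of log(xi) vs
  log(t), nominally 1/3 for diffusive/coalescence coarsening.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .correlation import ContrastProfile, TwoTimeCorrelation
from .errors import InsufficientPeaksError, ParameterError

__all__ = [
    "SpacingStats",
    "FeatureReport",
    "detect_tails",
    "xi_from_tails",
    "square_strength",
    "default_split_time",
    "modulation_spacing",
    "fit_power_law",
    "analyze_ttc",
]


def detect_tails(profile: ContrastProfile, prominence: float = 0.05) -> np.ndarray:
    """Age times of contrast maxima with at least the given prominence.

    Endpoints are excluded (a maximum must be interior).  An empty array
    is a valid result — e.g. for a monotonically decaying profile.
    """
    if len(profile) < 5:
        raise ParameterError(f"profile must have >= 5 samples, got {len(profile)}")
    peaks, _ = find_peaks(profile.values, prominence=prominence)
    return profile.t_age[peaks]


def xi_from_tails(
    tail_times: np.ndarray, q: float, n0: int = 1
) -> list[tuple[float, float]]:
    """Characteristic lengths from tail times via the integer-multiple rule.

    The k-th tail (0-based, times sorted ascending) is assigned
    xi = (n0 + k) * 2*pi/q, where ``n0`` indexes the first detectable
    tail (anchored, e.g., on an independent early-size estimate such as
    xi_USAXS at the first tail time).  Returns (t_age, xi) pairs; merging
    the pairs from several q-rings traces xi(t) over a wider window.
    """
    if not q > 0:
        raise ParameterError(f"q must be positive, got {q}")
    if n0 < 1:
        raise ParameterError(f"n0 must be >= 1, got {n0}")
    tail_times = np.asarray(tail_times, dtype=float)
    if tail_times.size and np.any(np.diff(tail_times) < 0):
        raise ParameterError("tail_times must be sorted ascending")
    unit = 2.0 * np.pi / q
    return [(float(t), (n0 + k) * unit) for k, t in enumerate(tail_times)]


def default_split_time(ttc: TwoTimeCorrelation, smooth_window: int = 5) -> float:
    """Automatic split time: maximum-curvature point of the mean diagonal correlation.

    The row means m(t) = <G(t, .)> summarise how strongly each age
    correlates with the rest of the run; the change point where their
    (smoothed) second difference is largest marks the crossover between
    dynamical regimes.  Purely a default — pass an explicit ``t_split``
    when the split is known.
    """
    m = ttc.G.mean(axis=1)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        m = np.convolve(np.pad(m, smooth_window // 2, mode="edge"), kernel, mode="same")[
            smooth_window // 2 : smooth_window // 2 + ttc.n_frames
        ]
    if len(m) < 5:
        raise ParameterError("TTC too short for automatic split detection")
    curv = np.abs(np.diff(m, 2))
    k = int(np.argmax(curv[1:-1])) + 2  # keep the split strictly interior
    return float(ttc.times[k])


def square_strength(ttc: TwoTimeCorrelation, t_split: float | None = None) -> float:
    """Mean of G over the off-diagonal block {t1 < t_split < t2}.

    This is the frozen-in correlation between the pre-split and
    post-split epochs — the square feature's strength.  With no
    ``t_split`` the automatic change point of
    :func:`default_split_time` is used.
    """
    if t_split is None:
        t_split = default_split_time(ttc)
    times = ttc.times
    if not (times[0] < t_split < times[-1]):
        raise ParameterError(
            f"t_split = {t_split} must lie strictly inside ({times[0]}, {times[-1]})"
        )
    before = times < t_split
    after = times > t_split
    block = ttc.G[np.ix_(before, after)]
    if block.size < 4:
        raise ParameterError(
            f"split at t = {t_split} leaves a degenerate block of {block.size} entries"
        )
    return float(block.mean())


@dataclass
class SpacingStats:
    """Spacing statistics of adjacent contrast maxima."""

    mean: float
    sd: float
    spacings: np.ndarray
    nonuniform: bool  # sd/mean > 0.25: growth speed is not constant


def modulation_spacing(
    profile: ContrastProfile, prominence: float = 0.05
) -> SpacingStats:
    """Mean and spread of the spacing between adjacent contrast maxima.

    A relative spread sd/mean above 0.25 flags non-uniform spacing,
    i.e. a growth speed that changes over the run (the contrast is
    periodic only for constant speed).
    """
    tails = detect_tails(profile, prominence=prominence)
    if len(tails) < 2:
        raise InsufficientPeaksError(
            f"found {len(tails)} contrast maxima; spacing needs at least 2"
        )
    spacings = np.diff(tails)
    mean = float(spacings.mean())
    sd = float(spacings.std())
    return SpacingStats(
        mean=mean, sd=sd, spacings=spacings, nonuniform=bool(sd / mean > 0.25)
    )


def fit_power_law(
    t: np.ndarray, xi: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares power-law fit xi = prefactor * t^exponent.

    Linear regression of log(xi) on log(t); returns
    (exponent, prefactor, stderr of the exponent).
    """
    t = np.asarray(t, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if t.size < 4:
        raise ParameterError(f"power-law fit needs >= 4 points, got {t.size}")
    if np.any(t <= 0) or np.any(xi <= 0):
        raise ParameterError("power-law fit requires strictly positive t and xi")
    res = linregress(np.log(t), np.log(xi))
    return float(res.slope), float(np.exp(res.intercept)), float(res.stderr)


@dataclass
class FeatureReport:
    """Detected TTC features of one analysed series at one q-ring."""

    q_center: float
    tail_times: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    xi_points: list[tuple[float, float]] = dc_field(default_factory=list)
    square: float | None = None
    t_split: float | None = None
    modulation_mean_spacing: float | None = None
    modulation_sd_spacing: float | None = None
    modulation_nonuniform: bool | None = None
    power_law_exponent: float | None = None
    power_law_prefactor: float | None = None
    power_law_stderr: float | None = None

    def to_dict(self) -> dict:
        return {
            "q_center": self.q_center,
            "tail_times": list(map(float, self.tail_times)),
            "xi_points": [[float(t), float(x)] for t, x in self.xi_points],
            "square_strength": self.square,
            "t_split": self.t_split,
            "modulation_mean_spacing": self.modulation_mean_spacing,
            "modulation_sd_spacing": self.modulation_sd_spacing,
            "modulation_nonuniform": self.modulation_nonuniform,
            "power_law_exponent": self.power_law_exponent,
            "power_law_prefactor": self.power_law_prefactor,
            "power_law_stderr": self.power_law_stderr,
        }


def analyze_ttc(
    ttc: TwoTimeCorrelation,
    offset: int = 1,
    prominence: float = 0.05,
    n0: int = 1,
    t_split: float | None = None,
    fit_coarsening: bool = False,
) -> FeatureReport:
    """One-stop feature extraction from a TTC (tails, xi, square, spacing)."""
    from .correlation import contrast_profile  # local to avoid cycle at import time

    profile = contrast_profile(ttc, offset=offset)
    tails = detect_tails(profile, prominence=prominence)
    xi_points = xi_from_tails(tails, ttc.q_center, n0=n0)
    report = FeatureReport(q_center=ttc.q_center, tail_times=tails, xi_points=xi_points)
    try:
        report.t_split = t_split if t_split is not None else default_split_time(ttc)
        report.square = square_strength(ttc, report.t_split)
    except ParameterError:
        pass
    if len(tails) >= 2:
        stats = modulation_spacing(profile, prominence=prominence)
        report.modulation_mean_spacing = stats.mean
        report.modulation_sd_spacing = stats.sd
        report.modulation_nonuniform = stats.nonuniform
    if fit_coarsening and len(xi_points) >= 4:
        t = np.array([p[0] for p in xi_points])
        x = np.array([p[1] for p in xi_points])
        if np.all(t > 0):
            exp_, pre, err = fit_power_law(t, x)
            report.power_law_exponent = exp_
            report.power_law_prefactor = pre
            report.power_law_stderr = err
    return report
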