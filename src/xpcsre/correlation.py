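"""Two-time correlation functions over a q-ring, and their 1D cuts.

The two-time correlation function (TTC) correlates speckle intensities
between every pair of times (t1, t2) at fixed momentum transfer, the
average running over the pixels of a q-ring.  The normalized
(Pearson) estimator

    G(q, t1, t2) = cov_p[I(t1), I(t2)] / ( sd_p[I(t1)] * sd_p[I(t2)] )

is the default: it is exactly 1 for frozen speckle and 0 for fully
decorrelated frames, the two limits quoted for slow and fast Brownian
motion.  An unnormalized intensity estimator
<I(t1) I(t2)> / (<I(t1)><I(t2)>) is available for comparison with other
XPCS software.

Derived quantities: the near-diagonal contrast profile (TTC one or more
frames away from the diagonal, indexed by the age time
t_age = (t1 + t2)/2), g2-like cuts at fixed age, and relaxation-time
extraction by 1/e threshold or a Kohlrausch (KWW) fit
g = exp[-2 (tau/tau_r)^gamma].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import NoDecayError, ParameterError
from .scattering import QRing, SpeckleSeries

__all__ = [
    "TwoTimeCorrelation",
    "ContrastProfile",
    "G2Cut",
    "compute_ttc",
    "contrast_profile",
    "g2_cut",
    "relaxation_time",
]


@dataclass
class TwoTimeCorrelation:
    """The G(q, t1, t2) matrix at one q-ring.

    ``valid`` flags frames whose ring intensity had non-zero variance;
    rows/columns of constant frames are set to 0 and masked out.
    """

    G: np.ndarray
    times: np.ndarray
    q_center: float
    q_halfwidth: float
    ring_size: int
    valid: np.ndarray
    estimator: str = "pearson"

    @property
    def n_frames(self) -> int:
        return self.G.shape[0]


def _radial_envelope_normalize(ring_i: np.ndarray, q_ring: np.ndarray) -> np.ndarray:
    """Divide each frame's ring pixels by their instantaneous radial-bin mean.

    A ring of finite q-width carries a static radial intensity envelope
    (the isotropic I(|q|) profile varies across the ring); left in place
    it correlates even fully decorrelated frames.  Flat-fielding each
    frame by its own azimuthal mean per radial sub-bin (equal-count
    quantile bins, >= 32 pixels each) removes the envelope while leaving
    the speckle fluctuations — frozen speckle still correlates at 1.
    """
    n_sub = max(1, min(ring_i.shape[1] // 32, 16))
    if n_sub == 1:
        return ring_i
    edges = np.quantile(q_ring, np.linspace(0.0, 1.0, n_sub + 1))
    idx = np.clip(np.searchsorted(edges, q_ring, side="right") - 1, 0, n_sub - 1)
    out = ring_i.astype(float).copy()
    for b in range(n_sub):
        m = idx == b
        if not m.any():
            continue
        mean_b = out[:, m].mean(axis=1, keepdims=True)
        safe = np.where(mean_b > 0, mean_b, 1.0)
        out[:, m] = out[:, m] / safe
    return out


def compute_ttc(
    series: SpeckleSeries,
    ring: QRing,
    estimator: str = "pearson",
    envelope: str = "radial",
) -> TwoTimeCorrelation:
    """Correlate ring intensities between all frame pairs.

    Parameters
    ----------
    series : speckle series to analyse.
    ring : q-ring whose pixels form the averaging ensemble.  Fewer than
        16 pixels is an error; below 100 a warning is issued (estimator
        noise scales as 1/sqrt(ring size)).
    estimator : "pearson" (normalized covariance, default) or
        "intensity" (<I1 I2>/(<I1><I2>)).
    envelope : "radial" (default) divides each frame by its own radial
        intensity envelope across the ring before correlating (see
        :func:`_radial_envelope_normalize`); "none" correlates the raw
        intensities.
    """
    if estimator not in ("pearson", "intensity"):
        raise ParameterError(f"estimator must be 'pearson' or 'intensity', got {estimator!r}")
    if envelope not in ("radial", "none"):
        raise ParameterError(f"envelope must be 'radial' or 'none', got {envelope!r}")
    if ring.size < 16:
        raise ParameterError(
            f"q-ring has only {ring.size} pixels (< 16); widen q_halfwidth"
        )
    if ring.size < 100:
        warnings.warn(
            f"q-ring has only {ring.size} pixels; TTC estimator noise ~ "
            f"{1.0 / np.sqrt(ring.size):.2f}",
            stacklevel=2,
        )
    stack = series.stack().reshape(len(series), -1)
    ring_i = stack[:, ring.pixel_indices]  # (T, P)
    if envelope == "radial" and estimator == "pearson":
        q_ring = series.qmap.ravel()[ring.pixel_indices]
        ring_i = _radial_envelope_normalize(ring_i, q_ring)
    t = len(series)

    if estimator == "pearson":
        centered = ring_i - ring_i.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        valid = sd > 0
        norm = np.where(valid, sd, 1.0)
        z = centered / norm[:, None]
        G = (z @ z.T) / ring_i.shape[1]
        G = np.clip(G, -1.0, 1.0)
        G[~valid, :] = 0.0
        G[:, ~valid] = 0.0
        d = np.arange(t)
        G[d[valid], d[valid]] = 1.0
        if not np.all(valid):
            warnings.warn(
                f"{int((~valid).sum())} frame(s) have zero ring variance; "
                "their TTC rows are masked as 0",
                stacklevel=2,
            )
    else:
        mean_i = ring_i.mean(axis=1)
        valid = mean_i > 0
        norm = np.where(valid, mean_i, 1.0)
        G = (ring_i @ ring_i.T) / ring_i.shape[1]
        G /= np.outer(norm, norm)
        G[~valid, :] = 0.0
        G[:, ~valid] = 0.0
        if not np.all(valid):
            warnings.warn(
                f"{int((~valid).sum())} frame(s) have zero mean ring intensity; masked",
                stacklevel=2,
            )

    return TwoTimeCorrelation(
        G=G,
        times=series.times,
        q_center=ring.q_center,
        q_halfwidth=ring.q_halfwidth,
        ring_size=ring.size,
        valid=valid,
        estimator=estimator,
    )


@dataclass
class ContrastProfile:
    """TTC values at a fixed off-diagonal offset, vs age time (t1 + t2)/2."""

    values: np.ndarray
    t_age: np.ndarray
    offset: int

    def __len__(self) -> int:
        return len(self.values)


def contrast_profile(ttc: TwoTimeCorrelation, offset: int = 1) -> ContrastProfile:
    """Near-diagonal contrast: values[k] = G(k, k + offset), indexed by pair midpoint age."""
    n = ttc.n_frames
    if not 1 <= offset < n:
        raise ParameterError(f"offset must satisfy 1 <= offset < n_frames ({n}), got {offset}")
    idx = np.arange(n - offset)
    values = ttc.G[idx, idx + offset]
    t_age = 0.5 * (ttc.times[idx] + ttc.times[idx + offset])
    return ContrastProfile(values=values, t_age=t_age, offset=offset)


@dataclass
class G2Cut:
    """A g2-like correlation decay vs delay tau at fixed age time."""

    tau: np.ndarray
    values: np.ndarray
    t_age: float
    mode: str


def g2_cut(
    ttc: TwoTimeCorrelation,
    t_age: float,
    mode: str = "row",
    band_halfwidth: int = 2,
) -> G2Cut:
    """Cut the TTC at a fixed age.

    ``row`` mode returns G(t_age, t_age + tau) for tau >= 0.
    ``diagonal_band`` averages row cuts over ages within
    ``band_halfwidth`` frames of t_age (truncated at the matrix edge
    with a warning).
    """
    if mode not in ("row", "diagonal_band"):
        raise ParameterError(f"mode must be 'row' or 'diagonal_band', got {mode!r}")
    times = ttc.times
    if not (times[0] <= t_age <= times[-1]):
        raise ParameterError(
            f"t_age = {t_age} outside the series time range [{times[0]}, {times[-1]}]"
        )
    k = int(np.argmin(np.abs(times - t_age)))
    n = ttc.n_frames
    if mode == "row":
        values = ttc.G[k, k:]
        tau = times[k:] - times[k]
        return G2Cut(tau=tau, values=values.copy(), t_age=float(times[k]), mode=mode)

    lo, hi = k - band_halfwidth, k + band_halfwidth + 1
    if lo < 0 or hi > n:
        warnings.warn("diagonal band exceeds the TTC; truncating", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, n)
    max_tau = n - hi + 1  # delays available to every row in the band
    rows = [ttc.G[j, j : j + max_tau] for j in range(lo, hi)]
    values = np.mean(rows, axis=0)
    dt = times[1] - times[0] if n > 1 else 1.0
    tau = np.arange(max_tau) * dt
    return G2Cut(tau=tau, values=values, t_age=float(times[k]), mode=mode)


def _kww(tau: np.ndarray, tau_r: float, gamma: float) -> np.ndarray:
    return np.exp(-2.0 * (tau / tau_r) ** gamma)


def relaxation_time(cut: G2Cut, method: str = "threshold") -> tuple[float, float | None]:
    """Relaxation time of a correlation cut.

    ``threshold``: first delay where the correlation drops below 1/e,
    linearly interpolated between samples; returns (tau_relax, None).
    ``kww``: least-squares fit of exp[-2 (tau/tau_r)^gamma]; returns
    (tau_r, gamma).

    Raises :class:`NoDecayError` if the cut never crosses 1/e
    (threshold method) — frozen dynamics, distinct from a fit failure.
    """
    if method not in ("threshold", "kww"):
        raise ParameterError(f"method must be 'threshold' or 'kww', got {method!r}")
    tau, g = cut.tau, cut.values
    if method == "threshold":
        level = np.exp(-1.0)
        below = np.flatnonzero(g < level)
        below = below[below > 0]
        if below.size == 0:
            raise NoDecayError(
                "correlation never decays below 1/e within the cut (frozen dynamics)"
            )
        j = int(below[0])
        g0, g1 = g[j - 1], g[j]
        frac = (g0 - level) / (g0 - g1)
        return float(tau[j - 1] + frac * (tau[j] - tau[j - 1])), None

    pos = tau > 0
    if pos.sum() < 3:
        raise ParameterError("kww fit needs at least 3 positive-delay samples")
    guess_tau = float(tau[pos][len(tau[pos]) // 2])
    popt, _ = curve_fit(
        _kww,
        tau[pos],
        g[pos],
        p0=(guess_tau, 1.0),
        bounds=([tau[pos][0] * 1e-3, 0.1], [tau[-1] * 1e3, 3.0]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])
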