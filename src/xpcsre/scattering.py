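"""Speckle synthesis and reciprocal-space bookkeeping.

A coherent-scattering speckle frame is synthesized from a real-space
concentration map as the squared magnitude of the 2D FFT of the
concentration *fluctuations* (mean removed), zero frequency shifted to
the frame centre.  For simulated fields the per-pixel momentum transfer
is q = 2*pi*k/(N*dx) in inverse rescaled-length units; for experimental
detector stacks a :class:`Geometry` converts pixel position to physical
q (nm^-1) via the elastic-scattering relation q = (4*pi/lambda) sin(theta),
2*theta the scattering angle.

The module also provides azimuthal (radial) intensity profiles, the
scattering-peak characteristic length xi_USAXS = 2*pi/q_peak, q-ring pixel
selection for the correlation analysis, and additive detector noise with
a constant amplitude tied to the series-maximum intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .ch import ConcentrationField, FieldSeries
from .errors import EmptyRingError, OutOfWindowError, ParameterError

__all__ = [
    "HC_KEV_ANGSTROM",
    "Geometry",
    "SpeckleFrame",
    "SpeckleSeries",
    "QRing",
    "RadialProfile",
    "energy_to_wavelength",
    "q_map_physical",
    "q_map_simulation",
    "speckle_from_field",
    "speckle_series",
    "radial_profile",
    "xi_usaxs",
    "make_q_ring",
    "select_analysis_q",
    "add_noise",
]

#: hc in keV * Angstrom: lambda[A] = HC_KEV_ANGSTROM / E[keV]
HC_KEV_ANGSTROM = 12.398419843


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in Angstrom from energy in keV (lambda = hc/E)."""
    if not energy_kev > 0:
        raise ParameterError(f"energy_kev must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


@dataclass(frozen=True)
class Geometry:
    """Small-angle scattering geometry of a 2D detector.

    Attributes
    ----------
    photon_energy : incident energy in keV.
    detector_distance : sample-to-detector distance in metres.
    pixel_size : detector pixel pitch in micrometres.
    beam_center : (row, col) of the direct beam in pixels.
    """

    photon_energy: float
    detector_distance: float
    pixel_size: float
    beam_center: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.photon_energy > 0:
            raise ParameterError(f"photon_energy must be positive, got {self.photon_energy}")
        if not self.detector_distance > 0:
            raise ParameterError(
                f"detector_distance must be positive, got {self.detector_distance}"
            )
        if not self.pixel_size > 0:
            raise ParameterError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def wavelength(self) -> float:
        """Wavelength in Angstrom, derived from the photon energy."""
        return energy_to_wavelength(self.photon_energy)


def q_map_physical(geometry: Geometry, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel |q| in nm^-1 for a detector of the given shape.

    Exact elastic-scattering relation: for a pixel at radial distance d
    from the beam centre, theta = arctan(d * pixel / distance) / 2 and
    q = (4*pi/lambda) sin(theta).
    """
    rows = np.arange(shape[0])[:, None] - geometry.beam_center[0]
    cols = np.arange(shape[1])[None, :] - geometry.beam_center[1]
    d_m = np.hypot(rows, cols) * geometry.pixel_size * 1e-6
    theta = 0.5 * np.arctan2(d_m, geometry.detector_distance)
    wavelength_nm = geometry.wavelength * 0.1
    return (4.0 * np.pi / wavelength_nm) * np.sin(theta)


def q_map_simulation(n: int, dx: float = 1.0) -> np.ndarray:
    """Per-pixel |q| = 2*pi*|k|/(N*dx) on the centred FFT grid of an N x N field."""
    f = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    qx = 2.0 * np.pi * f
    return np.hypot(qx[:, None], qx[None, :])


@dataclass
class SpeckleFrame:
    """One zero-frequency-centred speckle (intensity) frame."""

    intensity: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ParameterError("intensity must be a 2D array")
        if np.any(self.intensity < 0):
            raise ParameterError("intensity must be non-negative")


@dataclass
class SpeckleSeries:
    """A time-ordered speckle stack with its per-pixel q-map."""

    frames: list[SpeckleFrame]
    qmap: np.ndarray
    geometry: Geometry | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ParameterError("frames must be non-empty")
        shapes = {f.intensity.shape for f in self.frames}
        if len(shapes) != 1:
            raise ParameterError("all frames must share the same shape")
        self.qmap = np.asarray(self.qmap, dtype=float)
        if self.qmap.shape != self.frames[0].intensity.shape:
            raise ParameterError("qmap shape must match the frame shape")
        t = self.times
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ParameterError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k: int) -> SpeckleFrame:
        return self.frames[k]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].intensity.shape

    def stack(self) -> np.ndarray:
        return np.stack([f.intensity for f in self.frames])

    @property
    def center_index(self) -> tuple[int, int]:
        """Index of the zero-frequency pixel (exact for synthesized series,
        nearest-q pixel otherwise)."""
        flat = int(np.argmin(self.qmap))
        return np.unravel_index(flat, self.qmap.shape)  # type: ignore[return-value]


def speckle_from_field(field: ConcentrationField) -> SpeckleFrame:
    """|FFT2(u - <u>)|^2 with the zero frequency shifted to the centre.

    The unnormalized forward FFT convention is used; only intensity
    ratios enter the correlation analysis, so the normalization is a
    bookkeeping choice.  Removing the spatial mean makes the central
    pixel exactly zero.
    """
    u = field.values
    fluct = u - u.mean()
    amp = np.fft.fftshift(np.fft.fft2(fluct))
    return SpeckleFrame(intensity=np.abs(amp) ** 2, time=field.time)


def speckle_series(series: FieldSeries) -> SpeckleSeries:
    """Synthesize the speckle series of a field series (simulation q units)."""
    frames = [speckle_from_field(f) for f in series]
    n = series[0].grid_n
    return SpeckleSeries(frames=frames, qmap=q_map_simulation(n, series.dx))


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs |q| (equal-width bins)."""

    q: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.q) == len(self.intensity) == len(self.counts)):
            raise ParameterError("q, intensity and counts must have equal length")


def radial_profile(
    intensity: np.ndarray, qmap: np.ndarray, n_bins: int | None = None
) -> RadialProfile:
    """Azimuthal mean of ``intensity`` in equal-width |q| bins.

    The q = 0 pixel is excluded.  Empty bins are reported with count 0
    and NaN mean.  Default bin count is N/4 for an N-pixel-wide map.
    """
    intensity = np.asarray(intensity, dtype=float)
    if n_bins is None:
        n_bins = max(4, intensity.shape[0] // 4)
    if n_bins < 4:
        raise ParameterError(f"n_bins must be >= 4, got {n_bins}")
    q = np.asarray(qmap, dtype=float).ravel()
    i = intensity.ravel()
    keep = q > 0
    q, i = q[keep], i[keep]
    edges = np.linspace(0.0, q.max(), n_bins + 1)
    idx = np.clip(np.digitize(q, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=i, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(q=centers, intensity=mean, counts=counts)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="same")[pad : pad + len(y)]


def xi_usaxs(
    profile: RadialProfile, smooth_window: int = 1, refine: bool = True
) -> tuple[float, float]:
    """Peak position of the radial profile and xi_USAXS = 2*pi/q_peak.

    The peak is the argmax of the (optionally box-smoothed) profile with
    the first and last bins excluded; a peak landing on a boundary bin
    raises :class:`OutOfWindowError` (the peak has left the measurement
    window).  With ``refine=True`` a parabolic fit through the peak bin
    and its neighbours gives sub-bin resolution.
    """
    y = profile.intensity.copy()
    y[profile.counts == 0] = -np.inf
    y = np.where(np.isfinite(y), y, -np.inf)
    ys = _smooth(np.where(np.isfinite(y), y, 0.0), smooth_window)
    ys[~np.isfinite(y)] = -np.inf
    if len(ys) < 3 or not np.any(np.isfinite(ys)):
        raise OutOfWindowError("radial profile too short or empty for peak search")
    k = int(np.argmax(ys[1:-1])) + 1
    if ys[k] <= ys[0] or ys[k] <= ys[-1] or not np.isfinite(ys[k]):
        raise OutOfWindowError(
            "intensity maximum sits on the edge of the q window; "
            "the scattering peak has moved out of the measurement window"
        )
    q_peak = float(profile.q[k])
    if refine and np.isfinite(ys[k - 1]) and np.isfinite(ys[k + 1]):
        y0, y1, y2 = ys[k - 1], ys[k], ys[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper local maximum
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            q_peak = float(profile.q[k] + shift * (profile.q[1] - profile.q[0]))
    return q_peak, 2.0 * np.pi / q_peak


@dataclass
class QRing:
    """The set of detector pixels with |q| within q_center +/- q_halfwidth."""

    q_center: float
    q_halfwidth: float
    pixel_indices: np.ndarray  # flat indices into a frame

    def __post_init__(self) -> None:
        self.pixel_indices = np.asarray(self.pixel_indices, dtype=np.intp)
        if self.pixel_indices.size == 0:
            raise EmptyRingError(
                f"q-ring at q = {self.q_center} +/- {self.q_halfwidth} contains no pixels; "
                "increase q_halfwidth"
            )

    @property
    def size(self) -> int:
        return int(self.pixel_indices.size)


def make_q_ring(series: SpeckleSeries, q_center: float, q_halfwidth: float) -> QRing:
    """Select the ring pixels {p : |q_p - q_center| <= q_halfwidth}, excluding q = 0."""
    if q_halfwidth <= 0:
        raise ParameterError(f"q_halfwidth must be positive, got {q_halfwidth}")
    q = series.qmap.ravel()
    mask = (np.abs(q - q_center) <= q_halfwidth) & (q > 0)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptyRingError(
            f"q-ring at q = {q_center} +/- {q_halfwidth} contains no pixels; "
            "increase q_halfwidth"
        )
    return QRing(q_center=q_center, q_halfwidth=q_halfwidth, pixel_indices=idx)


def select_analysis_q(
    series: SpeckleSeries, early_frames: int = 5, n_bins: int | None = None
) -> float:
    """Analysis momentum transfer: early-stage scattering-peak position.

    Returns the radial-profile peak q averaged over the first
    ``early_frames`` frames that exhibit an interior peak (frames before
    the structure factor has developed — e.g. the initial noise of a
    quench — are skipped), mirroring the practice of correlating near
    the early-stage structure-factor peak.  ``early_frames`` larger than
    the series is clipped with a warning.
    """
    if early_frames < 1:
        raise ParameterError(f"early_frames must be >= 1, got {early_frames}")
    if early_frames > len(series):
        warnings.warn(
            f"early_frames = {early_frames} exceeds the series length {len(series)}; clipping",
            stacklevel=2,
        )
        early_frames = len(series)
    peaks: list[float] = []
    for frame in series.frames:
        try:
            prof = radial_profile(frame.intensity, series.qmap, n_bins=n_bins)
            q_peak, _ = xi_usaxs(prof)
        except OutOfWindowError:
            continue
        peaks.append(q_peak)
        if len(peaks) >= early_frames:
            break
    if not peaks:
        raise OutOfWindowError("no frame in the series shows an interior scattering peak")
    return float(np.mean(peaks))


def add_noise(series: SpeckleSeries, fraction: float, seed: int = 0) -> SpeckleSeries:
    """Add i.i.d. uniform noise on [0, fraction * I_max] to every pixel of every frame.

    ``I_max`` is the maximum intensity over the whole input series, so
    the noise amplitude is constant across frames while the signal
    evolves — the mechanism behind time-dependent near-diagonal contrast.
    Uniform (rather than Gaussian) noise keeps intensities non-negative.
    """
    if fraction < 0:
        raise ParameterError(f"fraction must be >= 0, got {fraction}")
    if fraction == 0:
        frames = [SpeckleFrame(intensity=f.intensity.copy(), time=f.time) for f in series.frames]
        return SpeckleSeries(frames=frames, qmap=series.qmap.copy(), geometry=series.geometry)
    rng = np.random.default_rng(seed)
    i_max = max(float(f.intensity.max()) for f in series.frames)
    amplitude = fraction * i_max
    frames = [
        SpeckleFrame(
            intensity=f.intensity + rng.uniform(0.0, amplitude, size=f.intensity.shape),
            time=f.time,
        )
        for f in series.frames
    ]
    return SpeckleSeries(frames=frames, qmap=series.qmap.copy(), geometry=series.geometry)
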