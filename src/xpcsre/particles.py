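"""Particle-based heuristic simulator of phase-separation domains.

Domains are modelled as 2D disks (or ellipses) at random positions on a
periodic grid, with *programmable* radius, shape, concentration and
motion schedules.  The concentration is constant inside the domains
(``u_in``, default -1, the dilute phase) and outside them (``u_out``,
default +1, the dense phase); rasterizing the ensemble frame by frame
yields a concentration-field series that feeds the same speckle/TTC
pipeline as the phase-field solver.  Decoupling growth, dissolution,
shape change, concentration contrast and Brownian motion into separate
schedules is what lets each TTC feature be traced back to one control
parameter.

Conventions:

* Radius schedules are piecewise linear in time and act as *offsets*:
  particle i has radius ``max(0, r0_i + S(t) - S(0))`` where ``r0_i`` is
  its sampled initial radius.  A particle whose radius reaches 0 has
  dissolved; schedules clamp outside their control-point range.
* Ellipse shape change preserves area: for axis ratio rho (minor/major,
  in (0, 1]) the semi-axes are ``r/sqrt(rho)`` and ``r*sqrt(rho)``, so a
  pure shape change does not alter the amount of either phase.
  Orientations are fixed per particle, drawn uniformly at placement.
* Brownian motion is an uncorrelated Gaussian random walk per frame
  (no inertia, no hydrodynamics); the per-axis step RMS ``step_sigma``
  may itself follow a schedule to emulate the slowdown that accompanies
  domain growth and rising dense-phase viscosity.
* Overlapping particles are the union of their interiors (no excluded
  volume); positions and rasterized shapes wrap periodically, matching
  the periodic FFT used for speckle synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .ch import ConcentrationField, FieldSeries
from .errors import ParameterError, PlacementError

__all__ = [
    "PiecewiseLinear",
    "RadiusSchedule",
    "ShapeSchedule",
    "MotionSpec",
    "ParticleEnsembleSpec",
    "Ensemble",
    "SCENARIO_NAMES",
    "as_schedule",
    "radius_at",
    "sample_ensemble",
    "step_positions",
    "rasterize",
    "simulate",
    "build_scenario",
]


@dataclass(frozen=True)
class PiecewiseLinear:
    """A piecewise-linear function of time; clamps to the nearest endpoint outside."""

    control_points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.control_points) == 0:
            raise ParameterError("control_points must be non-empty")
        t = np.array([p[0] for p in self.control_points], dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ParameterError("control-point times must be strictly increasing")

    def at(self, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        pts = np.asarray(self.control_points, dtype=float)
        out = np.interp(t, pts[:, 0], pts[:, 1])
        return float(out) if np.isscalar(t) else out


ScheduleLike = Union[float, int, Sequence[tuple[float, float]], PiecewiseLinear]


def as_schedule(value: ScheduleLike) -> PiecewiseLinear:
    """Coerce a constant or a list of (time, value) pairs into a schedule."""
    if isinstance(value, PiecewiseLinear):
        return value
    if isinstance(value, (int, float)):
        return PiecewiseLinear(((0.0, float(value)),))
    return PiecewiseLinear(tuple((float(t), float(v)) for t, v in value))


class RadiusSchedule(PiecewiseLinear):
    """Piecewise-linear radius-offset schedule (see module notes on semantics)."""

    def __post_init__(self) -> None:
        super().__post_init__()


def radius_at(schedule: PiecewiseLinear, t: float) -> float:
    """Schedule value at time t (linear interpolation, clamped outside the range)."""
    return float(schedule.at(t))


@dataclass(frozen=True)
class ShapeSchedule:
    """Ellipse axis-ratio (minor/major) schedule; ratio 1 is a disk."""

    axis_ratio: PiecewiseLinear

    def __post_init__(self) -> None:
        vals = np.array([v for _, v in self.axis_ratio.control_points])
        if np.any(vals <= 0) or np.any(vals > 1):
            raise ParameterError("axis_ratio values must lie in (0, 1]")

    @classmethod
    def constant(cls, ratio: float = 1.0) -> "ShapeSchedule":
        return cls(axis_ratio=as_schedule(ratio))

    @classmethod
    def from_points(cls, points: Sequence[tuple[float, float]]) -> "ShapeSchedule":
        return cls(axis_ratio=as_schedule(points))


@dataclass(frozen=True)
class MotionSpec:
    """Domain motion model: frozen positions or a Gaussian random walk.

    ``step_sigma`` is the per-frame RMS displacement per axis in pixels,
    either a constant or a schedule of time.
    """

    kind: str = "static"
    step_sigma: ScheduleLike = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "random_walk"):
            raise ParameterError(f"motion kind must be 'static' or 'random_walk', got {self.kind!r}")
        sched = as_schedule(self.step_sigma)
        if any(v < 0 for _, v in sched.control_points):
            raise ParameterError("step_sigma must be >= 0")
        if self.kind == "static" and any(v != 0 for _, v in sched.control_points):
            raise ParameterError("static motion requires step_sigma = 0")

    def sigma_at(self, t: float) -> float:
        return float(as_schedule(self.step_sigma).at(t))


@dataclass(frozen=True)
class ParticleEnsembleSpec:
    """Full description of a particle-ensemble scenario.

    ``radius_schedule`` may be a single schedule (shared by all
    particles), a short list (particles split into contiguous groups by
    ascending initial-radius rank — e.g. a dissolving and a growing
    Ostwald population), or one schedule per particle (rank-ordered,
    smallest first).
    """

    n_particles: int = 200
    box_n: int = 512
    radius_mean: float = 4.0
    radius_spread: float = 0.0
    radius_dist: str = "normal"
    radius_schedule: Union[PiecewiseLinear, Sequence[PiecewiseLinear]] = dc_field(
        default_factory=lambda: as_schedule(0.0)
    )
    shape_schedule: ShapeSchedule | None = None
    motion: MotionSpec = dc_field(default_factory=MotionSpec)
    u_in: ScheduleLike = -1.0
    u_out: ScheduleLike = 1.0
    min_separation: float = 0.0
    frame_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ParameterError(f"n_particles must be >= 1, got {self.n_particles}")
        if self.box_n < 32:
            raise ParameterError(f"box_n must be >= 32, got {self.box_n}")
        if self.radius_mean <= 0:
            raise ParameterError(f"radius_mean must be positive, got {self.radius_mean}")
        if self.radius_spread < 0:
            raise ParameterError(f"radius_spread must be >= 0, got {self.radius_spread}")
        if self.radius_dist not in ("normal", "uniform"):
            raise ParameterError(
                f"radius_dist must be 'normal' or 'uniform', got {self.radius_dist!r}"
            )
        if self.min_separation < 0:
            raise ParameterError(f"min_separation must be >= 0, got {self.min_separation}")
        if self.frame_interval <= 0:
            raise ParameterError(f"frame_interval must be positive, got {self.frame_interval}")

    @property
    def schedules(self) -> tuple[PiecewiseLinear, ...]:
        rs = self.radius_schedule
        if isinstance(rs, PiecewiseLinear):
            return (rs,)
        return tuple(rs)

    def u_in_at(self, t: float) -> float:
        return float(as_schedule(self.u_in).at(t))

    def u_out_at(self, t: float) -> float:
        return float(as_schedule(self.u_out).at(t))


@dataclass
class Ensemble:
    """A realised ensemble: trajectories plus per-particle static attributes."""

    spec: ParticleEnsembleSpec
    positions: np.ndarray  # (n_frames, n_particles, 2), wrapped into [0, box_n)
    radii0: np.ndarray  # (n_particles,)
    orientations: np.ndarray  # (n_particles,) radians
    schedule_index: np.ndarray  # (n_particles,) index into spec.schedules

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.spec.frame_interval

    def radii_at(self, t: float) -> np.ndarray:
        """Per-particle radii at time t (offset semantics, clamped at 0)."""
        scheds = self.spec.schedules
        offsets = np.array([s.at(t) - s.at(0.0) for s in scheds])
        return np.maximum(0.0, self.radii0 + offsets[self.schedule_index])


def _draw_radii(spec: ParticleEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.radius_spread == 0:
        return np.full(spec.n_particles, spec.radius_mean)
    if spec.radius_dist == "uniform":
        r = rng.uniform(
            spec.radius_mean - spec.radius_spread,
            spec.radius_mean + spec.radius_spread,
            size=spec.n_particles,
        )
        return np.maximum(r, 0.0)
    # truncated normal: resample draws that land at or below zero
    r = rng.normal(spec.radius_mean, spec.radius_spread, size=spec.n_particles)
    for _ in range(100):
        bad = r <= 0
        if not bad.any():
            break
        r[bad] = rng.normal(spec.radius_mean, spec.radius_spread, size=int(bad.sum()))
    return np.maximum(r, 1e-6)


def _place_particles(spec: ParticleEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    n, box = spec.n_particles, spec.box_n
    if spec.min_separation == 0:
        return rng.uniform(0.0, box, size=(n, 2))
    placed = np.empty((n, 2))
    attempts = 0
    budget = 100_000
    k = 0
    while k < n:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n} particles with min_separation = "
                f"{spec.min_separation} in a {box}x{box} box after {budget} attempts"
            )
        cand = rng.uniform(0.0, box, size=2)
        attempts += 1
        if k > 0:
            d = placed[:k] - cand
            d -= box * np.round(d / box)  # minimal image
            if np.any(np.hypot(d[:, 0], d[:, 1]) < spec.min_separation):
                continue
        placed[k] = cand
        k += 1
    return placed


def step_positions(
    positions: np.ndarray, step_sigma: float, box_n: int, rng: np.random.Generator
) -> np.ndarray:
    """One random-walk step: i.i.d. Gaussian displacement per axis, wrapped periodically."""
    new = positions + rng.normal(0.0, step_sigma, size=positions.shape)
    return np.mod(new, box_n)


def sample_ensemble(spec: ParticleEnsembleSpec, n_frames: int) -> Ensemble:
    """Draw the ensemble and integrate its motion for ``n_frames`` frames.

    All randomness (placement, initial radii, orientations, random walk)
    derives from ``spec.seed``, so the realisation is reproducible.
    Radius schedules are assigned by ascending initial-radius rank:
    with g schedules for n particles, the smallest n/g particles follow
    the first schedule, and so on (smallest particles first — the
    Ostwald-ripening ordering).
    """
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    rng = np.random.default_rng(spec.seed)
    radii0 = _draw_radii(spec, rng)
    pos0 = _place_particles(spec, rng)
    orientations = rng.uniform(0.0, np.pi, size=spec.n_particles)

    scheds = spec.schedules
    schedule_index = np.zeros(spec.n_particles, dtype=int)
    if len(scheds) > 1:
        rank = np.argsort(np.argsort(radii0, kind="stable"), kind="stable")
        group = (rank * len(scheds)) // spec.n_particles
        schedule_index = np.minimum(group, len(scheds) - 1)

    positions = np.empty((n_frames, spec.n_particles, 2))
    positions[0] = pos0
    if spec.motion.kind == "random_walk":
        for f in range(1, n_frames):
            sigma = spec.motion.sigma_at(f * spec.frame_interval)
            positions[f] = step_positions(positions[f - 1], sigma, spec.box_n, rng)
    else:
        positions[1:] = pos0[None, :, :]
    return Ensemble(
        spec=spec,
        positions=positions,
        radii0=radii0,
        orientations=orientations,
        schedule_index=schedule_index,
    )


def _paint_ellipse(
    field: np.ndarray,
    center: np.ndarray,
    a: float,
    b: float,
    theta: float,
    value: float,
) -> None:
    """Set pixels whose centres fall inside the (periodically wrapped) ellipse."""
    n = field.shape[0]
    h = int(math.ceil(a)) + 1
    cx, cy = center
    if 2 * h + 1 >= n:
        ix = np.arange(n)
        dx = ix[:, None] - cx
        dy = ix[None, :] - cy
        dx -= n * np.round(dx / n)
        dy -= n * np.round(dy / n)
    else:
        ix = np.arange(int(math.floor(cx)) - h, int(math.floor(cx)) + h + 1)
        iy = np.arange(int(math.floor(cy)) - h, int(math.floor(cy)) + h + 1)
        dx = (ix[:, None] - cx).astype(float)
        dy = (iy[None, :] - cy).astype(float)
    c, s = math.cos(theta), math.sin(theta)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    if 2 * h + 1 >= n:
        field[inside] = value
    else:
        rows = np.mod(ix, n)
        cols = np.mod(iy, n)
        sub = field[np.ix_(rows, cols)]
        sub[inside] = value
        field[np.ix_(rows, cols)] = sub


def rasterize(ensemble: Ensemble, frame: int) -> ConcentrationField:
    """Paint frame ``frame`` of the ensemble onto the concentration grid.

    Pixel centres inside any (wrapped) particle take ``u_in(t)``; all
    others take ``u_out(t)``.  Overlaps are the union of interiors.
    """
    if not 0 <= frame < ensemble.n_frames:
        raise ParameterError(f"frame {frame} outside trajectory of length {ensemble.n_frames}")
    spec = ensemble.spec
    t = float(ensemble.times[frame])
    u_in, u_out = spec.u_in_at(t), spec.u_out_at(t)
    if u_in == u_out:
        raise ParameterError(f"u_in and u_out coincide ({u_in}) at t = {t}")
    field = np.full((spec.box_n, spec.box_n), u_out, dtype=float)
    radii = ensemble.radii_at(t)
    ratio = 1.0
    if spec.shape_schedule is not None:
        ratio = float(spec.shape_schedule.axis_ratio.at(t))
    sq = math.sqrt(ratio)
    for p in range(ensemble.n_particles):
        r = radii[p]
        if r <= 0:
            continue
        a, b = r / sq, r * sq
        _paint_ellipse(field, ensemble.positions[frame, p], a, b, ensemble.orientations[p], u_in)
    return ConcentrationField(values=field, time=t, dx=1.0)


def simulate(spec: ParticleEnsembleSpec, n_frames: int) -> FieldSeries:
    """Sample the ensemble and rasterize every frame into a field series."""
    ensemble = sample_ensemble(spec, n_frames)
    fields = [rasterize(ensemble, f) for f in range(n_frames)]
    return FieldSeries(fields=fields, sample_interval=spec.frame_interval)


SCENARIO_NAMES = (
    "linear_growth",
    "growth_distribution",
    "nonlinear_growth",
    "two_step_growth_dissolution",
    "shape_change",
    "concentration_ramp",
    "brownian",
    "brownian_plus_growth",
    "early_stage_llps",
)


def _two_step_schedules(
    n_particles: int,
    duration: float,
    rate_ratio: float,
    growth_rate: float,
    stagger_fraction: float,
) -> list[PiecewiseLinear]:
    """Per-particle schedules: common growth, then staggered dissolution.

    Stage 1 (first 30% of the run): every particle grows at
    ``growth_rate``.  Stage 2: particles start dissolving at
    ``growth_rate / rate_ratio``, smallest first, with onsets staggered
    over ``stagger_fraction`` of the run — the Ostwald-ripening ordering
    in which small domains are the first to dissolve.  ``rate_ratio``
    of infinity means no dissolution (sizes freeze after stage 1).
    """
    t_grow = 0.3 * duration
    peak = growth_rate * t_grow
    if not np.isfinite(rate_ratio):
        return [as_schedule([(0.0, 0.0), (t_grow, peak)])] * 1
    if rate_ratio <= 0:
        raise ParameterError(f"rate_ratio must be positive, got {rate_ratio}")
    d_rate = growth_rate / rate_ratio
    stagger = stagger_fraction * duration
    scheds: list[PiecewiseLinear] = []
    for i in range(n_particles):
        delay = stagger * i / max(n_particles - 1, 1)
        t_on = t_grow + delay
        # dissolve well past zero offset so every particle can reach extinction
        t_end = max(duration, t_on + 1.0) + 1.0
        v_end = peak - d_rate * (t_end - t_on)
        points = [(0.0, 0.0), (t_grow, peak)]
        if t_on > t_grow:
            points.append((t_on, peak))
        points.append((t_end, v_end))
        scheds.append(as_schedule(points))
    return scheds


def build_scenario(
    name: str,
    overrides: Mapping[str, object] | None = None,
    *,
    duration: float = 200.0,
    n_particles: int = 200,
    box_n: int = 512,
    seed: int = 0,
    rate_ratio: float = 4.0,
    growth_rate: float | None = None,
    step_sigma: float | None = None,
) -> ParticleEnsembleSpec:
    """A fully populated spec for one of the canonical study scenarios.

    Parameters
    ----------
    name : one of :data:`SCENARIO_NAMES`.
    overrides : mapping of :class:`ParticleEnsembleSpec` field names
        applied last (changes only the named fields).
    duration : nominal run length in frames over which the preset
        schedules are laid out (schedules clamp beyond it).
    rate_ratio : two-step scenario only — ratio of the stage-1 growth
        rate to the magnitude of the stage-2 dissolution rate;
        ``float('inf')`` disables dissolution.
    growth_rate, step_sigma : optional scenario-level knobs replacing
        the preset growth speed (px/frame) or random-walk step (px).
    """
    if name not in SCENARIO_NAMES:
        raise ParameterError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    base: dict[str, object] = dict(
        n_particles=n_particles, box_n=box_n, seed=seed, radius_mean=4.0
    )
    g = growth_rate if growth_rate is not None else 0.1

    if name == "linear_growth":
        base["radius_schedule"] = as_schedule([(0.0, 0.0), (duration, g * duration)])
    elif name == "growth_distribution":
        base["radius_schedule"] = as_schedule([(0.0, 0.0), (duration, g * duration)])
        base["radius_spread"] = 0.2 * 4.0
    elif name == "nonlinear_growth":
        # accelerating growth: mean speed g, final speed ~ 3x the initial
        base["radius_schedule"] = as_schedule(
            [(0.0, 0.0), (0.6 * duration, 0.3 * g * duration), (duration, g * duration)]
        )
    elif name == "two_step_growth_dissolution":
        base["radius_mean"] = 4.0
        base["radius_spread"] = 0.5
        base["radius_schedule"] = _two_step_schedules(
            n_particles, duration, rate_ratio, g, stagger_fraction=0.2
        )
        # a weak random walk removes the exact configuration recurrence a
        # perfectly static ensemble exhibits when radii retrace earlier
        # values — a model degeneracy no real system has
        sigma = step_sigma if step_sigma is not None else 0.15
        base["motion"] = MotionSpec(kind="random_walk", step_sigma=sigma)
    elif name == "shape_change":
        base["radius_mean"] = 8.0
        base["shape_schedule"] = ShapeSchedule.from_points(
            [(0.0, 1.0), (0.45 * duration, 1.0), (0.55 * duration, 0.35)]
        )
    elif name == "concentration_ramp":
        base["radius_mean"] = 8.0
        base["u_in"] = [(0.0, -0.2), (duration, -1.0)]
    elif name == "brownian":
        base["radius_mean"] = 6.0
        # minimum separation gives the ensemble an interparticle
        # structure-factor peak for the analysis ring to sit on
        base["min_separation"] = 2.2 * 6.0
        sigma = step_sigma if step_sigma is not None else 0.5
        base["motion"] = MotionSpec(kind="random_walk", step_sigma=sigma)
    elif name == "brownian_plus_growth":
        base["radius_schedule"] = as_schedule([(0.0, 0.0), (duration, g * duration)])
        sigma = step_sigma if step_sigma is not None else 0.3
        base["motion"] = MotionSpec(kind="random_walk", step_sigma=sigma)
    elif name == "early_stage_llps":
        # simultaneous growth and decaying Brownian motion: fast thermal
        # dynamics early, growth features emerging as motion slows
        base["radius_mean"] = 2.0
        base["radius_schedule"] = as_schedule([(0.0, 0.0), (duration, g * duration)])
        sigma = step_sigma if step_sigma is not None else 2.0
        base["motion"] = MotionSpec(
            kind="random_walk",
            step_sigma=[(0.0, sigma), (duration, 0.02 * sigma)],
        )

    if overrides:
        unknown = set(overrides) - set(ParticleEnsembleSpec.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown override field(s): {sorted(unknown)}")
        base.update(overrides)
    return ParticleEnsembleSpec(**base)  # type: ignore[arg-type]
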