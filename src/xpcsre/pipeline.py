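"""Pipeline orchestration: config parsing, end-to-end runs, fixtures.

A pipeline run is: source (phase-field run, particle scenario, or an
external frame stack) -> speckle synthesis (+ optional noise) -> q-ring
selection -> two-time correlation -> feature extraction, with every
artefact written to disk together with a provenance record (config
hash, derived seeds, package version) sufficient to replay the run.

All randomness derives from one master seed via
``numpy.random.SeedSequence``, so a (config, seed) pair reproduces its
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .ch import CHParams, FieldSeries, binarize, dilate_domains, evolve
from .correlation import TwoTimeCorrelation, compute_ttc, contrast_profile
from .errors import ConfigError, ParameterError
from .features import FeatureReport, analyze_ttc
from .io import (
    read_frames,
    write_features_csv,
    write_features_json,
    write_field_series,
    write_speckle_series,
    write_ttc,
)
from .particles import SCENARIO_NAMES, build_scenario, simulate
from .scattering import (
    Geometry,
    SpeckleSeries,
    add_noise,
    make_q_ring,
    select_analysis_q,
    speckle_series,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "generate_fixture",
    "preset_config",
    "FIXTURE_NAMES",
    "PRESET_NAMES",
]

_SOURCE_KINDS = ("ch", "particles", "frames")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_dict`` for the schema)."""

    source_kind: str
    source: dict[str, Any]
    noise_fraction: float = 0.0
    q_center: float | None = None
    q_halfwidth: float | None = None
    early_frames: int = 5
    estimator: str = "pearson"
    offset: int = 1
    prominence: float = 0.05
    n0: int = 1
    t_split: float | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a nested mapping::

            source:     {kind: ch|particles|frames, ...kind-specific keys}
            scattering: {noise_fraction: float}
            analysis:   {q_center, q_halfwidth, early_frames, estimator,
                         offset, prominence, n0, t_split}
            seed:       int
        """
        if not isinstance(raw, Mapping):
            raise ConfigError("config must be a mapping")
        src = raw.get("source")
        if not isinstance(src, Mapping) or "kind" not in src:
            raise ConfigError("config requires a 'source' block with a 'kind' key")
        kind = src["kind"]
        if kind not in _SOURCE_KINDS:
            raise ConfigError(f"source.kind must be one of {_SOURCE_KINDS}, got {kind!r}")
        scat = raw.get("scattering", {}) or {}
        ana = raw.get("analysis", {}) or {}
        unknown = set(raw) - {"source", "scattering", "analysis", "seed"}
        if unknown:
            raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
        try:
            cfg = cls(
                source_kind=kind,
                source={k: v for k, v in src.items() if k != "kind"},
                noise_fraction=float(scat.get("noise_fraction", 0.0)),
                q_center=None if ana.get("q_center") is None else float(ana["q_center"]),
                q_halfwidth=None if ana.get("q_halfwidth") is None else float(ana["q_halfwidth"]),
                early_frames=int(ana.get("early_frames", 5)),
                estimator=str(ana.get("estimator", "pearson")),
                offset=int(ana.get("offset", 1)),
                prominence=float(ana.get("prominence", 0.05)),
                n0=int(ana.get("n0", 1)),
                t_split=None if ana.get("t_split") is None else float(ana["t_split"]),
                seed=int(raw.get("seed", 0)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config value: {exc}") from exc
        if cfg.noise_fraction < 0:
            raise ConfigError("scattering.noise_fraction must be >= 0")
        if cfg.estimator not in ("pearson", "intensity"):
            raise ConfigError("analysis.estimator must be 'pearson' or 'intensity'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of the artefacts of one pipeline run."""

    field_series: FieldSeries | None
    speckle: SpeckleSeries
    ttc: TwoTimeCorrelation
    report: FeatureReport
    q_center: float
    provenance: dict[str, Any]


def _source_field_series(cfg: PipelineConfig, seed: int) -> FieldSeries:
    src = dict(cfg.source)
    if cfg.source_kind == "ch":
        n_steps = int(src.pop("n_steps", 2000))
        sample_every = int(src.pop("sample_every", 20))
        do_binarize = bool(src.pop("binarize", False))
        dilate = src.pop("dilate", None)
        src.setdefault("seed", seed)
        try:
            params = CHParams(**src)
        except TypeError as exc:
            raise ConfigError(f"invalid ch source parameters: {exc}") from exc
        series = evolve(params, n_steps=n_steps, sample_every=sample_every)
        if do_binarize or dilate:
            series = FieldSeries(
                fields=[binarize(f) for f in series], sample_interval=series.sample_interval
            )
        if dilate:
            series = dilate_domains(
                series,
                pixels_per_frame=int(dilate.get("pixels_per_frame", 1)),
                phase=str(dilate.get("phase", "dense")),
            )
        return series
    # particles
    n_frames = int(src.pop("n_frames", 100))
    scenario = src.pop("scenario", None)
    if scenario is not None:
        kw = {
            k: src.pop(k)
            for k in ("duration", "n_particles", "box_n", "rate_ratio", "growth_rate", "step_sigma")
            if k in src
        }
        kw.setdefault("seed", seed)
        try:
            spec = build_scenario(str(scenario), overrides=src.pop("overrides", None), **kw)
        except TypeError as exc:
            raise ConfigError(f"invalid particle scenario parameters: {exc}") from exc
        if src:
            raise ConfigError(f"unknown particle source key(s): {sorted(src)}")
    else:
        from .particles import ParticleEnsembleSpec

        src.setdefault("seed", seed)
        try:
            spec = ParticleEnsembleSpec(**src)
        except TypeError as exc:
            raise ConfigError(f"invalid particle spec parameters: {exc}") from exc
    return simulate(spec, n_frames=n_frames)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute source -> speckle -> q-ring -> TTC -> features.

    Writes (when ``out_dir`` is given) ``fields.h5``, ``speckle.h5``,
    ``ttc.h5``, ``features.csv``/``features.json``, ``contrast.csv`` and
    ``provenance.json``.  On a stage failure the partial outputs remain
    on disk next to a ``FAILED`` marker naming the stage.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3)
    seeds = [int(s % (2**31)) for s in seeds]
    timings: dict[str, float] = {}
    stage = "source"
    try:
        t0 = _time.perf_counter()
        field_series: FieldSeries | None = None
        if cfg.source_kind == "frames":
            geometry = None
            if "geometry" in cfg.source:
                try:
                    geometry = Geometry(**cfg.source["geometry"])
                except TypeError as exc:
                    raise ConfigError(f"invalid geometry block: {exc}") from exc
            speckle = read_frames(
                cfg.source["path"],
                format=cfg.source.get("format"),
                geometry=geometry,
                dx=float(cfg.source.get("dx", 1.0)),
            )
        else:
            field_series = _source_field_series(cfg, seeds[0])
            speckle = speckle_series(field_series)
        timings["source"] = _time.perf_counter() - t0

        stage = "scattering"
        t0 = _time.perf_counter()
        if cfg.noise_fraction > 0:
            speckle = add_noise(speckle, cfg.noise_fraction, seed=seeds[1])
        timings["scattering"] = _time.perf_counter() - t0

        stage = "analysis"
        t0 = _time.perf_counter()
        q_center = cfg.q_center
        if q_center is None:
            q_center = select_analysis_q(speckle, early_frames=cfg.early_frames)
        q_halfwidth = cfg.q_halfwidth
        if q_halfwidth is None:
            # two q-pixels on the simulation grid
            q_halfwidth = 2.0 * 2.0 * np.pi / speckle.shape[0]
        ring = make_q_ring(speckle, q_center, q_halfwidth)
        ttc = compute_ttc(speckle, ring, estimator=cfg.estimator)
        report = analyze_ttc(
            ttc,
            offset=cfg.offset,
            prominence=cfg.prominence,
            n0=cfg.n0,
            t_split=cfg.t_split,
        )
        timings["analysis"] = _time.perf_counter() - t0
    except Exception as exc:
        if out is not None:
            (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    provenance = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "derived_seeds": {"source": seeds[0], "noise": seeds[1]},
        "q_center": float(q_center),
        "q_halfwidth": float(q_halfwidth),
        "ring_size": ring.size,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    if out is not None:
        if field_series is not None:
            write_field_series(out / "fields.h5", field_series)
        write_speckle_series(out / "speckle.h5", speckle)
        write_ttc(out / "ttc.h5", ttc)
        write_features_csv(out / "features.csv", report)
        write_features_json(out / "features.json", report)
        from .io import write_profile_csv

        write_profile_csv(out / "contrast.csv", contrast_profile(ttc, offset=cfg.offset))
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return PipelineResult(
        field_series=field_series,
        speckle=speckle,
        ttc=ttc,
        report=report,
        q_center=float(q_center),
        provenance=provenance,
    )


PRESET_NAMES = ("identical_growth", "ch_vs_binary", "two_step", "brownian", "ch_noisy")


def preset_config(name: str, seed: int = 0, size: str = "standard") -> PipelineConfig:
    """Ready-made pipeline configurations for the canonical study scenarios.

    ``size = "tiny"`` shrinks grids/frame counts for fast smoke runs;
    ``"standard"`` mirrors the scenario defaults.
    """
    if size not in ("tiny", "standard"):
        raise ConfigError(f"size must be 'tiny' or 'standard', got {size!r}")
    tiny = size == "tiny"
    if name == "identical_growth":
        raw: dict[str, Any] = {
            "source": {
                "kind": "particles",
                "scenario": "linear_growth",
                "n_frames": 60 if tiny else 200,
                "box_n": 64 if tiny else 512,
                "n_particles": 12 if tiny else 200,
                "duration": 60.0 if tiny else 200.0,
            },
            "seed": seed,
            "analysis": {"q_center": 2 * np.pi / 6.0},
        }
    elif name == "brownian":
        raw = {
            "source": {
                "kind": "particles",
                "scenario": "brownian",
                "n_frames": 60 if tiny else 100,
                "box_n": 64 if tiny else 256,
                "n_particles": 12 if tiny else 200,
            },
            "seed": seed,
            "analysis": {"q_center": 2 * np.pi / 10.0},
        }
    elif name == "two_step":
        raw = {
            "source": {
                "kind": "particles",
                "scenario": "two_step_growth_dissolution",
                "n_frames": 60 if tiny else 200,
                "box_n": 64 if tiny else 512,
                "n_particles": 12 if tiny else 200,
                "duration": 60.0 if tiny else 200.0,
            },
            "seed": seed,
            "analysis": {"q_center": 2 * np.pi / 8.0, "t_split": 18.0 if tiny else 60.0},
        }
    elif name == "ch_vs_binary":
        raw = {
            "source": {
                "kind": "ch",
                "grid_n": 64 if tiny else 256,
                "n_steps": 600 if tiny else 4000,
                "sample_every": 10 if tiny else 40,
            },
            "seed": seed,
        }
    elif name == "ch_noisy":
        raw = {
            "source": {
                "kind": "ch",
                "grid_n": 64 if tiny else 256,
                "n_steps": 600 if tiny else 4000,
                "sample_every": 10 if tiny else 40,
            },
            "scattering": {"noise_fraction": 0.04},
            "seed": seed,
        }
    else:
        raise ConfigError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    return PipelineConfig.from_dict(raw)


FIXTURE_NAMES = SCENARIO_NAMES + ("ch_coarsening",)


def generate_fixture(name: str, size: str = "tiny", out_dir: str | Path = ".", seed: int = 0) -> Path:
    """Write a small seeded field-series dataset for tests and demos.

    ``tiny`` fixtures are 64^2 grids with 60 frames (seconds to build);
    ``standard`` mirrors the scenario defaults.  Regeneration under the
    same seed is idempotent.
    """
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
    if size not in ("tiny", "standard"):
        raise ConfigError(f"size must be 'tiny' or 'standard', got {size!r}")
    tiny = size == "tiny"
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{name}_{size}.h5"
    if name == "ch_coarsening":
        params = CHParams(grid_n=64 if tiny else 256, seed=seed)
        series = evolve(params, n_steps=590 if tiny else 4000, sample_every=10 if tiny else 40)
        write_field_series(path, series, params_json=params.to_json())
        return path
    spec = build_scenario(
        name,
        box_n=64 if tiny else 512,
        n_particles=12 if tiny else 200,
        duration=60.0 if tiny else 200.0,
        seed=seed,
        growth_rate=0.1,
    )
    series = simulate(spec, n_frames=60 if tiny else 200)
    write_field_series(path, series)
    return path
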