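"""Readers and writers for the pipeline artefacts.

On-disk schemas (all HDF5 payloads are float32; metadata lossless):

* field series  — dataset ``/u`` of shape (frames, N, N), dataset
  ``/times``; attributes ``dx``, ``sample_interval`` and optionally a
  ``params`` JSON string.
* speckle series — datasets ``/I`` (frames, N, N), ``/qmap`` (N, N),
  ``/times``; optional geometry attributes.
* TTC — datasets ``/G`` (T, T), ``/times``, ``/valid``; attributes
  ``q_center``, ``q_halfwidth``, ``ring_size``, ``estimator``.

Multi-page TIFF stacks can be imported as speckle frames (uniform unit
timestamps are synthesized with a warning, since TIFF carries no time
axis) and field series can be exported as 16-bit TIFF for visual
inspection.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .ch import ConcentrationField, FieldSeries
from .correlation import ContrastProfile, G2Cut, TwoTimeCorrelation
from .errors import FormatError
from .features import FeatureReport
from .scattering import Geometry, SpeckleFrame, SpeckleSeries, q_map_simulation

__all__ = [
    "write_field_series",
    "read_field_series",
    "write_speckle_series",
    "read_speckle_series",
    "read_frames",
    "write_ttc",
    "read_ttc",
    "write_tiff_stack",
    "write_features_csv",
    "write_features_json",
    "write_profile_csv",
]


def _require(h5: h5py.File, name: str, path: Path) -> h5py.Dataset:
    if name not in h5:
        raise FormatError(f"{path}: missing dataset '{name}'")
    return h5[name]


def write_field_series(path: str | Path, series: FieldSeries, params_json: str | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("u", data=series.stack().astype(np.float32))
        h5.create_dataset("times", data=series.times)
        h5.attrs["dx"] = series.dx
        h5.attrs["sample_interval"] = series.sample_interval
        if params_json is not None:
            h5.attrs["params"] = params_json


def read_field_series(path: str | Path) -> FieldSeries:
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            u = np.asarray(_require(h5, "u", path), dtype=float)
            times = np.asarray(_require(h5, "times", path), dtype=float)
            if "dx" not in h5.attrs:
                raise FormatError(f"{path}: missing attribute 'dx'")
            dx = float(h5.attrs["dx"])
            interval = float(h5.attrs.get("sample_interval", 1.0))
    except OSError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not a readable HDF5 field-series file ({exc})") from exc
    if u.ndim != 3 or len(times) != u.shape[0]:
        raise FormatError(f"{path}: dataset 'u' must be (frames, N, N) matching 'times'")
    fields = [ConcentrationField(values=u[k], time=float(times[k]), dx=dx) for k in range(len(times))]
    return FieldSeries(fields=fields, sample_interval=interval)


def write_speckle_series(path: str | Path, series: SpeckleSeries) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("I", data=series.stack().astype(np.float32))
        h5.create_dataset("qmap", data=series.qmap.astype(np.float32))
        h5.create_dataset("times", data=series.times)
        if series.geometry is not None:
            g = series.geometry
            h5.attrs["photon_energy"] = g.photon_energy
            h5.attrs["detector_distance"] = g.detector_distance
            h5.attrs["pixel_size"] = g.pixel_size
            h5.attrs["beam_center"] = list(g.beam_center)


def read_speckle_series(path: str | Path) -> SpeckleSeries:
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            intensity = np.asarray(_require(h5, "I", path), dtype=float)
            qmap = np.asarray(_require(h5, "qmap", path), dtype=float)
            times = np.asarray(_require(h5, "times", path), dtype=float)
            geometry = None
            if "photon_energy" in h5.attrs:
                geometry = Geometry(
                    photon_energy=float(h5.attrs["photon_energy"]),
                    detector_distance=float(h5.attrs["detector_distance"]),
                    pixel_size=float(h5.attrs["pixel_size"]),
                    beam_center=tuple(h5.attrs["beam_center"]),
                )
    except OSError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not a readable HDF5 speckle file ({exc})") from exc
    frames = [SpeckleFrame(intensity=intensity[k], time=float(times[k])) for k in range(len(times))]
    return SpeckleSeries(frames=frames, qmap=qmap, geometry=geometry)


def read_frames(
    path: str | Path,
    format: str | None = None,
    geometry: Geometry | None = None,
    dx: float = 1.0,
) -> SpeckleSeries:
    """Read a detector frame stack (HDF5 schema above, or a multi-page TIFF).

    TIFF stacks carry no q-map or timestamps: uniform unit timestamps
    are synthesized (with a warning) and the q-map comes from
    ``geometry`` when given, else from the simulation convention with
    spacing ``dx``.
    """
    path = Path(path)
    if format is None:
        format = "tiff_stack" if path.suffix.lower() in (".tif", ".tiff") else "hdf5"
    if format == "hdf5":
        return read_speckle_series(path)
    if format != "tiff_stack":
        raise FormatError(f"unknown frame format {format!r} (use 'hdf5' or 'tiff_stack')")
    try:
        stack = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable TIFF stack ({exc})") from exc
    stack = np.atleast_3d(np.asarray(stack, dtype=float))
    if stack.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2D pages, got shape {stack.shape}")
    warnings.warn(
        f"{path}: TIFF carries no timestamps; synthesizing uniform unit-interval times",
        stacklevel=2,
    )
    frames = [SpeckleFrame(intensity=np.maximum(stack[k], 0.0), time=float(k)) for k in range(stack.shape[0])]
    if geometry is not None:
        from .scattering import q_map_physical

        qmap = q_map_physical(geometry, frames[0].intensity.shape)
    else:
        qmap = q_map_simulation(frames[0].intensity.shape[0], dx)
    return SpeckleSeries(frames=frames, qmap=qmap, geometry=geometry)


def write_tiff_stack(path: str | Path, series: FieldSeries | SpeckleSeries) -> None:
    """Export frames as a 16-bit TIFF stack (per-stack linear rescale)."""
    stack = series.stack()
    lo, hi = float(stack.min()), float(stack.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    data = ((stack - lo) * scale).astype(np.uint16)
    tifffile.imwrite(Path(path), data)


def write_ttc(path: str | Path, ttc: TwoTimeCorrelation) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("G", data=ttc.G.astype(np.float32))
        h5.create_dataset("times", data=ttc.times)
        h5.create_dataset("valid", data=ttc.valid)
        h5.attrs["q_center"] = ttc.q_center
        h5.attrs["q_halfwidth"] = ttc.q_halfwidth
        h5.attrs["ring_size"] = ttc.ring_size
        h5.attrs["estimator"] = ttc.estimator


def read_ttc(path: str | Path) -> TwoTimeCorrelation:
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            G = np.asarray(_require(h5, "G", path), dtype=float)
            times = np.asarray(_require(h5, "times", path), dtype=float)
            valid = np.asarray(_require(h5, "valid", path), dtype=bool)
            for attr in ("q_center", "q_halfwidth", "ring_size"):
                if attr not in h5.attrs:
                    raise FormatError(f"{path}: missing attribute '{attr}'")
            return TwoTimeCorrelation(
                G=G,
                times=times,
                q_center=float(h5.attrs["q_center"]),
                q_halfwidth=float(h5.attrs["q_halfwidth"]),
                ring_size=int(h5.attrs["ring_size"]),
                valid=valid,
                estimator=str(h5.attrs.get("estimator", "pearson")),
            )
    except OSError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not a readable HDF5 TTC file ({exc})") from exc


def write_features_csv(path: str | Path, report: FeatureReport) -> None:
    """One row per detected feature (kind, t_age, value)."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "t_age", "value"])
        for t, xi in report.xi_points:
            w.writerow(["xi_xpcs", f"{t:.10g}", f"{xi:.10g}"])
        for t in report.tail_times:
            w.writerow(["tail", f"{float(t):.10g}", ""])
        if report.square is not None:
            w.writerow(["square_strength", f"{report.t_split:.10g}", f"{report.square:.10g}"])
        if report.modulation_mean_spacing is not None:
            w.writerow(["modulation_spacing", "", f"{report.modulation_mean_spacing:.10g}"])
        if report.power_law_exponent is not None:
            w.writerow(["power_law_exponent", "", f"{report.power_law_exponent:.10g}"])


def write_features_json(path: str | Path, report: FeatureReport) -> None:
    with open(Path(path), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_profile_csv(path: str | Path, profile: ContrastProfile | G2Cut) -> None:
    """Contrast profiles (t_age, G) or g2 cuts (tau, g) as two-column CSV."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        if isinstance(profile, ContrastProfile):
            w.writerow(["t_age", "contrast"])
            for t, v in zip(profile.t_age, profile.values):
                w.writerow([f"{t:.10g}", f"{v:.10g}"])
        else:
            w.writerow(["tau", "g"])
            for t, v in zip(profile.tau, profile.values):
                w.writerow([f"{t:.10g}", f"{v:.10g}"])
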