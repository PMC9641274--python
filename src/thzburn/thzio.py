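"""On-disk containers: HDF5 image cubes, CSV feature tables, JSON reports.

Cubes are stored in an HDF5 layout following the dotTHz community
convention for THz-TDS data: one group per measurement holding the sample
matrix and time-axis metadata as attributes, plus the validity mask and
the site's histology labels.  Feature tables are plain CSV (full float
precision, diff-able); evaluation reports are JSON.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .containers import ImageCube, SiteLabel, WaveformTrace
from .errors import FormatError, IntegrityError

__all__ = [
    "write_cube",
    "read_cube",
    "write_dataset",
    "read_dataset",
    "write_observations",
    "read_observations",
    "write_features",
    "read_features",
    "write_report",
]

_LABEL_FIELDS = ("site_id", "etiology", "dermal_burn_pct", "reepi_pct_day28")


def _write_cube_group(grp: h5py.Group, cube: ImageCube) -> None:
    grp.create_dataset("samples", data=cube.data, compression="gzip", compression_opts=1)
    grp.create_dataset("valid_mask", data=cube.valid_mask)
    grp.attrs["t0"] = cube.t0
    grp.attrs["dt"] = cube.dt
    grp.attrs["pixel_pitch"] = cube.pixel_pitch
    fov = cube.field_of_view_mm
    grp.attrs["field_of_view_mm"] = fov
    for name in _LABEL_FIELDS:
        grp.attrs[name] = getattr(cube.label, name)
    grp.attrs["meta_json"] = json.dumps(cube.meta, default=str)


def _read_cube_group(grp: h5py.Group) -> ImageCube:
    for name in ("dt", "t0", "pixel_pitch", *_LABEL_FIELDS):
        if name not in grp.attrs:
            raise FormatError(f"cube group {grp.name!r} missing attribute {name!r}")
    for name in ("samples", "valid_mask"):
        if name not in grp:
            raise FormatError(f"cube group {grp.name!r} missing dataset {name!r}")
    label = SiteLabel(
        site_id=str(grp.attrs["site_id"]),
        etiology=str(grp.attrs["etiology"]),
        dermal_burn_pct=float(grp.attrs["dermal_burn_pct"]),
        reepi_pct_day28=float(grp.attrs["reepi_pct_day28"]),
    )
    meta = json.loads(grp.attrs.get("meta_json", "{}"))
    return ImageCube(
        t0=float(grp.attrs["t0"]),
        dt=float(grp.attrs["dt"]),
        data=grp["samples"][()],
        pixel_pitch=float(grp.attrs["pixel_pitch"]),
        valid_mask=grp["valid_mask"][()].astype(bool),
        label=label,
        meta=meta,
    )


def write_cube(cube: ImageCube, path) -> None:
    """Write a single cube (lossless round-trip with :func:`read_cube`)."""
    with h5py.File(path, "w") as f:
        _write_cube_group(f.create_group(cube.label.site_id), cube)


def read_cube(path) -> ImageCube:
    """Read a single-cube file (the first measurement group)."""
    with h5py.File(path, "r") as f:
        groups = [k for k in f.keys() if isinstance(f[k], h5py.Group)]
        if not groups:
            raise FormatError(f"{path}: no measurement group found")
        return _read_cube_group(f[groups[0]])


def _write_trace_group(grp: h5py.Group, trace: WaveformTrace) -> None:
    grp.create_dataset("samples", data=trace.samples)
    grp.attrs["t0"] = trace.t0
    grp.attrs["dt"] = trace.dt
    grp.attrs["meta_json"] = json.dumps(trace.meta, default=str)


def _read_trace_group(grp: h5py.Group) -> WaveformTrace:
    for name in ("dt", "t0"):
        if name not in grp.attrs:
            raise FormatError(f"trace group {grp.name!r} missing attribute {name!r}")
    return WaveformTrace(
        t0=float(grp.attrs["t0"]),
        dt=float(grp.attrs["dt"]),
        samples=grp["samples"][()],
        meta=json.loads(grp.attrs.get("meta_json", "{}")),
    )


def write_dataset(cubes: Sequence[ImageCube], air: WaveformTrace, path) -> None:
    """Write a multi-site study: one group per cube plus the air reference."""
    ids = [c.label.site_id for c in cubes]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate site ids in dataset")
    with h5py.File(path, "w") as f:
        meas = f.create_group("measurements")
        meas.attrs["site_order"] = ids
        for cube in cubes:
            _write_cube_group(meas.create_group(cube.label.site_id), cube)
        _write_trace_group(f.create_group("air_reference"), air)


def read_dataset(path) -> tuple[list[ImageCube], WaveformTrace]:
    with h5py.File(path, "r") as f:
        if "measurements" not in f:
            raise FormatError(f"{path}: missing 'measurements' group")
        if "air_reference" not in f:
            raise FormatError(f"{path}: missing 'air_reference' group")
        meas = f["measurements"]
        if "site_order" in meas.attrs:
            order = [s if isinstance(s, str) else s.decode() for s in meas.attrs["site_order"]]
        else:
            order = sorted(meas.keys())
        cubes = [_read_cube_group(meas[k]) for k in order]
        air = _read_trace_group(f["air_reference"])
    return cubes, air


def write_observations(observations, path) -> None:
    """Write conditioned ROI observations (shared time axis) to HDF5."""
    from .preprocess import ROIObservation  # local import to avoid cycle

    if not observations:
        raise IntegrityError("no observations to write")
    t0 = observations[0].mean_trace.t0
    dt = observations[0].mean_trace.dt
    traces = np.stack([o.mean_trace.samples for o in observations])
    ids = [o.roi_id for o in observations]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate roi ids")
    with h5py.File(path, "w") as f:
        grp = f.create_group("observations")
        grp.create_dataset("traces", data=traces, compression="gzip", compression_opts=1)
        grp.attrs["t0"] = t0
        grp.attrs["dt"] = dt
        str_dt = h5py.string_dtype()
        grp.create_dataset("roi_id", data=np.array(ids, dtype=object), dtype=str_dt)
        grp.create_dataset(
            "site_id", data=np.array([o.site_id for o in observations], dtype=object), dtype=str_dt
        )
        grp.create_dataset(
            "etiology", data=np.array([o.label.etiology for o in observations], dtype=object), dtype=str_dt
        )
        grp.create_dataset(
            "dermal_burn_pct", data=[o.label.dermal_burn_pct for o in observations]
        )
        grp.create_dataset(
            "reepi_pct_day28", data=[o.label.reepi_pct_day28 for o in observations]
        )


def read_observations(path):
    from .preprocess import ROIObservation

    with h5py.File(path, "r") as f:
        if "observations" not in f:
            raise FormatError(f"{path}: missing 'observations' group")
        grp = f["observations"]
        for name in ("t0", "dt"):
            if name not in grp.attrs:
                raise FormatError(f"{path}: observations missing attribute {name!r}")
        t0, dt = float(grp.attrs["t0"]), float(grp.attrs["dt"])
        traces = grp["traces"][()]
        out = []
        for i in range(traces.shape[0]):
            label = SiteLabel(
                site_id=grp["site_id"][i].decode(),
                etiology=grp["etiology"][i].decode(),
                dermal_burn_pct=float(grp["dermal_burn_pct"][i]),
                reepi_pct_day28=float(grp["reepi_pct_day28"][i]),
            )
            out.append(
                ROIObservation(
                    roi_id=grp["roi_id"][i].decode(),
                    site_id=label.site_id,
                    mean_trace=WaveformTrace(t0, dt, traces[i]),
                    label=label,
                )
            )
    return out


_REQUIRED_FEATURE_COLUMNS = ("roi_id", "site_id", "etiology", "dermal_burn_pct", "reepi_pct_day28")


def _validate_features(df: pd.DataFrame, origin: str) -> None:
    for col in _REQUIRED_FEATURE_COLUMNS:
        if col not in df.columns:
            raise IntegrityError(f"{origin}: missing required column {col!r}")
    if not any(c.startswith("eser_") for c in df.columns):
        raise IntegrityError(f"{origin}: no eser_* feature columns")
    if df["roi_id"].duplicated().any():
        dupes = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise IntegrityError(f"{origin}: duplicated observation id(s) {dupes[:5]}")


def write_features(df: pd.DataFrame, path) -> None:
    """Write a feature table to CSV at full (round-trippable) precision."""
    _validate_features(df, "feature table")
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_features(df, str(path))
    return df


def write_report(report_dict: dict, path) -> None:
    """Write an evaluation report (JSON, NaN-safe)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as f:
        json.dump(report_dict, f, indent=2, default=_default, allow_nan=True)
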