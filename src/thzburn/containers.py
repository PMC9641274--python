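"""In-memory containers for THz time-domain measurements.

A reflection-mode THz-TDS imager records, at every pixel of a raster scan,
the electric field of a picosecond pulse as a function of optical delay.
One measurement site therefore yields a small image cube: an (ny, nx) grid
of time-domain traces sharing a common time axis, plus a validity mask
(biopsy and corner pixels are excluded from analysis) and the histology
labels of the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError

__all__ = ["WaveformTrace", "SiteLabel", "ImageCube"]


@dataclass(frozen=True)
class WaveformTrace:
    """One time-domain electric-field record.

    Parameters
    ----------
    t0 : float
        Time of the first sample, picoseconds.
    dt : float
        Sampling step, picoseconds.
    samples : ndarray
        Electric-field amplitudes (arbitrary units).
    meta : dict
        Free-form provenance (e.g. gate parameters once gated).
    """

    t0: float
    dt: float
    samples: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if samples.ndim != 1:
            raise ConfigurationError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def time(self) -> np.ndarray:
        """Time axis in picoseconds."""
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def nyquist_thz(self) -> float:
        """Nyquist frequency in THz (dt is in ps)."""
        return 0.5 / self.dt

    def energy(self) -> float:
        """Sum of squared sample amplitudes."""
        return float(np.sum(self.samples**2))

    def with_samples(self, samples: np.ndarray, **meta) -> "WaveformTrace":
        new_meta = {**self.meta, **meta}
        return replace(self, samples=np.asarray(samples, dtype=float), meta=new_meta)


@dataclass(frozen=True)
class SiteLabel:
    """Histology ground truth for one measurement site.

    ``dermal_burn_pct`` is the day-0 depth of the deepest injury relative to
    the dermis thickness; ``reepi_pct_day28`` is the day-28 wound-closure
    (re-epithelialisation) percentage.
    """

    site_id: str
    etiology: str  # {"scald", "contact", "healthy"}
    dermal_burn_pct: float
    reepi_pct_day28: float

    def __post_init__(self) -> None:
        if self.etiology not in ("scald", "contact", "healthy"):
            raise ConfigurationError(f"unknown etiology {self.etiology!r}")
        for name in ("dermal_burn_pct", "reepi_pct_day28"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigurationError(f"{name}={v} outside [0, 100]")


@dataclass
class ImageCube:
    """Grid of co-registered traces for one measurement site.

    ``data`` has shape (ny, nx, n_samples); every pixel shares ``t0``/``dt``.
    ``valid_mask`` is False at biopsy and corner pixels.
    """

    t0: float
    dt: float
    data: np.ndarray
    pixel_pitch: float
    valid_mask: np.ndarray
    label: SiteLabel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ConfigurationError("cube data must have shape (ny, nx, n_samples)")
        if self.valid_mask.shape != self.data.shape[:2]:
            raise ConfigurationError(
                f"mask shape {self.valid_mask.shape} != grid shape {self.data.shape[:2]}"
            )
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.pixel_pitch <= 0:
            raise ConfigurationError("pixel_pitch must be positive")

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def field_of_view_mm(self) -> tuple[float, float]:
        """(width, height) of the scanned area in mm."""
        return (self.nx * self.pixel_pitch, self.ny * self.pixel_pitch)

    def trace(self, iy: int, ix: int) -> WaveformTrace:
        return WaveformTrace(self.t0, self.dt, self.data[iy, ix].copy())

    def copy(self) -> "ImageCube":
        return ImageCube(
            t0=self.t0,
            dt=self.dt,
            data=self.data.copy(),
            pixel_pitch=self.pixel_pitch,
            valid_mask=self.valid_mask.copy(),
            label=self.label,
            meta=dict(self.meta),
        )
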