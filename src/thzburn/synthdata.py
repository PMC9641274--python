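"""Synthetic THz-TDS burn-imaging simulator.

Emulates the measurement geometry of a reflection-mode handheld THz
time-domain scanner pressed against skin through an imaging window: every
pixel records two overlapping reflections — one from the air/window
interface (arrival ``tau1``), one from the window/tissue interface
(``tau2``) — plus, at biopsy pixels, a delayed Fabry-Perot echo from the
air gap left by the punch.  The probing pulse is modelled as the negative
second derivative of a Gaussian (a Ricker pulse), which is single-cycle,
DC-free and band-limited to a few hundred GHz for a ~2-ps width, matching
the usable 0.1–1 THz band of such scanners.

Burn severity enters through the tissue reflection's spectral response
``rho * exp(-beta * f)``: deeper burns are modelled with a lower broadband
reflectivity ``rho`` and a steeper spectral-tilt rate ``beta`` (1/THz).
The steeper tilt narrows the reflected band, spreading the gated pulse in
time and raising its coefficient entropy, so the mean in-band
energy-to-entropy ratio (ESER) decreases monotonically along the severity
ladder healthy → SPT → DPT → FT — the qualitative contrast the downstream
classifiers rely on.  The tilt values are free design parameters of the
simulator, not estimates of porcine skin.

Every site additionally gets one global integer-sample timing shift
(mechanical drift, bounded by ``drift_max``) and per-pixel additive white
Gaussian noise at ``snr_db``.  Corner pixels are flagged invalid (the
scanner housing clips the beam there).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .containers import ImageCube, SiteLabel, WaveformTrace
from .errors import ConfigurationError

__all__ = [
    "SceneConfig",
    "SEVERITY_ORDER",
    "generate_pulse",
    "generate_site_cube",
    "generate_dataset",
    "demo_config",
    "paper_scale_counts",
]

SEVERITY_ORDER = ("H", "SPT", "DPT", "FT")

# (rho, beta): broadband reflectivity scale and spectral-tilt rate in 1/THz.
# rho strictly decreasing and beta strictly increasing with severity; the
# tilt drives the decreasing in-band ESER trend (rho cancels after gating).
DEFAULT_REFLECTIVITY = {
    "H": (0.85, 0.3),
    "SPT": (0.70, 0.9),
    "DPT": (0.55, 1.8),
    "FT": (0.40, 3.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated measurement scene.

    Times in picoseconds, frequencies in THz, amplitudes arbitrary.
    """

    dt: float = 0.01  # sampling step (ps)
    n_samples: int = 6144
    pulse_width: float = 2.0  # intensity-envelope FWHM (ps)
    tau1: float = 14.0  # air/window reflection arrival (ps)
    tau2: float = 32.0  # window/tissue reflection arrival (ps)
    a1: float = 1.0  # air/window reflection amplitude
    reflectivity_by_class: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITY)
    )
    fp_delay: float = 6.0  # Fabry-Perot echo delay at biopsy pixels (ps)
    fp_amp: float = 0.5  # echo amplitude as a fraction of the tissue pulse
    snr_db: Optional[float] = 30.0  # None or inf -> noise-free
    drift_max: int = 8  # per-site global timing drift bound (samples)
    nx: int = 27
    ny: int = 27
    pixel_pitch: float = 1.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 64:
            raise ConfigurationError(f"n_samples must be >= 64, got {self.n_samples}")
        horizon = self.n_samples * self.dt
        if not (0 < self.tau1 < self.tau2 < self.tau2 + self.fp_delay < horizon):
            raise ConfigurationError(
                "need 0 < tau1 < tau2 < tau2 + fp_delay < n_samples*dt, got "
                f"tau1={self.tau1}, tau2={self.tau2}, fp_delay={self.fp_delay}, "
                f"horizon={horizon}"
            )
        if self.pulse_width <= 0:
            raise ConfigurationError("pulse_width must be positive")
        if self.drift_max < 0:
            raise ConfigurationError("drift_max must be >= 0")
        if self.nx < 1 or self.ny < 1:
            raise ConfigurationError("grid must be at least 1x1")
        rungs = [c for c in SEVERITY_ORDER if c in self.reflectivity_by_class]
        rhos = [self.reflectivity_by_class[c][0] for c in rungs]
        if len(rungs) == len(SEVERITY_ORDER) and not all(
            a > b for a, b in zip(rhos, rhos[1:])
        ):
            raise ConfigurationError(
                "reflectivity rho must be strictly decreasing along the "
                f"severity ladder, got {dict(zip(rungs, rhos))}"
            )

    @property
    def sigma(self) -> float:
        """Gaussian width parameter from the intensity-envelope FWHM."""
        return self.pulse_width / (2.0 * np.sqrt(np.log(2.0)))

    @property
    def time(self) -> np.ndarray:
        return self.dt * np.arange(self.n_samples)


def _ricker(t: np.ndarray, sigma: float) -> np.ndarray:
    """Peak-normalised negative second derivative of a Gaussian."""
    u = (t / sigma) ** 2
    return (1.0 - u) * np.exp(-0.5 * u)


def generate_pulse(config: SceneConfig) -> WaveformTrace:
    """The probing pulse, centred at t = 0, peak amplitude 1.

    A Ricker pulse is zero-mean (DC-free) with amplitude spectrum
    proportional to f^2 * exp(-2 pi^2 sigma^2 f^2), peaking at
    f = 1 / (pi sigma sqrt(2)); the default 2-ps width puts that peak near
    0.19 THz, inside the 0.1–1 THz measurement band.
    """
    n = config.n_samples
    t0 = -config.dt * (n // 2)
    t = t0 + config.dt * np.arange(n)
    return WaveformTrace(t0=t0, dt=config.dt, samples=_ricker(t, config.sigma))


def _tilted_pulse(config: SceneConfig, tau: float, rho: float, beta: float) -> np.ndarray:
    """Tissue-reflected pulse at delay ``tau``: Ricker filtered by
    rho * exp(-beta * f) in the frequency domain."""
    clean = _ricker(config.time - tau, config.sigma)
    f = np.fft.rfftfreq(config.n_samples, d=config.dt)  # THz
    response = rho * np.exp(-beta * f)
    return np.fft.irfft(np.fft.rfft(clean) * response, n=config.n_samples)


def _corner_mask(ny: int, nx: int) -> np.ndarray:
    mask = np.ones((ny, nx), dtype=bool)
    for iy in (0, ny - 1):
        for ix in (0, nx - 1):
            mask[iy, ix] = False
    return mask


def _severity_class(label: SiteLabel) -> str:
    # duplicate of model.assign_labels kept import-cycle-free
    if label.etiology == "healthy":
        return "H"
    d = label.dermal_burn_pct
    if d < 60.0:
        return "SPT"
    if d <= 90.0:
        return "DPT"
    return "FT"


def generate_site_cube(
    config: SceneConfig,
    label: SiteLabel,
    biopsy_region: Optional[tuple[int, int, int, int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> ImageCube:
    """Simulate one measurement site.

    ``biopsy_region`` is ``(y0, x0, height, width)`` in pixels; those pixels
    get the Fabry-Perot echo and are recorded in ``meta['biopsy_region']``
    (the generated ``valid_mask`` marks only corners invalid — flagging
    biopsy pixels is the preprocessing stage's job).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cls = _severity_class(label)
    if cls not in config.reflectivity_by_class:
        raise ConfigurationError(f"no reflectivity entry for class {cls!r}")
    rho, beta = config.reflectivity_by_class[cls]

    t = config.time
    p1 = config.a1 * _ricker(t - config.tau1, config.sigma)
    p2 = _tilted_pulse(config, config.tau2, rho, beta)
    base = p1 + p2
    echo = None
    if biopsy_region is not None:
        y0, x0, h, w = biopsy_region
        if not (0 <= y0 and 0 <= x0 and y0 + h <= config.ny and x0 + w <= config.nx):
            raise ConfigurationError(
                f"biopsy_region {biopsy_region} outside {config.ny}x{config.nx} grid"
            )
        echo = config.fp_amp * _tilted_pulse(
            config, config.tau2 + config.fp_delay, rho, beta
        )

    data = np.broadcast_to(base, (config.ny, config.nx, config.n_samples)).copy()
    if echo is not None:
        y0, x0, h, w = biopsy_region
        data[y0 : y0 + h, x0 : x0 + w, :] = base + echo

    drift = 0
    if config.drift_max > 0:
        drift = int(rng.integers(-config.drift_max, config.drift_max + 1))
        data = np.roll(data, drift, axis=2)

    snr = config.snr_db
    if snr is not None and np.isfinite(snr):
        signal_power = float(np.mean(base**2))
        sigma_n = np.sqrt(signal_power / 10.0 ** (snr / 10.0))
        data = data + rng.normal(0.0, sigma_n, size=data.shape)

    meta = {"drift_samples": drift, "severity_class": cls}
    if biopsy_region is not None:
        meta["biopsy_region"] = tuple(int(v) for v in biopsy_region)
    return ImageCube(
        t0=0.0,
        dt=config.dt,
        data=data,
        pixel_pitch=config.pixel_pitch,
        valid_mask=_corner_mask(config.ny, config.nx),
        label=label,
        meta=meta,
    )


def _draw_label(cls: str, site_id: str, rng: np.random.Generator) -> SiteLabel:
    """Histology percentages consistent with the class thresholds
    (<60 / 60-90 / >90 % dermal burn), re-epithelialisation negatively
    correlated with severity."""
    if cls == "H":
        return SiteLabel(site_id, "healthy", 0.0, 100.0)
    etiology = str(rng.choice(["scald", "contact"]))
    if cls == "SPT":
        dermal = float(rng.uniform(15.0, 59.5))
        reepi = 100.0 if rng.random() < 0.75 else float(rng.uniform(70.0, 99.0))
    elif cls == "DPT":
        dermal = float(rng.uniform(60.0, 90.0))
        reepi = 100.0 if rng.random() < 0.2 else float(rng.uniform(40.0, 90.0))
    elif cls == "FT":
        dermal = float(rng.uniform(90.5, 100.0))
        reepi = float(rng.uniform(0.0, 40.0))
    else:
        raise ConfigurationError(f"unknown class {cls!r}")
    return SiteLabel(site_id, etiology, dermal, reepi)


def generate_dataset(
    config: SceneConfig,
    class_counts: Mapping[str, int],
    seed: Optional[int] = None,
    biopsy_fraction: float = 0.0,
    biopsy_size: int = 4,
) -> tuple[list[ImageCube], WaveformTrace]:
    """Simulate a multi-site study plus its air-reference trace.

    Returns ``(cubes, air_reference)``.  The air reference is the bare
    air/window reflection (no tissue pulse) recorded at 20 dB better SNR
    than the tissue scans.  A fraction of sites optionally receives a
    planted square biopsy region.  Bit-reproducible for a given seed.
    """
    for cls, count in class_counts.items():
        if count < 1:
            raise ConfigurationError(f"class_counts[{cls!r}] must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cubes: list[ImageCube] = []
    for cls in [c for c in SEVERITY_ORDER if c in class_counts]:
        for i in range(class_counts[cls]):
            site_id = f"{cls}-{i:03d}"
            label = _draw_label(cls, site_id, rng)
            biopsy = None
            if biopsy_fraction > 0.0 and rng.random() < biopsy_fraction:
                y0 = int(rng.integers(1, config.ny - biopsy_size))
                x0 = int(rng.integers(1, config.nx - biopsy_size))
                biopsy = (y0, x0, biopsy_size, biopsy_size)
            cubes.append(generate_site_cube(config, label, biopsy, rng=rng))

    air = config.a1 * _ricker(config.time - config.tau1, config.sigma)
    if config.snr_db is not None and np.isfinite(config.snr_db):
        power = float(np.mean(air**2))
        sigma_n = np.sqrt(power / 10.0 ** ((config.snr_db + 20.0) / 10.0))
        air = air + rng.normal(0.0, sigma_n, size=air.shape)
    air_trace = WaveformTrace(t0=0.0, dt=config.dt, samples=air, meta={"kind": "air"})
    return cubes, air_trace


def demo_config(**overrides) -> SceneConfig:
    """Reduced-scale scene for fast experiments: 51.2-ps traces at
    dt = 0.05 ps, so a 12.8-ps gate holds 256 samples and level-8 packet
    trees stay small."""
    params = dict(dt=0.05, n_samples=1024, tau1=8.0, tau2=20.0, fp_delay=6.0)
    params.update(overrides)
    return SceneConfig(**params)


def paper_scale_counts() -> dict[str, int]:
    """Site counts sized so a 27x27 grid (24 usable 5x5 tiles after the
    corner exclusion) yields roughly 300/332/224/569 ROI observations for
    H/SPT/DPT/FT."""
    return {"H": 13, "SPT": 14, "DPT": 9, "FT": 24}
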