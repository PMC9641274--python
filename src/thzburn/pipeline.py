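"""Glue between scene simulation, conditioning, and ESER features.

A :class:`ConditioningPlan` collects the time windows and thresholds the
preprocessing stages need (alignment gate on the first reflection, search
interval for the tissue reflection, post-pulse gate for biopsy detection,
band edges, ROI size); :func:`plan_from_scene` derives sensible windows
from a simulated scene's geometry.  A :class:`FeatureConfig` names one
(wavelet, level, sub-band selection) combination; :func:`eser_features`
turns conditioned ROI observations into the deconvolved ESER feature
matrix the classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ImageCube, WaveformTrace
from .errors import ConfigurationError
from .eser import ESERVector, deconvolve_reference, eser_vector
from .modwpt import WaveletSpec, modwpt_transform, select_subbands
from .preprocess import (
    GateSpec,
    ROIObservation,
    align_cube,
    bandpass,
    bandpass_cube,
    detect_invalid_pixels,
    extract_roi_observations,
    gate_cube,
    gate_tissue_reflection,
)
from .synthdata import SceneConfig

__all__ = [
    "ConditioningPlan",
    "FeatureConfig",
    "plan_from_scene",
    "condition_air",
    "condition_cube",
    "extract_observations",
    "eser_features",
    "features_dataframe",
]


@dataclass(frozen=True)
class ConditioningPlan:
    """Windows and thresholds for the conditioning chain (times in ps)."""

    f_lo: float = 0.1
    f_hi: float = 1.0
    gate: GateSpec = field(default_factory=GateSpec)
    ref_gate: tuple[float, float] = (10.0, 18.0)  # first-reflection gate
    search: tuple[float, float] = (23.0, 60.0)  # tissue-reflection search
    air_search: tuple[float, float] = (10.0, 20.0)  # air principal reflection
    post_gate: tuple[float, float] = (35.5, 41.5)  # biopsy-echo gate
    k_mad: float = 5.0
    roi_side: int = 5


def plan_from_scene(
    config: SceneConfig,
    gate_width: float = 25.0,
    roi_side: int = 5,
    k_mad: float = 5.0,
    f_lo: float = 0.1,
    f_hi: float = 1.0,
) -> ConditioningPlan:
    """Derive conditioning windows from a simulated scene's geometry.

    The tissue-reflection search starts midway between the two arrivals;
    the biopsy gate brackets the expected Fabry-Perot echo.
    """
    pw = config.pulse_width
    horizon = config.n_samples * config.dt
    half = gate_width / 2.0
    if config.tau1 - half < 0 or config.tau2 + half >= horizon:
        raise ConfigurationError(
            f"{gate_width}-ps gate does not fit around tau1={config.tau1} / "
            f"tau2={config.tau2} within a {horizon}-ps trace"
        )
    echo = config.tau2 + config.fp_delay
    return ConditioningPlan(
        f_lo=f_lo,
        f_hi=f_hi,
        gate=GateSpec(width=gate_width),
        ref_gate=(config.tau1 - 2 * pw, config.tau1 + 2 * pw),
        search=(0.5 * (config.tau1 + config.tau2), horizon - 0.5),
        air_search=(config.tau1 - 2 * pw, config.tau1 + 3 * pw),
        post_gate=(echo - 2.5, echo + 3.5),
        k_mad=k_mad,
        roi_side=roi_side,
    )


def condition_air(air: WaveformTrace, plan: ConditioningPlan) -> WaveformTrace:
    """Band-pass and gate the air reference identically to tissue traces.

    The gate is centred on the air trace's principal (air/window)
    reflection, so the reference ESER cancels the instrument response
    coherently in the deconvolution.
    """
    bp = bandpass(air, plan.f_lo, plan.f_hi)
    return gate_tissue_reflection(bp, plan.gate, plan.air_search)


def condition_cube(
    cube: ImageCube,
    plan: ConditioningPlan,
    air: Optional[WaveformTrace] = None,
) -> tuple[ImageCube, np.ndarray]:
    """Run the full conditioning chain on one cube.

    Band-pass -> align on the first reflection (against the band-passed air
    reference when given, else the site median) -> flag biopsy/corner
    pixels -> Blackman-gate the tissue reflection.  Returns the gated cube
    and the applied alignment shifts.
    """
    bp = bandpass_cube(cube, plan.f_lo, plan.f_hi)
    template = bandpass(air, plan.f_lo, plan.f_hi) if air is not None else None
    aligned, shifts = align_cube(bp, plan.ref_gate, template=template)
    aligned.valid_mask = detect_invalid_pixels(aligned, plan.post_gate, plan.k_mad)
    gated = gate_cube(aligned, plan.gate, plan.search)
    return gated, shifts


def extract_observations(
    cubes: Sequence[ImageCube],
    plan: ConditioningPlan,
    air: Optional[WaveformTrace] = None,
) -> list[ROIObservation]:
    """Condition every cube and pool the ROI observations."""
    observations: list[ROIObservation] = []
    for cube in cubes:
        gated, _ = condition_cube(cube, plan, air=air)
        observations.extend(extract_roi_observations(gated, plan.roi_side))
    return observations


@dataclass(frozen=True)
class FeatureConfig:
    """One (wavelet, level, sub-band selection) feature combination.

    ``explicit_range`` pins the sequency indices directly (the conventional
    in-band choice is 10..80 at J=12 with a 50-THz Nyquist); otherwise the
    sub-bands overlapping [f_lo, f_hi] THz are selected per trace.
    """

    vanishing_moments: int = 1
    level: int = 12
    f_lo: float = 0.1
    f_hi: float = 1.0
    explicit_range: Optional[tuple[int, int]] = None

    def wavelet_spec(self) -> WaveletSpec:
        return WaveletSpec(self.vanishing_moments, self.level)

    def subbands(self, dt: float) -> list[int]:
        return select_subbands(
            self.level, dt, self.f_lo, self.f_hi, explicit_range=self.explicit_range
        )


def _air_eser(air_gated: WaveformTrace, fcfg: FeatureConfig) -> tuple[list[int], ESERVector]:
    band = fcfg.subbands(air_gated.dt)
    table = modwpt_transform(air_gated, fcfg.wavelet_spec(), band)
    vec = eser_vector(table, band)
    vec.reference_id = air_gated.meta.get("kind", "air")
    return band, vec


def eser_features(
    observations: Sequence[ROIObservation],
    air_gated: WaveformTrace,
    fcfg: FeatureConfig,
) -> tuple[np.ndarray, list[int]]:
    """Deconvolved ESER feature matrix (n_observations, n_subbands)."""
    if not observations:
        raise ConfigurationError("no observations to featurise")
    band, air_vec = _air_eser(air_gated, fcfg)
    spec = fcfg.wavelet_spec()
    X = np.empty((len(observations), len(band)))
    for i, obs in enumerate(observations):
        table = modwpt_transform(obs.mean_trace, spec, band)
        X[i] = deconvolve_reference(eser_vector(table, band), air_vec).eser
    return X, band


def features_dataframe(
    observations: Sequence[ROIObservation],
    air_gated: WaveformTrace,
    fcfg: FeatureConfig,
) -> pd.DataFrame:
    """Feature table with observation ids, labels and one column per sub-band."""
    X, band = eser_features(observations, air_gated, fcfg)
    rows = {
        "roi_id": [o.roi_id for o in observations],
        "site_id": [o.site_id for o in observations],
        "etiology": [o.label.etiology for o in observations],
        "dermal_burn_pct": [o.label.dermal_burn_pct for o in observations],
        "reepi_pct_day28": [o.label.reepi_pct_day28 for o in observations],
    }
    df = pd.DataFrame(rows)
    for j, n in enumerate(band):
        df[f"eser_{n}"] = X[:, j]
    return df
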