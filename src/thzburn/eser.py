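"""Energy-to-Shannon-entropy-ratio (ESER) features.

For each terminal MODWPT sub-band the coefficient magnitudes are normalised
into a discrete probability sequence

    P(t) = |W(J,n,t)|^2 / sum_t |W(J,n,t)|^2 ,

whose Shannon entropy H = -sum_t P log P (nats) measures how spread the
sub-band's energy is in time.  The sub-band's energy ratio is

    E(J,n) = sum_t |W(J,n,t)|^2 / sum_t |X(t)|^2 ,

the fraction of the analysed trace's energy it carries; over a full packet
tree the E values sum to one.  The classification feature is the ratio
ESER_n = E / H, and tissue features are divided element-wise by the ESER of
an identically conditioned air/mirror reference to cancel the instrument
response ("reference deconvolution").  ESER is invariant to the overall
amplitude of the trace, and the deconvolved ESER is invariant to the
logarithm base used for the entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, ReferenceDeconvolutionError
from .modwpt import PacketTable

__all__ = [
    "ESERVector",
    "subband_probability",
    "subband_entropy",
    "subband_energy_ratio",
    "eser_vector",
    "deconvolve_reference",
]

# Sub-band counted as energy-degenerate below this fraction of input energy.
DEGENERATE_ENERGY_FRACTION = 1e-12


@dataclass
class ESERVector:
    """Per-sub-band ESER features for one observation."""

    subband_indices: list[int]
    energy_ratio: np.ndarray
    entropy: np.ndarray  # nats (or the base used at construction)
    eser: np.ndarray
    degenerate: np.ndarray  # bool flags; eser is 0 there by convention
    deconvolved: bool = False
    reference_id: str | None = None


def subband_probability(coefficients: np.ndarray) -> tuple[np.ndarray, bool]:
    """Normalised energy sequence P(t) of one sub-band.

    Returns ``(P, degenerate)``; a near-zero-energy sub-band is flagged
    (P returned as zeros) rather than raising.
    """
    c = np.asarray(coefficients, dtype=float)
    power = c**2
    total = power.sum()
    if total <= 0.0 or not np.isfinite(total):
        return np.zeros_like(power), True
    return power / total, False


def subband_entropy(P: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy of a probability sequence, 0*log(0) := 0.

    Natural log by default (nats); ``base`` overrides (deconvolved ESER is
    base-invariant).
    """
    P = np.asarray(P, dtype=float)
    nz = P[P > 0.0]
    H = float(-(nz * np.log(nz)).sum())
    if base is not None:
        H /= np.log(base)
    return H


def subband_energy_ratio(coefficients: np.ndarray, input_energy: float) -> float:
    """Fraction of the analysed trace's energy carried by one sub-band."""
    if input_energy <= 0.0:
        raise DegenerateInputError("input trace has zero energy")
    return float(np.sum(np.asarray(coefficients, dtype=float) ** 2) / input_energy)


def eser_vector(
    table: PacketTable,
    selected: list[int] | None = None,
    base: float | None = None,
) -> ESERVector:
    """ESER features of the selected sub-bands of a packet table.

    Degenerate sub-bands (energy below 1e-12 of the input energy) get
    H := 0 and ESER := 0 and are flagged, keeping the feature vector finite.
    """
    if table.input_energy <= 0.0:
        raise DegenerateInputError("input trace has zero energy")
    if selected is None:
        selected = list(table.subband_indices)
    n_sel = len(selected)
    energy_ratio = np.empty(n_sel)
    entropy = np.empty(n_sel)
    eser = np.zeros(n_sel)
    degenerate = np.zeros(n_sel, dtype=bool)
    threshold = DEGENERATE_ENERGY_FRACTION * table.input_energy
    for i, n in enumerate(selected):
        coeffs = table.subband(n)
        e_abs = float(np.sum(coeffs**2))
        energy_ratio[i] = e_abs / table.input_energy
        if e_abs < threshold:
            degenerate[i] = True
            entropy[i] = 0.0
            continue
        P, flag = subband_probability(coeffs)
        if flag:
            degenerate[i] = True
            entropy[i] = 0.0
            continue
        H = subband_entropy(P, base=base)
        entropy[i] = H
        eser[i] = energy_ratio[i] / H if H > 0.0 else 0.0
        if H <= 0.0:
            # single-support-point sub-band: zero entropy, ESER set to 0
            degenerate[i] = True
    return ESERVector(
        subband_indices=list(selected),
        energy_ratio=energy_ratio,
        entropy=entropy,
        eser=eser,
        degenerate=degenerate,
    )


def deconvolve_reference(tissue: ESERVector, air: ESERVector) -> ESERVector:
    """Divide tissue ESER by the air-reference ESER, sub-band by sub-band.

    Both vectors must cover the same sub-bands; the air reference must be
    non-degenerate wherever it is used.
    """
    if tissue.subband_indices != air.subband_indices:
        raise ConfigurationError(
            "tissue and air ESER vectors cover different sub-bands"
        )
    bad = [
        n
        for n, flag, e in zip(air.subband_indices, air.degenerate, air.eser)
        if flag or e == 0.0
    ]
    if bad:
        raise ReferenceDeconvolutionError(
            f"air reference degenerate at sub-band(s) {bad}"
        )
    eser = np.where(tissue.degenerate, 0.0, tissue.eser / air.eser)
    return ESERVector(
        subband_indices=list(tissue.subband_indices),
        energy_ratio=tissue.energy_ratio.copy(),
        entropy=tissue.entropy.copy(),
        eser=eser,
        degenerate=tissue.degenerate.copy(),
        deconvolved=True,
        reference_id=air.reference_id or "air",
    )
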