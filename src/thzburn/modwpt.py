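"""Maximal-overlap discrete wavelet packet transform (MODWPT).

The MODWPT is an undecimated wavelet packet decomposition: at level J it
splits the Nyquist band into 2**J sub-bands of equal nominal width, and —
unlike the decimated DWT/DWPT — every sub-band keeps the full time
resolution of the input (N coefficients for an N-sample trace).

The level-j coefficients follow the circular recursion

    W(j, n, t) = sum_k u(k) * W(j-1, floor(n/2), (t - 2**(j-1) * k) mod N)

where ``u`` is the rescaled scaling filter ``g`` when ``n mod 4`` is 0 or 3
and the rescaled wavelet filter ``h`` when ``n mod 4`` is 1 or 2.  That
filter-selection rule compensates the spectral flip that high-pass filtering
introduces at every stage, so the terminal sub-bands come out in *sequency*
order: sub-band n nominally occupies [n, n+1] * f_Nyquist / 2**J.

Filters are the orthonormal Daubechies pairs rescaled by 1/sqrt(2) (the
maximal-overlap normalisation), which makes the transform energy-preserving:
the 2**J terminal sub-band energies sum exactly to the input energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pywt

from .containers import WaveformTrace
from .errors import ConfigurationError

__all__ = [
    "WaveletSpec",
    "PacketTable",
    "daubechies_filters",
    "modwpt_transform",
    "modwpt_transform_array",
    "subband_passband",
    "select_subbands",
]


def daubechies_filters(vanishing_moments: int) -> tuple[np.ndarray, np.ndarray]:
    """Return the maximal-overlap Daubechies pair (g, h) for ``dbK``.

    The orthonormal scaling filter (sum = sqrt(2), unit energy) is rescaled
    by 1/sqrt(2), giving sum(g) = 1, sum(h) = 0 and
    sum(g**2) + sum(h**2) = 1.  The wavelet filter is the quadrature mirror
    h(k) = (-1)**k * g(L-1-k) with L = 2 * vanishing_moments.
    """
    if not 1 <= int(vanishing_moments) <= 10:
        raise ConfigurationError(
            f"Daubechies order must be in 1..10, got {vanishing_moments}"
        )
    # pywt's reconstruction low-pass is the orthonormal scaling filter.
    g_orth = np.asarray(pywt.Wavelet(f"db{int(vanishing_moments)}").rec_lo, dtype=float)
    g = g_orth / np.sqrt(2.0)
    L = g.size
    h = ((-1.0) ** np.arange(L)) * g[::-1]
    return g, h


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family, order and decomposition depth for one transform.

    ``vanishing_moments`` selects db1..db10; filter length is twice that.
    """

    vanishing_moments: int
    level_J: int
    family: str = "db"

    def __post_init__(self) -> None:
        if self.family != "db":
            raise ConfigurationError("only Daubechies ('db') wavelets are supported")
        if not 1 <= self.vanishing_moments <= 10:
            raise ConfigurationError(
                f"vanishing_moments must be in 1..10, got {self.vanishing_moments}"
            )
        if self.level_J < 1:
            raise ConfigurationError(f"level_J must be >= 1, got {self.level_J}")

    @property
    def name(self) -> str:
        return f"db{self.vanishing_moments}"

    @property
    def filter_length(self) -> int:
        return 2 * self.vanishing_moments

    def filters(self) -> tuple[np.ndarray, np.ndarray]:
        return daubechies_filters(self.vanishing_moments)


@dataclass
class PacketTable:
    """Terminal MODWPT coefficients for one trace, sequency-ordered.

    ``coefficients[i]`` holds the N coefficients of sub-band
    ``subband_indices[i]`` at level ``level_J``; ``input_energy`` is the
    energy of the transformed trace (the denominator of downstream
    energy-ratio features).
    """

    level_J: int
    subband_indices: list[int]
    coefficients: np.ndarray  # shape (n_subbands, N)
    input_energy: float
    wavelet: str
    dt: float

    def subband(self, n: int) -> np.ndarray:
        try:
            i = self.subband_indices.index(n)
        except ValueError:
            raise ConfigurationError(f"sub-band {n} not stored in this table") from None
        return self.coefficients[i]

    def subband_energies(self) -> np.ndarray:
        return np.sum(self.coefficients**2, axis=1)


def _circular_filter(x: np.ndarray, u: np.ndarray, stride: int) -> np.ndarray:
    """y[..., t] = sum_k u[k] * x[..., (t - stride*k) mod N].

    Accepts a stack of traces on the leading axes; nodes sharing one filter
    are filtered together.
    """
    y = u[0] * x
    for k in range(1, u.size):
        y += u[k] * np.roll(x, stride * k, axis=-1)
    return y


def _filter_for_child(n_child: int, g: np.ndarray, h: np.ndarray) -> np.ndarray:
    # Sequency rule: scaling filter when n mod 4 in {0, 3}, else wavelet.
    return g if n_child % 4 in (0, 3) else h


def modwpt_transform_array(
    x: np.ndarray,
    spec: WaveletSpec,
    wanted_subbands: Union[Sequence[int], str] = "all",
    dt: float = 1.0,
) -> PacketTable:
    """Transform a bare sample array; see :func:`modwpt_transform`."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("input must be one-dimensional")
    N = x.size
    J = spec.level_J
    n_terminal = 2**J
    if isinstance(wanted_subbands, str):
        if wanted_subbands != "all":
            raise ConfigurationError(f"unknown sub-band selection {wanted_subbands!r}")
        wanted = list(range(n_terminal))
    else:
        wanted = [int(n) for n in wanted_subbands]
        if len(wanted) == 0:
            raise ConfigurationError("wanted_subbands must not be empty")
        bad = [n for n in wanted if not 0 <= n < n_terminal]
        if bad:
            raise ConfigurationError(
                f"sub-band indices {bad} outside [0, {n_terminal - 1}] at level {J}"
            )

    g, h = spec.filters()

    # Pruned breadth-first evaluation: keep only nodes ancestral to the
    # wanted terminal sub-bands.  nodes[j] maps node index -> coefficient
    # array at level j.
    needed: list[set[int]] = [set() for _ in range(J + 1)]
    for n in wanted:
        c = n
        for j in range(J, -1, -1):
            needed[j].add(c)
            c //= 2
    nodes: dict[int, np.ndarray] = {0: x}
    for j in range(1, J + 1):
        stride = 2 ** (j - 1)
        new_nodes: dict[int, np.ndarray] = {}
        children = sorted(needed[j])
        # batch the level: children sharing a filter are filtered together
        for u, subset in (
            (g, [c for c in children if c % 4 in (0, 3)]),
            (h, [c for c in children if c % 4 in (1, 2)]),
        ):
            if not subset:
                continue
            parents = np.stack([nodes[c // 2] for c in subset])
            filtered = _circular_filter(parents, u, stride)
            for i, c in enumerate(subset):
                new_nodes[c] = filtered[i]
        nodes = new_nodes

    coeffs = np.vstack([nodes[n] for n in wanted])
    return PacketTable(
        level_J=J,
        subband_indices=wanted,
        coefficients=coeffs,
        input_energy=float(np.sum(x**2)),
        wavelet=spec.name,
        dt=dt,
    )


def modwpt_transform(
    trace: WaveformTrace,
    spec: WaveletSpec,
    wanted_subbands: Union[Sequence[int], str] = "all",
) -> PacketTable:
    """MODWPT of a trace at level ``spec.level_J``.

    ``wanted_subbands`` may be ``"all"`` or a list of sequency indices in
    [0, 2**J - 1]; only tree branches ancestral to the wanted terminals are
    evaluated (a full J=12 tree over a long trace is needlessly large when
    only the in-band sub-bands are used).  Boundary handling is circular,
    the standard maximal-overlap convention.
    """
    return modwpt_transform_array(trace.samples, spec, wanted_subbands, dt=trace.dt)


def subband_passband(n: int, level_J: int, dt: float) -> tuple[float, float]:
    """Nominal passband (f_low, f_high) of sequency sub-band ``n``, in THz.

    Sub-band n at level J occupies [n, n+1] * f_Nyquist / 2**J with
    f_Nyquist = 1 / (2 dt) (dt in ps gives THz).
    """
    if not 0 <= n < 2**level_J:
        raise ConfigurationError(f"sub-band {n} invalid at level {level_J}")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    width = (0.5 / dt) / 2**level_J
    return (n * width, (n + 1) * width)


def select_subbands(
    level_J: int,
    dt: float,
    f_lo: Optional[float] = None,
    f_hi: Optional[float] = None,
    explicit_range: Optional[tuple[int, int]] = None,
) -> list[int]:
    """Sub-bands covering the measurement bandwidth.

    With ``explicit_range=(a, b)`` returns ``[a..b]`` verbatim (the
    conventional in-band choice at J=12 with 50-THz Nyquist is 10..80,
    spanning roughly 0.12–0.99 THz).  With a frequency interval, returns
    every sub-band whose nominal passband overlaps [f_lo, f_hi].
    """
    if explicit_range is not None:
        a, b = int(explicit_range[0]), int(explicit_range[1])
        if not (0 <= a <= b < 2**level_J):
            raise ConfigurationError(
                f"explicit range {explicit_range} invalid at level {level_J}"
            )
        return list(range(a, b + 1))
    if f_lo is None or f_hi is None:
        raise ConfigurationError("provide either a frequency interval or explicit_range")
    nyq = 0.5 / dt
    if not 0 <= f_lo < f_hi:
        raise ConfigurationError(f"invalid frequency interval ({f_lo}, {f_hi})")
    if f_lo >= nyq:
        raise ConfigurationError(
            f"interval ({f_lo}, {f_hi}) THz lies above Nyquist {nyq} THz"
        )
    width = nyq / 2**level_J
    selected = [
        n for n in range(2**level_J) if (n + 1) * width > f_lo and n * width < f_hi
    ]
    if not selected:
        raise ConfigurationError("empty sub-band selection")
    return selected
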