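"""Six-level db4 discrete-wavelet decomposition implemented as a two-channel
filter-bank cascade.

Each level convolves the running approximation with an orthonormal low-pass /
high-pass analysis pair and keeps the even-indexed outputs
(``y[m] = sum_k s[k] * f[2m - k]``).  The default boundary handling is
periodization, which makes the transform an exact isometry: subband energies
sum to the time-domain energy and the inverse cascade reconstructs the input
to machine precision.  Odd-length approximations are zero-padded by one sample
before the periodized step (the pad carries no energy, so the isometry is
preserved exactly); the pad positions are recorded so reconstruction can undo
them.

A ``symmetric`` analysis mode (half-point reflection) is available for
comparison only; it is neither orthogonal nor invertible here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epoch import Epoch
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "WaveletFilterPair",
    "SubbandSet",
    "DB4",
    "SUBBAND_NAMES",
    "SUBBAND_TO_BAND",
    "dwt_level",
    "idwt_level",
    "wavedec6",
    "waverec6",
]

#: Daubechies-4 analysis low-pass taps (8 coefficients, double precision,
#: standard construction; orthonormality is asserted in the test suite rather
#: than assumed).
_DB4_DEC_LO = np.array(
    [
        -0.010597401784997278,
        0.032883011666982945,
        0.030841381835986965,
        -0.18703481171888114,
        -0.02798376941698385,
        0.6308807679295904,
        0.7148465705525415,
        0.23037781330885523,
    ]
)

#: Decomposition depth fixed by the pipeline design (0-31.25 Hz coverage of
#: the clinical bands at fs = 500 Hz).
N_LEVELS = 6

#: Subband keys in coarse-to-fine order.
SUBBAND_NAMES = ("A6", "D6", "D5", "D4", "D3", "D2", "D1")

#: Clinical interpretation of the four reported subbands.
SUBBAND_TO_BAND = {"A6": "delta", "D6": "theta", "D5": "alpha", "D4": "beta"}


def _qmf(g: np.ndarray) -> np.ndarray:
    """Quadrature-mirror high-pass of an orthonormal low-pass filter."""
    h = g[::-1].copy()
    h[1::2] *= -1.0
    return h


@dataclass(frozen=True)
class WaveletFilterPair:
    """Orthonormal analysis filter pair (low-pass ``g``, high-pass ``h``)."""

    g: np.ndarray
    h: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        h = np.asarray(self.h, dtype=float)
        if g.ndim != 1 or h.ndim != 1 or g.size != h.size or g.size % 2:
            raise ConfigurationError("filter pair must be 1-D, equal even length")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "h", h)

    @classmethod
    def db4(cls) -> "WaveletFilterPair":
        g = _DB4_DEC_LO.copy()
        return cls(g=g, h=_qmf(g), name="db4")

    @property
    def n_taps(self) -> int:
        return int(self.g.size)


#: The pipeline's default wavelet.
DB4 = WaveletFilterPair.db4()


def _analysis_step_per(s: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Periodized ``y[m] = sum_k f[k] * s[(2m - k) mod n]`` for even ``n``."""
    n = s.size
    taps = f.size
    # prepend the periodic tail (mod-indexed: n may be shorter than the
    # filter, in which case the tail wraps more than once)
    tail = s[np.arange(n - taps + 1, n) % n] if taps > 1 else s[:0]
    ext = np.concatenate([tail, s])
    out = np.zeros(n // 2)
    for k in range(taps):
        out += f[k] * ext[taps - 1 - k : taps - 1 - k + n : 2]
    return out


def _analysis_step_sym(s: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Half-point symmetric extension analysis (comparison mode only)."""
    taps = f.size
    ext = np.concatenate([s[taps - 2 :: -1], s, s[-1 : -taps : -1]])
    full = np.convolve(ext, f, mode="valid")
    return full[1::2]


def dwt_level(
    s: np.ndarray,
    filters: WaveletFilterPair = DB4,
    boundary: str = "periodized",
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level: returns ``(approx, detail)``.

    In periodized mode an odd-length input is zero-padded by one trailing
    sample first, so both outputs have ``ceil(n / 2)`` coefficients and
    ``sum(approx**2) + sum(detail**2) == sum(s**2)`` exactly.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise InvalidInputError("dwt_level: signal must be non-empty and 1-D")
    if not np.all(np.isfinite(s)):
        raise InvalidInputError("dwt_level: signal contains non-finite values")
    if boundary == "periodized":
        if s.size % 2:
            s = np.append(s, 0.0)
        return _analysis_step_per(s, filters.g), _analysis_step_per(s, filters.h)
    if boundary == "symmetric":
        if s.size < filters.n_taps:
            raise InvalidInputError("symmetric mode needs length >= filter taps")
        return _analysis_step_sym(s, filters.g), _analysis_step_sym(s, filters.h)
    raise ConfigurationError(f"unknown boundary mode {boundary!r}")


def idwt_level(
    approx: np.ndarray,
    detail: np.ndarray,
    n_out: int,
    filters: WaveletFilterPair = DB4,
) -> np.ndarray:
    """Invert one periodized level, truncating to the original length."""
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape or approx.ndim != 1:
        raise InvalidInputError("idwt_level: approx/detail shapes inconsistent")
    n = 2 * approx.size
    if n_out not in (n, n - 1):
        raise InvalidInputError(
            f"idwt_level: cannot truncate {n} reconstructed samples to {n_out}"
        )
    taps = filters.n_taps
    wrap = np.arange(taps - 1) % n  # may wrap repeatedly when n < taps - 1
    out = np.zeros(n)
    up = np.zeros(n + taps - 1)
    # transpose of the analysis operator: x[j] = sum_k f[k] * u[(j + k) mod n]
    for coeffs, f in ((approx, filters.g), (detail, filters.h)):
        up[:] = 0.0
        up[0:n:2] = coeffs
        up[n:] = up[wrap]
        for k in range(taps):
            out += f[k] * up[k : k + n]
    return out[:n_out]


@dataclass(frozen=True)
class SubbandSet:
    """The seven coefficient sequences {A6, D6..D1} of one decomposed epoch.

    ``input_lengths`` records the approximation length entering each level so
    the inverse cascade can undo the odd-length zero pads.
    """

    coeffs: dict[str, np.ndarray]
    fs: float
    input_lengths: tuple[int, ...]
    wavelet: str = "db4"
    boundary: str = "periodized"
    epoch_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        missing = set(SUBBAND_NAMES) - set(self.coeffs)
        if missing:
            raise InvalidInputError(f"SubbandSet missing subbands: {sorted(missing)}")
        if len(self.input_lengths) != N_LEVELS:
            raise InvalidInputError("input_lengths must have one entry per level")

    @property
    def n_samples(self) -> int:
        return self.input_lengths[0]

    @property
    def band_map(self) -> dict[str, tuple[str, tuple[float, float]]]:
        """Nominal dyadic frequency range (Hz) and band label per subband."""
        nyq = self.fs / 2.0
        out: dict[str, tuple[str, tuple[float, float]]] = {}
        for level, name in enumerate(("D1", "D2", "D3", "D4", "D5", "D6"), start=1):
            out[name] = (
                SUBBAND_TO_BAND.get(name, "residual"),
                (nyq / 2**level, nyq / 2 ** (level - 1)),
            )
        out["A6"] = ("delta", (0.0, nyq / 2**N_LEVELS))
        return out

    def energy(self) -> float:
        return float(sum(np.dot(c, c) for c in self.coeffs.values()))


def wavedec6(
    epoch: Epoch,
    filters: WaveletFilterPair = DB4,
    boundary: str = "periodized",
) -> SubbandSet:
    """Full 6-level cascade on the approximation branch."""
    if epoch.n_samples < 2**N_LEVELS:
        raise InvalidInputError(
            f"wavedec6 needs >= {2**N_LEVELS} samples, got {epoch.n_samples}"
        )
    approx = epoch.samples
    coeffs: dict[str, np.ndarray] = {}
    lengths: list[int] = []
    for level in range(1, N_LEVELS + 1):
        lengths.append(approx.size)
        approx, detail = dwt_level(approx, filters, boundary)
        coeffs[f"D{level}"] = detail
    coeffs["A6"] = approx
    return SubbandSet(
        coeffs=coeffs,
        fs=epoch.fs,
        input_lengths=tuple(lengths),
        wavelet=filters.name,
        boundary=boundary,
        epoch_id=epoch.epoch_id,
        group=epoch.group,
    )


def waverec6(
    subbands: SubbandSet,
    filters: WaveletFilterPair = DB4,
) -> np.ndarray:
    """Invert :func:`wavedec6` (periodized mode only)."""
    if subbands.boundary != "periodized":
        raise ConfigurationError(
            "waverec6 supports only the periodized (orthonormal) transform"
        )
    approx = subbands.coeffs["A6"]
    for level in range(N_LEVELS, 0, -1):
        detail = subbands.coeffs[f"D{level}"]
        if detail.shape != approx.shape:
            raise InvalidInputError(
                f"waverec6: level {level} coefficient lengths inconsistent"
            )
        approx = idwt_level(approx, detail, subbands.input_lengths[level - 1], filters)
    return approx
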