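"""The epoch record shared by every pipeline stage.

An epoch is a single-channel EEG segment in microvolts together with its
sampling rate and (optionally) a group label.  Band names and their clinical
frequency ranges live here as module constants so that synthesis, analysis
and reporting agree on one vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

#: Canonical group labels.
GROUPS = ("normal", "encephalopathy", "unknown")

#: The four clinical bands reported downstream, in fixed order.
BANDS = ("delta", "theta", "alpha", "beta")

#: All five synthesis bands (the residual covers everything above beta).
BANDS_WITH_RESIDUAL = BANDS + ("residual",)

#: Clinical band edges in Hz used for synthesis and periodogram checks.
#: The residual upper edge is resolved to the Nyquist frequency at use time.
CLINICAL_BAND_EDGES_HZ: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 31.25),
    "residual": (31.25, float("inf")),
}


@dataclass(frozen=True)
class Epoch:
    """One EEG segment: ``samples`` in microvolts at sampling rate ``fs``."""

    samples: np.ndarray
    fs: float
    epoch_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidInputError(
                f"epoch {self.epoch_id!r}: samples must be a non-empty 1-D array"
            )
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError(
                f"epoch {self.epoch_id!r}: samples contain non-finite values"
            )
        if not self.fs > 0:
            raise InvalidInputError(f"epoch {self.epoch_id!r}: fs must be > 0")
        if self.group not in GROUPS:
            raise InvalidInputError(
                f"epoch {self.epoch_id!r}: unknown group {self.group!r}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def energy(self) -> float:
        """Time-domain energy, sum of squared samples (µV²·samples)."""
        return float(np.dot(self.samples, self.samples))

    def with_samples(self, samples: np.ndarray) -> "Epoch":
        """Copy of this epoch with new sample values (same fs/id/group)."""
        return replace(self, samples=np.asarray(samples, dtype=float))
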