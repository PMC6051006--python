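"""Subband energies and the per-cohort feature table.

Absolute energy of a subband is the sum of its squared wavelet coefficients;
the total is the sum over all seven subbands (A6 and D1..D6), so with the
periodized transform it equals the epoch's time-domain energy.  Relative
energies of delta/theta/alpha/beta come from A6/D6/D5/D4; the D1-D3 share is
kept as an explicit residual column but is not used as a classifier feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .denoise import LpfTvdParams, lpf_tvd
from .epoch import BANDS, Epoch
from .errors import InvalidInputError, ZeroEnergyError
from .wavelet import DB4, SUBBAND_NAMES, SUBBAND_TO_BAND, SubbandSet, WaveletFilterPair, wavedec6

__all__ = ["BandEnergies", "FEATURE_COLUMNS", "band_energies", "epoch_band_energies", "build_feature_table"]

logger = logging.getLogger(__name__)

#: Column layout of the feature table (percent scale).
FEATURE_COLUMNS = ["epoch_id", "group", "delta_pct", "theta_pct", "alpha_pct", "beta_pct"]


@dataclass(frozen=True)
class BandEnergies:
    """Absolute and relative subband energies of one epoch."""

    e_abs: dict[str, float]
    e_total: float
    rel: dict[str, float]
    rel_residual: float

    def as_percent(self) -> dict[str, float]:
        return {band: 100.0 * self.rel[band] for band in BANDS}


def band_energies(subbands: SubbandSet) -> BandEnergies:
    """Energies per subband and relative band shares for one decomposition."""
    e_abs = {
        name: float(np.dot(c, c)) for name, c in subbands.coeffs.items()
    }
    e_total = sum(e_abs[name] for name in SUBBAND_NAMES)
    if e_total <= 0.0:
        raise ZeroEnergyError(
            f"epoch {subbands.epoch_id!r} has zero total energy; "
            "relative energies are undefined"
        )
    rel = {band: e_abs[sub] / e_total for sub, band in SUBBAND_TO_BAND.items()}
    rel_residual = (e_abs["D1"] + e_abs["D2"] + e_abs["D3"]) / e_total
    return BandEnergies(e_abs=e_abs, e_total=e_total, rel=rel, rel_residual=rel_residual)


def epoch_band_energies(
    epoch: Epoch,
    denoise_params: LpfTvdParams | None = None,
    denoise: bool = True,
    filters: WaveletFilterPair = DB4,
) -> BandEnergies:
    """Denoise (optionally), decompose and measure one epoch."""
    if denoise:
        epoch = lpf_tvd(epoch, denoise_params)
    return band_energies(wavedec6(epoch, filters))


def build_feature_table(
    cohort: list[Epoch],
    denoise_params: LpfTvdParams | None = None,
    denoise: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Run denoise -> 6-level DWT -> relative energies over a cohort.

    Returns the feature table (percent scale, one row per epoch) and the list
    of rejected epoch ids (zero-energy epochs are skipped with a warning, not
    propagated as errors).
    """
    rows = []
    rejects: list[str] = []
    for epoch in cohort:
        try:
            energies = epoch_band_energies(epoch, denoise_params, denoise=denoise)
        except ZeroEnergyError:
            logger.warning("skipping zero-energy epoch %r", epoch.epoch_id)
            rejects.append(epoch.epoch_id)
            continue
        row = {"epoch_id": epoch.epoch_id, "group": epoch.group}
        row.update(
            {f"{band}_pct": pct for band, pct in energies.as_percent().items()}
        )
        rows.append(row)
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return table, rejects


def validate_feature_table(table: pd.DataFrame) -> None:
    """Raise if a feature table violates its structural contract."""
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"feature table missing columns: {sorted(missing)}")
    pct = table[[f"{b}_pct" for b in BANDS]]
    if pct.isna().any().any():
        raise InvalidInputError("feature table contains missing values")
    if ((pct < 0) | (pct > 100)).any().any():
        raise InvalidInputError("percentages must lie in [0, 100]")
    bad = set(table["group"]) - {"normal", "encephalopathy"}
    if bad:
        raise InvalidInputError(f"unexpected group labels: {sorted(bad)}")
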