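"""Synthetic EEG cohort generation.

Each epoch is a sum of band-limited Gaussian-noise components (zero-phase
Butterworth band-pass of white noise), one per clinical band plus a
high-frequency residual, with the per-band energy shares drawn from
group-specific truncated normals and renormalized to sum to one.  Relative
band energies are the only downstream features, so the absolute power scale
is arbitrary; the default corresponds to ~50 µV RMS scalp EEG.

Band shares are sampled independently per band (only marginal means/SDs are
specified per group; independence is the least-informative completion) and
truncated at zero by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.special import ndtr, ndtri

from .epoch import BANDS, BANDS_WITH_RESIDUAL, CLINICAL_BAND_EDGES_HZ, Epoch
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "BandStats",
    "GeneratorParams",
    "TABLE_BAND_STATS",
    "DEFAULT_N_EPOCHS",
    "default_params",
    "sample_band_fractions",
    "synthesize_epoch",
    "generate_cohort",
    "measurement_transfer_matrix",
]

#: Published group summaries driving the default generator: per group, per
#: band, (mean, SD) of relative energy in percent of total.  The residual
#: (>31.25 Hz) share is not reported; the defaults below make each group's
#: means sum to ~100 %.
TABLE_BAND_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "delta": (31.39, 10.34),
        "theta": (19.71, 6.47),
        "alpha": (30.60, 6.03),
        "beta": (14.96, 6.85),
        "residual": (3.30, 1.00),
    },
    "encephalopathy": {
        "delta": (67.73, 19.34),
        "theta": (19.20, 11.78),
        "alpha": (9.64, 7.68),
        "beta": (2.89, 2.71),
        "residual": (0.50, 0.25),
    },
}

#: Published cohort sizes (epochs per group).
DEFAULT_N_EPOCHS = {"encephalopathy": 232, "normal": 218}


@dataclass(frozen=True)
class BandStats:
    """Mean and SD of one band's relative energy, in percent."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ConfigurationError("band mean and sd must be nonnegative")


@dataclass(frozen=True)
class GeneratorParams:
    """Full configuration of a synthetic cohort."""

    per_group_band_stats: Mapping[str, Mapping[str, BandStats]]
    n_epochs_per_group: Mapping[str, int]
    fs: float = 500.0
    duration_s: float = 12.0
    total_power: float = 2500.0  # µV² mean square, ~50 µV RMS
    noise_floor: float | None = None
    trend_amplitude: float = 0.0
    calibrate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_floor is not None and not 0.0 <= self.noise_floor < 1.0:
            raise ConfigurationError("noise_floor must lie in [0, 1)")
        if self.trend_amplitude < 0:
            raise ConfigurationError("trend_amplitude must be nonnegative")
        for group, stats in self.per_group_band_stats.items():
            missing = set(BANDS_WITH_RESIDUAL) - set(stats)
            if missing:
                raise ConfigurationError(
                    f"group {group!r} missing band stats: {sorted(missing)}"
                )
            total = sum(stats[b].mean for b in BANDS_WITH_RESIDUAL)
            if total > 100.0 + 1e-9:
                raise ConfigurationError(
                    f"group {group!r}: band means sum to {total:.2f} > 100 %"
                )
        for group, n in self.n_epochs_per_group.items():
            if group not in self.per_group_band_stats:
                raise ConfigurationError(f"no band stats for group {group!r}")
            if n < 0:
                raise ConfigurationError("epoch counts must be nonnegative")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration_s must be positive")
        n_samples = self.fs * self.duration_s
        if abs(n_samples - round(n_samples)) > 1e-9 or round(n_samples) < 1:
            raise ConfigurationError(
                f"fs * duration_s = {n_samples} is not a positive integer"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def default_params(seed: int = 0, **overrides) -> GeneratorParams:
    """Generator parameterized by the published group summaries."""
    stats = {
        group: {band: BandStats(*ms) for band, ms in bands.items()}
        for group, bands in TABLE_BAND_STATS.items()
    }
    kwargs = dict(
        per_group_band_stats=stats,
        n_epochs_per_group=dict(DEFAULT_N_EPOCHS),
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorParams(**kwargs)


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One draw from N(mean, sd) truncated at zero (inverse-CDF, exact)."""
    if sd == 0.0:
        return max(mean, 0.0)
    # u uniform on [P(X < 0), 1) maps through the normal quantile function
    p_below = ndtr(-mean / sd)
    u = p_below + (1.0 - p_below) * rng.random()
    return mean + sd * float(ndtri(min(u, 1.0 - 1e-16)))


def _sample_fractions_raw(
    means: np.ndarray, sds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal draws per band, renormalized to sum to one."""
    draws = np.array(
        [_truncated_normal(m, s, rng) for m, s in zip(means, sds)]
    )
    total = draws.sum()
    if total <= 0:
        raise ConfigurationError("all band draws are zero")
    return draws / total


def _group_mean_sd(params: GeneratorParams, group: str) -> tuple[np.ndarray, np.ndarray]:
    if group not in params.per_group_band_stats:
        raise ConfigurationError(f"unknown group label {group!r}")
    stats = dict(params.per_group_band_stats[group])
    if params.noise_floor is not None:
        stats["residual"] = BandStats(100.0 * params.noise_floor, 0.0)
    means = np.array([stats[b].mean for b in BANDS_WITH_RESIDUAL])
    sds = np.array([stats[b].sd for b in BANDS_WITH_RESIDUAL])
    return means, sds


def sample_band_fractions(
    params: GeneratorParams, group: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw one epoch's (delta, theta, alpha, beta, residual) energy shares.

    Each share is drawn from the group's truncated normal (percent scale),
    then the vector is renormalized to sum exactly to one.
    """
    means, sds = _group_mean_sd(params, group)
    return _sample_fractions_raw(means, sds, rng)


#: Butterworth order of the band selectors; applied forward-backward, so the
#: effective attenuation is doubled.  Order 6 keeps out-of-band leakage of a
#: pure-band component under a few percent.
_FILTER_ORDER = 6


def _band_sos(band: str, fs: float) -> np.ndarray:
    """Zero-phase Butterworth selector for one clinical band (SOS form)."""
    lo, hi = CLINICAL_BAND_EDGES_HZ[band]
    nyq = fs / 2.0
    if lo <= 0.0:
        return butter(_FILTER_ORDER, hi / nyq, btype="low", output="sos")
    if not np.isfinite(hi) or hi >= nyq:
        return butter(_FILTER_ORDER, lo / nyq, btype="high", output="sos")
    return butter(_FILTER_ORDER, [lo / nyq, hi / nyq], btype="band", output="sos")


def synthesize_epoch(
    fractions: Sequence[float],
    fs: float,
    duration_s: float,
    total_power: float,
    rng: np.random.Generator,
    epoch_id: str = "",
    group: str = "unknown",
) -> Epoch:
    """Realize a band-fraction vector as a single-channel time series.

    Each band component is zero-phase band-pass-filtered white noise scaled
    so its empirical energy equals exactly its requested share of
    ``total_power * n_samples``; the components are then summed.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != len(BANDS_WITH_RESIDUAL):
        raise InvalidInputError(
            f"expected {len(BANDS_WITH_RESIDUAL)} fractions, got {fractions.size}"
        )
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-6:
        raise InvalidInputError("fractions must be nonnegative and sum to 1")
    if total_power < 0:
        raise InvalidInputError("total_power must be nonnegative")
    n_samples = int(round(fs * duration_s))
    if abs(fs * duration_s - n_samples) > 1e-9 or n_samples < 1:
        raise ConfigurationError("fs * duration_s must be a positive integer")
    target_energy = total_power * n_samples
    signal = np.zeros(n_samples)
    for band, frac in zip(BANDS_WITH_RESIDUAL, fractions):
        # white noise is always consumed so the rng stream does not depend
        # on which fractions happen to be zero
        component = sosfiltfilt(_band_sos(band, fs), rng.standard_normal(n_samples))
        if frac == 0.0 or target_energy == 0.0:
            continue
        energy = np.dot(component, component)
        if energy > 0:
            signal += component * np.sqrt(frac * target_energy / energy)
    # band-edge cross terms perturb the summed energy by a few percent;
    # rescale globally (band shares are unaffected)
    total = np.dot(signal, signal)
    if total > 0 and target_energy > 0:
        signal *= np.sqrt(target_energy / total)
    return Epoch(samples=signal, fs=fs, epoch_id=epoch_id, group=group)


#: Cache of measurement transfer matrices keyed by (fs, duration_s, denoise).
_TRANSFER_CACHE: dict[tuple, np.ndarray] = {}

#: Internal seed for the calibration measurements (independent of cohorts).
_CALIBRATION_SEED = 131_071


def measurement_transfer_matrix(
    fs: float,
    duration_s: float,
    denoise: bool = True,
    n_avg: int = 6,
) -> np.ndarray:
    """Energy-transfer matrix of the denoise + DWT measurement chain.

    Row ``i``, column ``j`` is the fraction of a unit-energy pure-band-``i``
    component's energy that the pipeline measures in band ``j`` (bands in
    ``BANDS_WITH_RESIDUAL`` order).  The wavelet subbands are dyadic and have
    gradual rolloffs, so the matrix is diagonally dominant but not diagonal;
    its inverse is used to pre-compensate requested fractions so that
    *measured* group statistics land on the configured targets.
    """
    key = (float(fs), float(duration_s), bool(denoise))
    if key in _TRANSFER_CACHE:
        return _TRANSFER_CACHE[key]
    from .features import epoch_band_energies  # deferred: avoids module cycle

    rng = np.random.default_rng(_CALIBRATION_SEED)
    n_bands = len(BANDS_WITH_RESIDUAL)
    transfer = np.zeros((n_bands, n_bands))
    for i in range(n_bands):
        fractions = np.zeros(n_bands)
        fractions[i] = 1.0
        for _ in range(n_avg):
            epoch = synthesize_epoch(fractions, fs, duration_s, 2500.0, rng)
            energies = epoch_band_energies(epoch, denoise=denoise)
            measured = np.array(
                [energies.rel[b] for b in BANDS] + [energies.rel_residual]
            )
            transfer[i] += measured * energies.e_total / epoch.energy
    transfer /= n_avg
    _TRANSFER_CACHE[key] = transfer
    return transfer


def _compensate(fractions: np.ndarray, transfer_inv: np.ndarray) -> np.ndarray:
    """Pre-distort target fractions through the inverse transfer matrix."""
    raw = fractions @ transfer_inv
    raw = np.clip(raw, 0.0, None)
    return raw / raw.sum()


#: Cache of closed-loop group-mean adjustments, keyed by the full generator
#: configuration (minus seed and epoch counts).
_MEAN_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _calibration_key(params: GeneratorParams) -> tuple:
    stats = tuple(
        (group, band, s.mean, s.sd)
        for group in sorted(params.per_group_band_stats)
        for band, s in sorted(params.per_group_band_stats[group].items())
    )
    return (stats, params.fs, params.duration_s, params.total_power, params.noise_floor)


def _calibrated_stats(
    params: GeneratorParams,
    transfer_inv: np.ndarray,
    n_cal: int = 80,
    n_sd_rounds: int = 3,
    n_mean_rounds: int = 3,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Adjust per-group sampling (means, sds) so the *measured* group
    statistics hit the configured targets.

    Truncation, renormalization (which compresses spread), the
    leakage-compensation clipping and the nonlinear denoiser all bias the
    measured group statistics away from the configured targets; this closed
    loop runs small calibration batches through the real synthesis +
    measurement chain and corrects the residuals.  The mean update uses a
    control variate — the cheap fraction-sampler mean plus the measured
    per-epoch distortion — so the expensive batch only has to estimate the
    (small) distortion term.  Deterministic (internal seed) and cached per
    configuration.
    """
    key = _calibration_key(params)
    if key in _MEAN_CACHE:
        return _MEAN_CACHE[key]
    from .features import epoch_band_energies  # deferred: avoids module cycle

    adjusted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for group in sorted(params.per_group_band_stats):
        target_mean, target_sd = _group_mean_sd(params, group)
        means = target_mean.copy()
        sds = target_sd.copy()
        rng = np.random.default_rng(_CALIBRATION_SEED + 1)
        pooled_distortion = np.zeros(len(BANDS_WITH_RESIDUAL))
        pooled_n = 0
        for round_idx in range(n_sd_rounds + n_mean_rounds):
            mean_only = round_idx >= n_sd_rounds
            # renormalization damps the measured response to a sampling-mean
            # shift (gain < 1), so several mean-only settling rounds are
            # needed; they get larger batches — and pool their distortion
            # samples — because the final residual error is frozen into every
            # cohort generated under this configuration
            n_cheap = 20_000 if mean_only else 5000
            batch = 4 * n_cal if mean_only else n_cal
            sample_mean = np.mean(
                [_sample_fractions_raw(means, sds, rng) for _ in range(n_cheap)], axis=0
            )
            distortion = np.zeros(len(BANDS_WITH_RESIDUAL))
            measured_batch = np.zeros((batch, len(BANDS_WITH_RESIDUAL)))
            for i in range(batch):
                sampled = _sample_fractions_raw(means, sds, rng)
                epoch = synthesize_epoch(
                    _compensate(sampled, transfer_inv),
                    params.fs,
                    params.duration_s,
                    params.total_power,
                    rng,
                )
                energies = epoch_band_energies(epoch)
                measured = np.array(
                    [energies.rel[b] for b in BANDS] + [energies.rel_residual]
                )
                measured_batch[i] = measured
                distortion += measured - sampled
            if mean_only:
                # the distortion term varies only weakly with small mean
                # shifts, so pooling across settling rounds is safe
                pooled_distortion += distortion
                pooled_n += batch
                distortion = pooled_distortion / pooled_n
            else:
                distortion /= batch
            measured_mean = 100.0 * (sample_mean + distortion)
            # a negative sampling location is legitimate (the draw is still
            # truncated at zero); bound it at -2 sd so rejection sampling
            # keeps a workable acceptance rate
            lower = np.where(sds > 0, -2.0 * sds, 0.0)
            means = np.clip(means + (target_mean - measured_mean), lower, None)
            if not mean_only:
                measured_sd = 100.0 * measured_batch.std(axis=0, ddof=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(measured_sd > 0, target_sd / measured_sd, 1.0)
                sds = np.minimum(sds * np.clip(ratio, 0.5, 2.0), 50.0)
                # keep the locations within reach of the shrunken spreads
                means = np.clip(means, np.where(sds > 0, -2.0 * sds, 0.0), None)
        adjusted[group] = (means, sds)
    _MEAN_CACHE[key] = adjusted
    return adjusted


def _step_trend(
    n_samples: int, params: GeneratorParams, rng: np.random.Generator
) -> np.ndarray:
    """Sparse-derivative drift: a few random steps of bounded amplitude."""
    trend = np.zeros(n_samples)
    for pos in rng.integers(1, n_samples, size=3):
        trend[pos:] += rng.uniform(-params.trend_amplitude, params.trend_amplitude)
    return trend - trend.mean()


def generate_cohort(params: GeneratorParams) -> tuple[list[Epoch], dict]:
    """Generate the full labelled cohort plus its manifest.

    The manifest records the seed, scalar parameters and each epoch's
    ground-truth band fractions; identical (params, seed) give bit-identical
    cohorts.
    """
    rng = np.random.default_rng(params.seed)
    transfer_inv = None
    cal_stats: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    if params.calibrate:
        transfer_inv = np.linalg.inv(
            measurement_transfer_matrix(params.fs, params.duration_s)
        )
        cal_stats = _calibrated_stats(params, transfer_inv)
    epochs: list[Epoch] = []
    records: list[dict] = []
    for group in sorted(params.n_epochs_per_group):
        for i in range(params.n_epochs_per_group[group]):
            epoch_id = f"{group}_{i:04d}"
            if cal_stats is not None:
                target = _sample_fractions_raw(*cal_stats[group], rng)
                fractions = _compensate(target, transfer_inv)
            else:
                target = sample_band_fractions(params, group, rng)
                fractions = target
            epoch = synthesize_epoch(
                fractions,
                params.fs,
                params.duration_s,
                params.total_power,
                rng,
                epoch_id=epoch_id,
                group=group,
            )
            if params.trend_amplitude > 0:
                epoch = epoch.with_samples(
                    epoch.samples + _step_trend(epoch.n_samples, params, rng)
                )
            epochs.append(epoch)
            records.append(
                {
                    "epoch_id": epoch_id,
                    "group": group,
                    "fs": params.fs,
                    "n_samples": epoch.n_samples,
                    "true_fractions": {
                        band: float(frac)
                        for band, frac in zip(BANDS_WITH_RESIDUAL, target)
                    },
                    "synth_fractions": {
                        band: float(frac)
                        for band, frac in zip(BANDS_WITH_RESIDUAL, fractions)
                    },
                }
            )
    manifest = {
        "seed": params.seed,
        "calibrated": bool(params.calibrate),
        "fs": params.fs,
        "duration_s": params.duration_s,
        "total_power": params.total_power,
        "n_epochs_per_group": dict(params.n_epochs_per_group),
        "band_stats": {
            group: {band: [stats.mean, stats.sd] for band, stats in bands.items()}
            for group, bands in params.per_group_band_stats.items()
        },
        "epochs": records,
    }
    if cal_stats is not None:
        manifest["calibrated_sampling_stats"] = {
            group: {"mean": list(map(float, m)), "sd": list(map(float, s))}
            for group, (m, s) in cal_stats.items()
        }
    return epochs, manifest
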