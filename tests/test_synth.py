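import numpy as np
import pytest
from scipy import stats as sps

from eegbands.epoch import BANDS_WITH_RESIDUAL, CLINICAL_BAND_EDGES_HZ
from eegbands.errors import ConfigurationError, InvalidInputError
from eegbands.features import epoch_band_energies
from eegbands.synth import (
    BandStats,
    GeneratorParams,
    TABLE_BAND_STATS,
    default_params,
    generate_cohort,
    sample_band_fractions,
    synthesize_epoch,
)

from oracles import periodogram_band_fractions


def _degenerate_params(**overrides):
    """All SDs zero so sampling is deterministic."""
    stats = {
        group: {band: BandStats(mean, 0.0) for band, (mean, _) in bands.items()}
        for group, bands in TABLE_BAND_STATS.items()
    }
    kwargs = dict(
        per_group_band_stats=stats,
        n_epochs_per_group={"encephalopathy": 1, "normal": 1},
        calibrate=False,
    )
    kwargs.update(overrides)
    return GeneratorParams(**kwargs)


class TestSampleBandFractions:
    def test_zero_sd_normal_group_reproduces_published_means(self, rng):
        fractions = sample_band_fractions(_degenerate_params(), "normal", rng)
        means = np.array([31.39, 19.71, 30.60, 14.96, 3.30])
        np.testing.assert_allclose(fractions, means / means.sum(), atol=1e-12)
        # renormalization barely moves the published values (sum ~99.96 %)
        np.testing.assert_allclose(
            fractions[:4], [0.3139, 0.1971, 0.3060, 0.1496], atol=5e-4
        )

    def test_single_band_degenerate_case(self, rng):
        stats = {
            "normal": {
                band: BandStats(100.0 if band == "delta" else 0.0, 0.0)
                for band in BANDS_WITH_RESIDUAL
            }
        }
        params = GeneratorParams(
            per_group_band_stats=stats,
            n_epochs_per_group={"normal": 1},
            calibrate=False,
        )
        fractions = sample_band_fractions(params, "normal", rng)
        np.testing.assert_array_equal(fractions, [1.0, 0.0, 0.0, 0.0, 0.0])

    def test_truncated_mean_matches_monte_carlo_oracle(self, rng):
        # pre-renormalization delta draws for the encephalopathy group
        from eegbands.synth import _truncated_normal

        mean, sd = 67.73, 19.34
        draws = np.array([_truncated_normal(mean, sd, rng) for _ in range(10_000)])
        a = (0.0 - mean) / sd
        oracle = sps.truncnorm(a, np.inf, loc=mean, scale=sd)
        se = oracle.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - oracle.mean()) < 3 * se
        # truncation bias itself is small at this mean/sd ratio
        assert abs(oracle.mean() - mean) < 0.05

    def test_unknown_group_raises(self, rng):
        with pytest.raises(ConfigurationError):
            sample_band_fractions(_degenerate_params(), "martian", rng)

    def test_fractions_sum_to_one(self, rng):
        params = default_params(seed=0)
        for group in ("normal", "encephalopathy"):
            for _ in range(20):
                fractions = sample_band_fractions(params, group, rng)
                assert fractions.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(fractions >= 0)


class TestSynthesizeEpoch:
    def test_single_band_spectral_purity(self, rng):
        epoch = synthesize_epoch([1, 0, 0, 0, 0], 500.0, 12.0, 2500.0, rng)
        fractions = periodogram_band_fractions(
            epoch.samples, epoch.fs, {"above4": (4.0, 250.0)}
        )
        assert fractions["above4"] < 0.05

    def test_zero_power_gives_zero_epoch(self, rng):
        epoch = synthesize_epoch([0.5, 0.2, 0.2, 0.05, 0.05], 500.0, 12.0, 0.0, rng)
        assert not epoch.samples.any()

    def test_energy_accounting_against_periodogram(self, rng):
        requested = np.array([0.31, 0.20, 0.31, 0.15, 0.03])
        epoch = synthesize_epoch(requested, 500.0, 12.0, 2500.0, rng)
        edges = dict(CLINICAL_BAND_EDGES_HZ)
        measured = periodogram_band_fractions(epoch.samples, epoch.fs, edges)
        for band, want in zip(BANDS_WITH_RESIDUAL, requested):
            assert measured[band] == pytest.approx(want, abs=0.05)

    def test_total_energy_within_one_percent(self, rng):
        epoch = synthesize_epoch([0.4, 0.2, 0.2, 0.1, 0.1], 500.0, 12.0, 2500.0, rng)
        assert epoch.energy == pytest.approx(2500.0 * 6000, rel=0.01)

    def test_dwt_recovers_requested_fractions(self, rng):
        requested = np.array([0.31, 0.20, 0.31, 0.15, 0.03])
        epoch = synthesize_epoch(requested, 500.0, 12.0, 2500.0, rng)
        energies = epoch_band_energies(epoch, denoise=False)
        measured = [energies.rel[b] for b in ("delta", "theta", "alpha", "beta")]
        np.testing.assert_allclose(measured, requested[:4], atol=0.05)

    def test_invalid_fractions_raise(self, rng):
        with pytest.raises(InvalidInputError):
            synthesize_epoch([0.5, 0.2, 0.1, 0.1, 0.05], 500.0, 12.0, 2500.0, rng)
        with pytest.raises(InvalidInputError):
            synthesize_epoch([1.2, -0.2, 0, 0, 0], 500.0, 12.0, 2500.0, rng)


class TestGenerateCohort:
    def test_default_counts_and_lengths(self):
        params = default_params(seed=5, calibrate=False)
        cohort, manifest = generate_cohort(params)
        groups = [e.group for e in cohort]
        assert groups.count("encephalopathy") == 232
        assert groups.count("normal") == 218
        assert all(e.n_samples == 6000 for e in cohort)
        assert len(manifest["epochs"]) == 450

    def test_empty_cohort_valid_manifest(self):
        params = default_params(
            seed=1, n_epochs_per_group={"encephalopathy": 0, "normal": 0},
            calibrate=False,
        )
        cohort, manifest = generate_cohort(params)
        assert cohort == []
        assert manifest["epochs"] == []
        assert manifest["seed"] == 1

    def test_determinism_same_seed(self):
        params = default_params(
            seed=11, n_epochs_per_group={"encephalopathy": 3, "normal": 3},
            calibrate=False,
        )
        cohort_a, _ = generate_cohort(params)
        cohort_b, _ = generate_cohort(params)
        for a, b in zip(cohort_a, cohort_b):
            np.testing.assert_array_equal(a.samples, b.samples)
            assert a.epoch_id == b.epoch_id

    def test_different_seeds_differ(self):
        small = {"encephalopathy": 1, "normal": 1}
        a, _ = generate_cohort(default_params(seed=1, n_epochs_per_group=small, calibrate=False))
        b, _ = generate_cohort(default_params(seed=2, n_epochs_per_group=small, calibrate=False))
        assert not np.array_equal(a[0].samples, b[0].samples)

    def test_manifest_records_ground_truth(self):
        params = default_params(
            seed=3, n_epochs_per_group={"encephalopathy": 2, "normal": 2},
            calibrate=False,
        )
        _, manifest = generate_cohort(params)
        for record in manifest["epochs"]:
            fracs = record["true_fractions"]
            assert set(fracs) == set(BANDS_WITH_RESIDUAL)
            assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ConfigurationError):
            default_params(seed=0, fs=500.0, duration_s=0.0015)

    def test_group_separation_directional(self, small_uncalibrated_cohort):
        cohort, manifest = small_uncalibrated_cohort
        by_group = {"normal": [], "encephalopathy": []}
        for record in manifest["epochs"]:
            by_group[record["group"]].append(record["true_fractions"]["delta"])
        assert np.mean(by_group["encephalopathy"]) > np.mean(by_group["normal"])

    def test_trend_amplitude_adds_drift(self):
        small = {"encephalopathy": 1, "normal": 1}
        flat, _ = generate_cohort(
            default_params(seed=9, n_epochs_per_group=small, calibrate=False)
        )
        trended, _ = generate_cohort(
            default_params(
                seed=9, n_epochs_per_group=small, calibrate=False, trend_amplitude=200.0
            )
        )
        assert trended[0].energy > flat[0].energy

    def test_invalid_means_sum_rejected(self):
        stats = {
            "normal": {b: BandStats(30.0, 1.0) for b in BANDS_WITH_RESIDUAL}
        }  # 5 * 30 = 150 % > 100 %
        with pytest.raises(ConfigurationError):
            GeneratorParams(
                per_group_band_stats=stats, n_epochs_per_group={"normal": 1}
            )


class TestCalibratedCohort:
    def test_measured_group_means_near_targets(self, features_seed0):
        table = features_seed0
        for group, column, target in [
            ("encephalopathy", "delta_pct", 67.73),
            ("normal", "delta_pct", 31.39),
            ("normal", "alpha_pct", 30.60),
            ("encephalopathy", "beta_pct", 2.89),
        ]:
            measured = table.loc[table["group"] == group, column].mean()
            assert measured == pytest.approx(target, abs=2.5)

    def test_delta_ratio_near_two(self, features_seed0):
        table = features_seed0
        enc = table.loc[table["group"] == "encephalopathy", "delta_pct"].mean()
        nor = table.loc[table["group"] == "normal", "delta_pct"].mean()
        assert 1.8 <= enc / nor <= 2.6
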