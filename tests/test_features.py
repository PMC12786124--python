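"""Differential entropy, band power bookkeeping, demographic encoding."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma

from eegfuse.features import (BANDS, BandDefinition, band_psd,
                              differential_entropy, encode_demographics,
                              extract_de, fit_demographic_stats)
from eegfuse.preprocess import (bandpass_filter, segment_windows,
                                zscore_per_session)
from conftest import make_trial


def knn_entropy_1d(samples: np.ndarray) -> float:
    """Kozachenko-Leonenko nearest-neighbour entropy estimate (nats),
    an estimator independent of any Gaussian closed form."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    r = np.empty(n)
    r[1:-1] = np.minimum(x[1:-1] - x[:-2], x[2:] - x[1:-1])
    r[0] = x[1] - x[0]
    r[-1] = x[-1] - x[-2]
    r = np.maximum(r, 1e-15)
    return float(digamma(n) - digamma(1) + np.mean(np.log(2 * r)))


class TestDifferentialEntropy:
    def test_analytic_zero(self):
        assert differential_entropy(1.0 / (math.pi * math.e)) == pytest.approx(
            0.0, abs=1e-15)

    def test_quadrupling_power_adds_ln2(self):
        for s2 in (0.01, 1.0, 37.5):
            assert (differential_entropy(4 * s2) - differential_entropy(s2)
                    ) == pytest.approx(math.log(2), abs=1e-12)

    def test_monotone_in_power(self):
        values = differential_entropy(np.array([0.1, 1.0, 10.0]))
        assert np.all(np.diff(values) > 0)

    def test_nonpositive_power_rejected_unless_floored(self):
        with pytest.raises(ValueError):
            differential_entropy(0.0)
        assert np.isfinite(differential_entropy(0.0, floor=1e-12))

    def test_convention_offset_against_knn_estimator(self):
        # the default convention omits the factor 2 of the standard
        # Gaussian entropy, i.e. sits ln(2)/2 below it
        rng = np.random.default_rng(42)
        sigma2 = 2.5
        mc = knn_entropy_1d(rng.normal(0.0, np.sqrt(sigma2), size=100_000))
        assert differential_entropy(sigma2) == pytest.approx(
            mc - 0.5 * math.log(2), abs=0.02)
        assert differential_entropy(sigma2, convention="standard") == pytest.approx(
            mc, abs=0.02)


class TestBandPower:
    def test_band_edges_are_canonical(self):
        edges = {b.name: (b.low, b.high) for b in BANDS}
        assert edges == {"delta": (1, 4), "theta": (4, 8), "alpha": (8, 12),
                         "beta": (12, 30), "gamma": (30, 50)}

    def test_zero_window_zero_power(self):
        w = np.zeros((62, 800))
        for band in BANDS:
            assert band_psd(w, band, sampling_rate=200.0).sigma2.max() == 0.0

    def test_parseval_consistency_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 800))
        bp = band_psd(x, BANDS[0], sampling_rate=200.0)
        total = bp.spectrum.sum(axis=-1)
        np.testing.assert_allclose(total, (x**2).mean(axis=-1), rtol=1e-6)

    def test_sinusoid_concentrates_in_its_band(self):
        t = np.arange(800) / 200.0
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        alpha = band_psd(x, BANDS[2], sampling_rate=200.0).sigma2[0]
        beta = band_psd(x, BANDS[3], sampling_rate=200.0).sigma2[0]
        assert alpha / beta >= 100

    def test_bin_count_at_200hz(self):
        bp = band_psd(np.zeros((1, 800)), BandDefinition("alpha", 8, 12),
                      sampling_rate=200.0)
        assert bp.n_bins == 16          # 4 Hz span at 0.25 Hz spacing

    def test_empty_band_rejected(self):
        # bins sit at multiples of 0.25 Hz; (10.05, 10.2) contains none
        with pytest.raises(ValueError, match="no DFT bins"):
            band_psd(np.zeros((1, 800)), BandDefinition("x", 10.05, 10.2),
                     sampling_rate=200.0)


class TestExtractDE:
    def test_shape_from_windowing(self):
        trial = make_trial(seconds=61.0)
        de = extract_de(trial)
        assert de.values.shape == (15, 62, 5)
        assert np.isfinite(de.values).all()

    def test_amplitude_doubling_shifts_by_ln2(self):
        trial = make_trial(seconds=8.0, seed=3)
        doubled = make_trial(samples=2 * trial.samples)
        shift = extract_de(doubled).values - extract_de(trial).values
        np.testing.assert_allclose(shift, math.log(2), atol=1e-9)

    def test_rescaling_invariance_after_zscore(self):
        # global amplitude rescaling is an additive DE constant,
        # annihilated by per-session standardization
        trial = make_trial(seconds=20.0, seed=4)
        scaled = make_trial(samples=3.7 * trial.samples)
        a = extract_de(trial).values.reshape(5, -1)
        b = extract_de(scaled).values.reshape(5, -1)
        za = zscore_per_session(a, ["s"] * 5, [1] * 5)
        zb = zscore_per_session(b, ["s"] * 5, [1] * 5)
        np.testing.assert_allclose(za, zb, atol=1e-8)

    def test_band_limited_power_matches_closed_form(self):
        # white noise filtered to one band: mean DE equals the closed
        # form at the measured band power
        rng = np.random.default_rng(5)
        trial = make_trial(samples=rng.standard_normal((62, 160 * 100)), fs=160.0)
        filtered = bandpass_filter(trial, low=8.0, high=12.0)
        de = extract_de(filtered)
        alpha = de.values[:, :, 2]
        sigma2 = np.stack([
            band_psd(w.samples, BANDS[2], sampling_rate=160.0).sigma2
            for w in segment_windows(filtered)])
        np.testing.assert_allclose(
            alpha.mean(), differential_entropy(sigma2).mean(), atol=1e-12)


class TestDemographics:
    def table(self):
        return pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "age": [20, 22, 24, 26],
            "sex": ["M", "F", "M", "F"],
            "nationality": ["Chinese", "French", "German", "French"],
        })

    def test_nationality_dummy_codes(self):
        stats = fit_demographic_stats(self.table())
        raw_codes = {"Chinese": (0, 0), "French": (1, 0), "German": (0, 1)}
        for nat, bits in raw_codes.items():
            row = pd.DataFrame({"subject_id": ["x"], "age": [23],
                                "sex": ["M"], "nationality": [nat]})
            enc = encode_demographics(row, stats)
            # undo the standardization to recover the raw bits
            raw = enc[0] * stats.sd + stats.mean
            assert tuple(np.round(raw[2:4]).astype(int)) == bits

    def test_age_zscores_by_hand(self):
        enc = encode_demographics(self.table())
        # ages (20,22,24,26): mean 23, sample SD sqrt(20/3)
        sd = math.sqrt(20.0 / 3.0)
        np.testing.assert_allclose(enc[:, 0],
                                   (np.array([20, 22, 24, 26]) - 23.0) / sd,
                                   atol=1e-12)

    def test_constant_column_zeroed(self):
        t = self.table()
        t["sex"] = "M"
        with pytest.warns(UserWarning, match="constant"):
            enc = encode_demographics(t)
        np.testing.assert_allclose(enc[:, 1], 0.0)

    def test_unknown_nationality_rejected(self):
        t = self.table()
        t.loc[0, "nationality"] = "Martian"
        with pytest.raises(ValueError, match="Martian"):
            encode_demographics(t)

    def test_training_stats_applied_to_new_rows(self):
        stats = fit_demographic_stats(self.table())
        row = pd.DataFrame({"subject_id": ["x"], "age": [23], "sex": ["M"],
                            "nationality": ["Chinese"]})
        enc = encode_demographics(row, stats)
        assert enc[0, 0] == pytest.approx(0.0, abs=1e-12)  # age 23 == train mean
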