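"""Peak matching, spectral agreement metrics, RT calibration and schemas."""

import math

import numpy as np
import pytest

import _oracles
from varipept import features as feat
from varipept.predictors import FragmentIon, FragmentPrediction, surrogate_fragments
from varipept.spectra_io import ApexResult, PSMRecord


def _pred(mzs, intensities=None, series=None):
    n = len(mzs)
    intensities = intensities if intensities is not None else [1.0 / n] * n
    series = series or ["b"] * n
    ions = tuple(
        FragmentIon(series[k], k + 1, 1, mzs[k], intensities[k]) for k in range(n)
    )
    return FragmentPrediction("X||2", 2, ions)


def _psm(**kw):
    defaults = dict(
        spectrum_id="scan=1",
        peptide="MAAAGHIK",
        modifications=(),
        charge=2,
        engine_score=1.0,
        precursor_mz_measured=405.72,
    )
    defaults.update(kw)
    return PSMRecord(**defaults)


class TestMatchPeaks:
    def test_ppm_boundary(self):
        pred = _pred([500.0])
        inside = feat.match_peaks(np.array([500.0049]), np.array([1.0]), pred, 10.0)
        outside = feat.match_peaks(np.array([500.0051]), np.array([1.0]), pred, 10.0)
        assert len(inside.matched) == 1  # 9.8 ppm
        assert len(outside.matched) == 0  # 10.2 ppm

    def test_closer_ppm_wins_competition(self):
        pred = _pred([500.000, 500.004])
        pair = feat.match_peaks(np.array([500.0041]), np.array([1.0]), pred, 10.0)
        assert len(pair.matched) == 1
        assert pair.matched[0][0].ordinal == 2  # the nearer ion

    def test_each_observed_peak_used_once(self):
        pred = _pred([500.000, 500.002])
        pair = feat.match_peaks(
            np.array([500.000, 500.002]), np.array([1.0, 2.0]), pred, 10.0
        )
        assert len(pair.matched) == 2
        assert {oi for _, oi in pair.matched} == {0, 1}

    def test_group_filtering(self):
        pred = _pred([100.0, 200.0], series=["b", "y"])
        pair_b = feat.match_peaks(np.array([100.0, 200.0]), np.ones(2), pred, 10.0, "b")
        assert [ion.series for ion, _ in pair_b.matched] == ["b"]


class TestSimilarity:
    def test_zero_matches_hits_angular_floor(self):
        pred = _pred([500.0, 600.0, 700.0])
        pair = feat.match_peaks(np.array([501.0]), np.array([1.0]), pred, 10.0)
        s = feat.similarity_features(pair)
        assert s["cosine"] == 0.0
        assert s["angular"] == 0.5
        assert s["pct_matched"] == 0.0

    def test_identity_spectrum(self):
        intens = [0.5, 0.3, 0.2]
        pred = _pred([500.0, 600.0, 700.0], intens)
        pair = feat.match_peaks(
            np.array([500.0, 600.0, 700.0]), np.array(intens), pred, 10.0
        )
        s = feat.similarity_features(pair)
        assert s["cosine"] == pytest.approx(1.0, abs=1e-12)
        assert s["angular"] == pytest.approx(1.0, abs=1e-6)
        entropy = -sum(p * math.log(p + feat.EPSILON) for p in intens)
        assert s["cross_entropy"] == pytest.approx(entropy, abs=1e-9)

    def test_hand_computed_partial_overlap(self):
        # obs = (1, 0, 1), pred = (1, 1, 0): cosine 1/2, angular 2/3
        pred = _pred([500.0, 600.0, 700.0], [0.5, 0.5, 0.0])
        pair = feat.match_peaks(np.array([500.0, 700.0]), np.array([1.0, 1.0]), pred, 10.0)
        s = feat.similarity_features(pair)
        assert s["cosine"] == pytest.approx(0.5, abs=1e-12)
        assert s["angular"] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_empty_prediction_floors(self):
        pair = feat.MatchedSpectrumPair([], [], [], "all", np.empty(0), np.empty(0))
        s = feat.similarity_features(pair)
        assert s == {
            "pct_matched": 0.0,
            "log_distance": 0.0,
            "cosine": 0.0,
            "angular": 0.5,
            "cross_entropy": 0.0,
        }

    def test_cosine_invariant_to_intensity_scaling(self):
        rng = np.random.default_rng(2)
        pred = _pred(list(200.0 + 50 * np.arange(6)), list(rng.dirichlet(np.ones(6))))
        obs_mz = np.array([200.0, 300.0, 450.0])
        obs = rng.uniform(0.1, 1.0, 3)
        s1 = feat.similarity_features(feat.match_peaks(obs_mz, obs, pred, 10.0))
        s2 = feat.similarity_features(feat.match_peaks(obs_mz, 1e4 * obs, pred, 10.0))
        assert s1["cosine"] == pytest.approx(s2["cosine"], rel=1e-12)
        assert s1["angular"] == pytest.approx(s2["angular"], rel=1e-12)

    def test_angular_range_property(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 12))
            pred = _pred(
                list(np.sort(rng.uniform(150, 1200, n))), list(rng.dirichlet(np.ones(n)))
            )
            m = int(rng.integers(0, 8))
            obs_mz = np.sort(rng.uniform(150, 1200, m))
            obs = rng.uniform(0, 1, m)
            s = feat.similarity_features(feat.match_peaks(obs_mz, obs, pred, 25.0))
            assert 0.5 <= s["angular"] <= 1.0
            assert (s["angular"] == 0.5) == (s["cosine"] == 0.0)

    def test_pct_matched_monotone_in_tolerance(self):
        rng = np.random.default_rng(9)
        pred = surrogate_fragments("MAAAGHIWK", 2)
        obs_mz = np.sort(
            np.array([i.mz for i in pred.ions]) * (1 + rng.normal(0, 8e-6, len(pred.ions)))
        )
        obs = np.ones(obs_mz.size)
        last = math.inf
        for tol in (20.0, 10.0, 5.0, 2.0, 0.5):
            s = feat.similarity_features(feat.match_peaks(obs_mz, obs, pred, tol))
            assert s["pct_matched"] <= last
            last = s["pct_matched"]


class TestConsecutiveRuns:
    def _pair(self, ordinals, series):
        ions = [FragmentIon(series, o, 1, 100.0 * o, 0.1) for o in ordinals]
        return feat.MatchedSpectrumPair(
            [(ion, i) for i, ion in enumerate(ions)], [], [], series,
            np.array([100.0 * o for o in ordinals]), np.ones(len(ions)),
        )

    def test_run_with_gap(self):
        b = self._pair([1, 2, 3, 5], "b")
        y = self._pair([], "y")
        assert feat.consecutive_runs(b, y) == (3, 0)

    def test_complete_ladder(self):
        n = 9
        y = self._pair(list(range(1, n)), "y")
        assert feat.consecutive_runs(self._pair([], "b"), y) == (0, n - 1)


class TestCalibration:
    def test_exact_linear_fit(self):
        pts = [(2 * x + 10, x) for x in (0.0, 50.0, 100.0, 150.0)]
        model = feat.calibrate_rt(pts)
        assert model.slope == pytest.approx(2.0, abs=1e-9)
        assert model.intercept == pytest.approx(10.0, abs=1e-9)
        assert model.n_calibration_psms == 4

    def test_slope_recovery_under_noise(self):
        rng = np.random.default_rng(21)
        pred = rng.uniform(0, 1000, 200)
        apex = 1.8 * pred + 120 + rng.normal(0, 5, 200)
        model = feat.calibrate_rt(list(zip(apex, pred)))
        assert model.slope == pytest.approx(1.8, rel=0.01)

    def test_too_few_or_degenerate(self):
        with pytest.raises(feat.CalibrationError):
            feat.calibrate_rt([(10.0, 5.0)])
        with pytest.raises(feat.CalibrationError):
            feat.calibrate_rt([(10.0, 5.0), (20.0, 5.0)])


class TestRtFeatures:
    def test_zero_residual(self):
        model = feat.CalibrationModel(1.0, 0.0, 10)
        apex = ApexResult("s", 100.0, "xic_apex")
        out = feat.rt_features(_psm(), apex, model, 100.0, rt_ms2=97.0)
        assert out["rt_abs_error"] == 0.0
        assert out["rt_sq_error"] == 0.0
        assert out["rt_log_error"] == 0.0
        assert out["rt_meas_apex_abs"] == pytest.approx(3.0)

    def test_hand_computed_residual(self):
        model = feat.CalibrationModel(1.0, 0.0, 10)
        apex = ApexResult("s", 97.0, "xic_apex")
        out = feat.rt_features(_psm(), apex, model, 100.0, rt_ms2=97.0)
        assert out["rt_abs_error"] == pytest.approx(3.0)
        assert out["rt_sq_error"] == pytest.approx(9.0)
        assert out["rt_log_error"] == pytest.approx(math.log(4.0))

    def test_fallback_apex_means_zero_distance(self):
        model = feat.CalibrationModel(1.0, 0.0, 10)
        apex = ApexResult("s", 250.0, "ms2_fallback")
        out = feat.rt_features(_psm(), apex, model, 100.0, rt_ms2=250.0)
        assert out["rt_meas_apex_abs"] == 0.0


class TestSchemas:
    def test_cardinalities(self):
        assert len(feat.STANDARD_FEATURES) == 18
        assert len(feat.EXTENDED_FEATURES) == 40
        extra = set(feat.EXTENDED_FEATURES) - set(feat.STANDARD_FEATURES)
        assert len(extra) == 22

    def test_assemble_counts_on_synthetic_psm(self, default_tables):
        std = default_tables.standard[0]
        ext = default_tables.extended[0]
        assert len(std.values) == 18
        assert len(ext.values) == 40

    def test_missing_part_named(self):
        parts = {n: 0.0 for n in feat.STANDARD_FEATURES if n != "delta_score"}
        with pytest.raises(ValueError, match="delta_score"):
            feat.assemble(_psm(), "standard", parts)


class TestOracleEquivalence:
    def test_matches_bruteforce_on_random_psms(self, default_sim, default_tables):
        """All similarity and RT features agree with an independent naive
        implementation on 500 synthetic PSMs to 1e-9 relative tolerance."""
        model = default_tables.calibration
        spectra = {s.spectrum_id: s for s in default_sim.ms2}
        diag = default_tables.diagnostics.set_index("spectrum_id")
        checked = 0
        for psm, ext in zip(default_sim.psms, default_tables.extended):
            if checked >= 500:
                break
            spec = spectra[psm.spectrum_id]
            pred = surrogate_fragments(psm.peptide, psm.charge)
            for group in ("b", "y", "all"):
                ions = [
                    i for i in pred.ions if group == "all" or i.series == group
                ]
                matched = _oracles.naive_match(spec.mz, spec.intensity, ions, 10.0)
                expect = _oracles.naive_similarity(ions, matched, spec.intensity)
                for name, val in expect.items():
                    got = ext.values[f"{name}_{group}"]
                    assert got == pytest.approx(val, rel=1e-9, abs=1e-12), (
                        psm.spectrum_id,
                        group,
                        name,
                    )
            row = diag.loc[psm.spectrum_id]
            expect_rt = _oracles.naive_rt_features(
                row["rt_apex"], row["rt_predicted"], model.slope, model.intercept,
                spec.rt_seconds,
            )
            for name, val in expect_rt.items():
                assert ext.values[name] == pytest.approx(val, rel=1e-9, abs=1e-12)
            checked += 1
        assert checked == 500
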