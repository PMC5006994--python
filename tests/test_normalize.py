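"""RQC reliability, run segmentation, and the drift-correction equation."""

import numpy as np
import pandas as pd
import pytest

from metaboqc import (
    SimulationConfig,
    count_undetectable,
    interpolate_sensitivity,
    is_reliable_rqc,
    normalize_table,
    segment_run,
    simulate_intensities,
    RQCDriftNormalizer,
)

from conftest import feature_frame, make_table, manifest_frame


def _rqc_table(values):
    """Ten-feature table with one RQC injection holding the given values."""
    feats = feature_frame([f"f{i}" for i in range(len(values))])
    man = manifest_frame([("rqc1", 0, "RQC")])
    return make_table(feats, man, np.array(values, dtype=float)[:, None])


class TestReliability:
    def test_all_present_counts_zero(self):
        t = _rqc_table([1.0] * 10)
        assert count_undetectable(t, "rqc1") == 0

    def test_missing_and_zero_both_count(self):
        vals = [1.0] * 7 + [np.nan, np.nan, 0.0]
        assert count_undetectable(_rqc_table(vals), "rqc1") == 3

    def test_unknown_injection_errors(self):
        with pytest.raises(KeyError):
            count_undetectable(_rqc_table([1.0]), "nope")

    @pytest.mark.parametrize("n_undetectable,expected", [(999, True), (1000, False), (0, True)])
    def test_threshold_is_strictly_less_than(self, n_undetectable, expected):
        vals = [np.nan] * n_undetectable + [1.0] * (1200 - n_undetectable)
        assert is_reliable_rqc(_rqc_table(vals), "rqc1", threshold=1000) is expected

    def test_fractional_threshold_scales_with_feature_count(self):
        t = _rqc_table([np.nan] * 6 + [1.0] * 4)
        assert not is_reliable_rqc(t, "rqc1", threshold=0.5)
        assert is_reliable_rqc(t, "rqc1", threshold=0.7)

    def test_non_rqc_injection_rejected(self):
        feats = feature_frame(["f0"])
        man = manifest_frame([("i1", 0, "study", "s")])
        t = make_table(feats, man, [[1.0]])
        with pytest.raises(ValueError, match="role"):
            is_reliable_rqc(t, "i1")


class TestSegmentation:
    def _run(self, middle_rqc_values):
        rows = [("rqc1", 0, "RQC")]
        rows += [(f"a{i}", i, "study", f"sa{i}") for i in range(1, 9)]
        rows += [("rqc2", 9, "RQC")]
        rows += [(f"b{i}", 9 + i, "study", f"sb{i}") for i in range(1, 9)]
        rows += [("rqc3", 18, "RQC")]
        feats = feature_frame([f"f{i}" for i in range(4)])
        X = np.ones((4, 19))
        X[:, 9] = middle_rqc_values
        return make_table(feats, manifest_frame(rows), X)

    def test_reliable_rqcs_pair_into_unit_segments(self):
        segs = segment_run(self._run([1.0] * 4), threshold=0.5)
        assert [s.S for s in segs] == [8, 8]

    def test_unreliable_rqc_merges_flanking_segments(self):
        segs = segment_run(self._run([np.nan] * 4), threshold=0.5)
        assert len(segs) == 1 and segs[0].S == 16
        assert (segs[0].left_rqc, segs[0].right_rqc) == ("rqc1", "rqc3")

    def test_adjacent_rqcs_give_empty_segment(self):
        feats = feature_frame(["f0"])
        man = manifest_frame([("rqc1", 0, "RQC"), ("rqc2", 1, "RQC")])
        segs = segment_run(make_table(feats, man, [[1.0, 1.0]]), threshold=0.5)
        assert len(segs) == 1 and segs[0].S == 0

    def test_fewer_than_two_reliable_rqcs_errors(self):
        feats = feature_frame(["f0"])
        man = manifest_frame([("rqc1", 0, "RQC")])
        with pytest.raises(ValueError, match="raw"):
            segment_run(make_table(feats, man, [[1.0]]), threshold=0.5)


class TestInterpolation:
    def test_printed_divisor_example(self):
        assert interpolate_sensitivity(100, 190, n=1, S=8) == pytest.approx(110.0)

    def test_endpoints(self):
        assert interpolate_sensitivity(100, 190, 0, 8) == 100
        assert interpolate_sensitivity(100, 190, 9, 8) == 190

    def test_no_drift_is_constant(self):
        for n in range(10):
            assert interpolate_sensitivity(42.0, 42.0, n, 8) == 42.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            interpolate_sensitivity(100, 190, 10, 8)
        with pytest.raises(ValueError):
            interpolate_sensitivity(0, 190, 1, 8)


class TestNormalization:
    def test_hand_example(self, simple_segment_table):
        out, _ = normalize_table(simple_segment_table, threshold=0.5, mode="literal")
        # x_1 = 220 with M1=100, M2=190: y = 220*100/110 = 200
        assert out.X.loc["f1", "s1"] == pytest.approx(200.0)

    def test_equal_rqcs_identity_is_exact(self):
        cfg = SimulationConfig(n_plates=1, n_study_per_plate=16, n_features=25,
                               noise_cv=0.0, drift_amplitude=0.0, plate_jump=0.0, seed=2)
        t, _ = simulate_intensities(cfg)
        for mode in ("literal", "anchored"):
            out, _ = normalize_table(t, 0.5, mode)
            assert out.X.equals(t.X)

    def test_linear_drift_oracle(self):
        cfg = SimulationConfig(n_plates=2, n_study_per_plate=24, n_features=40,
                               noise_cv=0.0, drift_amplitude=0.3, plate_jump=0.2, seed=1)
        t, gt = simulate_intensities(cfg)
        segs = segment_run(t, 0.5)
        lit, _ = normalize_table(t, 0.5, "literal")
        anc, _ = normalize_table(t, 0.5, "anchored")
        g = gt.sensitivity
        first = segs[0].left_rqc
        for seg in segs:
            for inj in seg.study_injections:
                truth = gt.true_abundance[t.manifest.loc[inj, "sample_id"]]
                np.testing.assert_allclose(lit.X[inj], truth * g[seg.left_rqc], rtol=1e-9)
                np.testing.assert_allclose(anc.X[inj], truth * g[first], rtol=1e-9)

    def test_anchored_rqcs_collapse_onto_first(self):
        cfg = SimulationConfig(n_plates=2, n_study_per_plate=16, n_features=30,
                               noise_cv=0.0, drift_amplitude=0.3, plate_jump=0.2, seed=4)
        t, _ = simulate_intensities(cfg)
        anc, _ = normalize_table(t, 0.5, "anchored")
        rqcs = t.injections("RQC").index
        ref = anc.X[rqcs[0]]
        for r in rqcs[1:]:
            np.testing.assert_allclose(anc.X[r], ref, rtol=1e-9)

    def test_missingness_preserved_and_nonnegative(self, simple_segment_table):
        t = simple_segment_table.copy()
        t.X.loc["f1", "s3"] = np.nan
        out, _ = normalize_table(t, 0.5, "anchored")
        assert np.isnan(out.X.loc["f1", "s3"])
        assert (out.X.fillna(0) >= 0).all().all()

    def test_uncovered_injections_pass_through_flagged(self):
        rows = [("sqc0", 0, "SQC"), ("rqc1", 1, "RQC"),
                ("s1", 2, "study", "a"), ("rqc2", 3, "RQC"), ("tail", 4, "SQC")]
        feats = feature_frame(["f"])
        t = make_table(feats, manifest_frame(rows), [[7.0, 100.0, 110.0, 120.0, 9.0]])
        out, rep = normalize_table(t, 0.5, "literal")
        assert set(rep.uncovered_injections) == {"sqc0", "tail"}
        assert out.X.loc["f", "sqc0"] == 7.0 and out.X.loc["f", "tail"] == 9.0

    def test_flank_fallback_uses_nearest_quantified_rqc(self):
        rows = [("rqc1", 0, "RQC"), ("s1", 1, "study", "a"),
                ("rqc2", 2, "RQC"), ("s2", 3, "study", "b"), ("rqc3", 4, "RQC")]
        # f1 undetected in rqc2, but rqc2 stays reliable thanks to f2
        X = [[100.0, 200.0, np.nan, 300.0, 100.0],
             [50.0, 60.0, 50.0, 70.0, 50.0]]
        t = make_table(feature_frame(["f1", "f2"]), manifest_frame(rows), X)
        out, rep = normalize_table(t, 0.9, "literal")
        # f1's right flank falls back to rqc3 (100): M1 = M2 = 100 → identity
        assert out.X.loc["f1", "s1"] == pytest.approx(200.0)
        assert rep.fallback_features >= 1

    def test_estimator_wrapper_matches_function(self, simple_segment_table):
        est = RQCDriftNormalizer(mode="literal", rqc_threshold=0.5)
        out = est.fit_transform(simple_segment_table)
        ref, _ = normalize_table(simple_segment_table, 0.5, "literal")
        pd.testing.assert_frame_equal(out.X, ref.X)
        assert est.get_params()["mode"] == "literal"
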