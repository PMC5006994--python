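"""Plate layout, run order, drift/noise model, and end-to-end recovery."""

import re

import numpy as np
import pandas as pd
import pytest

from metaboqc import (
    FilterConfig,
    ScoreConfig,
    SimulationConfig,
    apply_all_filters,
    make_plate_layout,
    make_run_order,
    normalize_table,
    segment_run,
    simulate_intensities,
    simulate_storage_series,
)
from metaboqc.scoring import compute_quality_score, marker_nlas_from_table


class TestLayout:
    def test_default_plate_has_88_study_and_6_qc_wells(self):
        layout = make_plate_layout()
        assert (layout["role"] == "study").sum() == 88
        assert set(layout.index[layout["role"] != "study"]) == \
            {"A12", "B12", "C12", "D12", "E12", "F12", "H12"}
        assert layout.loc["A12", "role"] == "RQC"
        assert layout.loc["H12", "role"] == "blank"

    def test_reduced_study_count_keeps_qc_wells(self):
        layout = make_plate_layout(24)
        assert (layout["role"] == "study").sum() == 24
        assert (layout["role"] == "dQC").sum() == 4

    def test_well_ids_are_valid_96_well_coordinates(self):
        layout = make_plate_layout()
        assert all(re.fullmatch(r"[A-H](1[0-2]|[1-9])", w) for w in layout.index)

    def test_oversize_rejected(self):
        with pytest.raises(ValueError):
            make_plate_layout(89)


class TestRunOrder:
    def test_starts_with_ten_conditioning_sqcs(self):
        man = make_run_order(SimulationConfig(seed=0))
        assert (man.iloc[:10]["role"] == "SQC").all()
        assert man.iloc[10]["role"] == "RQC"

    def test_88_study_samples_give_11_blocks(self):
        man = make_run_order(SimulationConfig(seed=0))
        assert (man["role"] == "study").sum() == 88
        assert (man["role"] == "RQC").sum() == 12  # 11 block openers + closer

    def test_sqc_after_every_eight_study_samples(self):
        man = make_run_order(SimulationConfig(seed=0))
        roles = man["role"].tolist()[10:]  # past conditioning
        for b in range(11):
            block = roles[b * 10:(b + 1) * 10]
            assert block == ["RQC"] + ["study"] * 8 + ["SQC"]

    def test_tail_is_closing_rqc_then_dilution_series(self):
        man = make_run_order(SimulationConfig(seed=0))
        tail = man.iloc[-16:]
        assert tail.iloc[0]["role"] == "RQC"
        folds = tail.iloc[1:13]["dilution_fold"].astype(int).tolist()
        assert folds == [16] * 3 + [8] * 3 + [4] * 3 + [2] * 3
        assert (tail.iloc[13:]["role"] == "SQC").all()

    def test_study_order_randomized_by_seed(self):
        man1 = make_run_order(SimulationConfig(seed=1))
        man2 = make_run_order(SimulationConfig(seed=2))
        s1 = man1.loc[man1["role"] == "study", "sample_id"].tolist()
        s2 = man2.loc[man2["role"] == "study", "sample_id"].tolist()
        assert sorted(s1) == sorted(s2) and s1 != s2


class TestIntensities:
    def test_identical_config_is_bit_identical(self):
        cfg = SimulationConfig(n_features=40, n_study_per_plate=16, seed=9)
        t1, gt1 = simulate_intensities(cfg)
        t2, gt2 = simulate_intensities(cfg)
        pd.testing.assert_frame_equal(t1.X, t2.X)
        pd.testing.assert_frame_equal(gt1.sensitivity, gt2.sensitivity)

    def test_noiseless_driftless_replicates_identical(self):
        cfg = SimulationConfig(n_features=20, n_study_per_plate=8, n_donors=2,
                               noise_cv=0.0, drift_amplitude=0.0, plate_jump=0.0, seed=5)
        t, gt = simulate_intensities(cfg)
        study = t.manifest[t.manifest["role"] == "study"]
        d1 = study.index[study["sample_id"].str.contains("D1")]
        assert (t.X[d1].nunique(axis=1) == 1).all()

    def test_dqc_means_inverse_to_fold(self):
        cfg = SimulationConfig(n_features=20, n_study_per_plate=8,
                               noise_cv=0.0, drift_amplitude=0.0, seed=5)
        t, _ = simulate_intensities(cfg)
        man = t.manifest
        sqc_cols = man.index[(man["role"] == "SQC")]
        base = t.X[sqc_cols[-1]]
        for fold in (2, 4, 8, 16):
            cols = man.index[(man["role"] == "dQC") & (man["dilution_fold"] == fold)]
            np.testing.assert_allclose(t.X[cols].mean(axis=1), base / fold, rtol=1e-9)

    def test_forced_rqc_failure_is_skipped_by_segmentation(self):
        cfg = SimulationConfig(n_features=50, n_study_per_plate=24,
                               forced_failed_rqcs=(1,), seed=6)
        t, _ = simulate_intensities(cfg)
        rqcs = t.injections("RQC").index.tolist()
        segs = segment_run(t, threshold=0.5)
        covered = {s.left_rqc for s in segs} | {s.right_rqc for s in segs}
        assert rqcs[1] not in covered
        assert any(s.S == 16 for s in segs)

    def test_every_injection_has_one_manifest_entry_and_truth_dims_match(self):
        cfg = SimulationConfig(n_features=15, n_study_per_plate=8, seed=3)
        t, gt = simulate_intensities(cfg)
        assert t.manifest.index.is_unique
        assert list(t.X.columns) == list(t.manifest.index)
        assert gt.sensitivity.shape == t.X.shape
        assert set(gt.true_abundance.columns) == set(
            t.manifest.loc[t.manifest["role"] == "study", "sample_id"])


class TestStorageSeries:
    def test_six_donors_eleven_conditions_give_66_samples(self, markers):
        cfg = SimulationConfig(seed=1)
        table, gt = simulate_storage_series(cfg, markers)
        assert len(gt.sample_meta) == 66
        assert (table.manifest["role"] == "study").sum() == 66

    def test_marker_feature_mean_tracks_trendline_at_48h(self, markers):
        from metaboqc.trendlines import evaluate_trendline
        cfg = SimulationConfig(noise_cv=0.03, donor_cv=0.05, drift_amplitude=0.0,
                               plate_jump=0.0, seed=2)
        table, gt = simulate_storage_series(cfg, markers)
        study = table.manifest[table.manifest["role"] == "study"]
        cols = study.index[(study["storage_temp"].astype(str) == "25")
                           & (study["storage_hours"].astype(float) == 48)]
        m = markers[2]  # oleoylcarnitine, a well-behaved power marker
        fid = gt.true_marker_ids[2]
        observed = table.X.loc[fid, cols].mean()
        assert observed == pytest.approx(evaluate_trendline(m.fit, 48.0), rel=0.1)

    def test_cold_series_is_flat(self, markers):
        """At 4 °C marker abundances have no storage-time trend: the slope of
        a per-feature regression on time is non-significant for ≥95%."""
        from scipy import stats
        cfg = SimulationConfig(noise_cv=0.05, drift_amplitude=0.0, plate_jump=0.0, seed=8)
        table, gt = simulate_storage_series(cfg, markers)
        study = table.manifest[table.manifest["role"] == "study"]
        cold = study[(study["storage_temp"].astype(str) == "4")]
        hours = cold["storage_hours"].astype(float).to_numpy()
        n_sig = 0
        for fid in gt.true_marker_ids:
            y = np.log(table.X.loc[fid, cold.index].to_numpy(dtype=float))
            res = stats.linregress(hours, y)
            n_sig += res.pvalue < 0.05
        assert n_sig <= 0.05 * len(gt.true_marker_ids) + 1


def test_end_to_end_scores_fresh_above_stale(markers):
    """simulate → normalize(anchored) → filter → score ranks 0–6 h samples
    above 48-h samples in direction-aware mode, for every seeded replicate."""
    for rep in range(20):
        cfg = SimulationConfig(noise_cv=0.05, drift_amplitude=0.3, plate_jump=0.2,
                               seed=300 + rep)
        table, _ = simulate_storage_series(cfg, markers, n_null_features=20)
        normalized, _ = normalize_table(table, 0.5, "anchored")
        filtered, _ = apply_all_filters(normalized, FilterConfig())
        study = filtered.manifest[filtered.manifest["role"] == "study"]
        hours = study["storage_hours"].astype(float)
        temp = study["storage_temp"].astype(str)
        fresh = study.index[(hours <= 6) & (temp != "25") | (hours == 0)]
        stale = study.index[(hours == 48) & (temp == "25")]
        sc = ScoreConfig("direction_aware")

        def mean_score(cols):
            vals = [compute_quality_score(
                marker_nlas_from_table(filtered, markers, c), markers, sc).total
                for c in cols]
            return float(np.mean(vals))

        assert mean_score(fresh) > mean_score(stale), f"replicate {rep}"
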