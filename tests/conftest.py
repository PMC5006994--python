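"""Shared fixtures: hand-written small tables and the constructed QC-filter
fixture with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metaboqc import FeatureTable, load_marker_table


def make_table(features: pd.DataFrame, manifest: pd.DataFrame, X) -> FeatureTable:
    Xdf = pd.DataFrame(np.asarray(X, dtype=float),
                       index=features.index, columns=manifest.index)
    return FeatureTable(features, manifest, Xdf)


def feature_frame(ids, mz=200.0, mode="C18pos", annotation=None):
    n = len(ids)
    return pd.DataFrame({
        "mz": np.full(n, mz, dtype=float) if np.isscalar(mz) else np.asarray(mz, dtype=float),
        "rt": np.linspace(1.0, 10.0, n),
        "assay_mode": [mode] * n if isinstance(mode, str) else list(mode),
        "annotation": [annotation] * n if annotation is None or isinstance(annotation, str) else list(annotation),
    }, index=pd.Index(ids, name="feature_id"))


def manifest_frame(rows) -> pd.DataFrame:
    """rows: list of (injection_id, run_index, role[, sample_id[, fold]])."""
    recs = []
    for row in rows:
        inj, ri, role = row[:3]
        sid = row[3] if len(row) > 3 else None
        fold = row[4] if len(row) > 4 else (1 if role == "SQC" else None)
        recs.append({"injection_id": inj, "run_index": ri, "plate_id": "plate1",
                     "role": role, "sample_id": sid, "dilution_fold": fold})
    man = pd.DataFrame(recs).set_index("injection_id")
    man["dilution_fold"] = man["dilution_fold"].astype("Int64")
    return man


@pytest.fixture(scope="session")
def markers():
    return load_marker_table()


@pytest.fixture()
def simple_segment_table():
    """RQC(100), eight study injections, RQC(190): one segment with S = 8."""
    rows = [("rqc1", 0, "RQC")]
    rows += [(f"s{i}", i, "study", f"samp{i}") for i in range(1, 9)]
    rows += [("rqc2", 9, "RQC")]
    man = manifest_frame(rows)
    feats = feature_frame(["f1"])
    x = [[100.0, 220.0, 120.0, 130.0, 140.0, 150.0, 160.0, 170.0, 180.0, 190.0]]
    return make_table(feats, man, x)


def build_filter_fixture() -> tuple[FeatureTable, dict]:
    """100-feature table with engineered, disjoint filter violations.

    10 features fail the SQC CV rule, 5 fail dQC monotonicity, 3 exceed the
    m/z caps; 82 clean features remain.  Returns the table and the expected
    reason map.
    """
    n = 100
    ids = [f"f{i:03d}" for i in range(n)]
    mz = np.full(n, 200.0)
    modes = ["C18pos"] * n
    # features 15..17: above the m/z caps
    mz[15], mz[16] = 960.0, 1200.0
    mz[17], modes[17] = 701.0, "HILICpos"
    feats = feature_frame(ids, mz=mz, mode=modes)

    rows = [(f"cond{i}", i, "SQC") for i in range(10)]               # conditioning
    rows += [(f"sqc{i}", 10 + i, "SQC") for i in range(6)]            # intercalated
    run = 16
    dqc_cols: dict[int, list[str]] = {}
    for fold in (16, 8, 4, 2):
        dqc_cols[fold] = []
        for r in range(3):
            inj = f"d{fold}_{r}"
            rows.append((inj, run, "dQC", None, fold))
            dqc_cols[fold].append(inj)
            run += 1
    trailing = [f"tsqc{r}" for r in range(3)]
    rows += [(inj, run + r, "SQC") for r, inj in enumerate(trailing)]
    man = manifest_frame(rows)

    X = pd.DataFrame(0.0, index=feats.index, columns=man.index)
    base_sqc = 1000.0
    for col in [f"cond{i}" for i in range(10)] + [f"sqc{i}" for i in range(6)] + trailing:
        X[col] = base_sqc
    for fold in (16, 8, 4, 2):
        for col in dqc_cols[fold]:
            X[col] = base_sqc / fold

    expected: dict[str, list[str]] = {}
    for i in range(10):                      # SQC repeatability violators
        fid = ids[i]
        X.loc[fid, ["sqc0", "sqc1"]] = [200.0, 1800.0]
        expected[fid] = ["sqc_cv"]
    for i in range(10, 15):                  # dilution-response violators
        fid = ids[i]
        for col in dqc_cols[8]:
            X.loc[fid, col] = 400.0          # d8 mean above d4 mean (250)
        expected[fid] = ["dqc_monotonicity"]
    for i in (15, 16, 17):
        expected[ids[i]] = ["mz_cap"]

    return make_table(feats, man, X.to_numpy()), expected


@pytest.fixture()
def filter_fixture():
    return build_filter_fixture()
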