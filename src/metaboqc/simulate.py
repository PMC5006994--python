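"""Synthetic feature-table generator with ground truth.

Emulates the statistical structure the QC protocol assumes: a 96-well plate
layout (study samples in A1–H11, QC wells in column 12), a run order opening
with ten column-conditioning SQC injections, RQC-bracketed blocks of eight
randomized study injections each followed by an SQC, a closing RQC, and an
end-of-run dilution series (d16/d8/d4/d2 triplets plus an SQC triplet).

Intensities follow

    intensity(i, f) = truth(sample(i), f) · g(i, f) · exp(ε),   ε ~ N(0, σ²)

with multiplicative lognormal noise and a per-feature sensitivity g that is
piecewise linear between RQC injections (in the same segment coordinate the
normalizer uses, so the drift model is exactly invertible on noiseless
data).  Sensitivity steps between RQC nodes are bounded by
``drift_amplitude``; an additional per-feature discontinuity of size
``plate_jump`` applies at each plate boundary.  QC truths are derived from
the study samples: SQC is the per-feature mean of all study truths (a pooled
mixture), dQC truths are SQC divided by the dilution fold, and the RQC is an
independent reference at the feature baseline.

Degraded RQC injections (probability ``rqc_failure_prob``, or forced by
ordinal) have a large fraction of features set missing, so that the
reliability rule rejects them.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import QualityMarker
from .table import FeatureTable
from .trendlines import evaluate_trendline

log = logging.getLogger(__name__)

MAX_STUDY_PER_PLATE = 88
_ROWS = string.ascii_uppercase[:8]  # A..H


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    Defaults mirror the canonical protocol: 88 study samples per plate,
    blocks of 8 between RQCs, 10 conditioning SQCs, dilution folds
    2/4/8/16 in triplicate, and — for storage series — 6 donors × times
    {3, 6, 12, 24, 48} h × temperatures {4, 25} °C plus a 0-h control.
    Noise and drift are multiplicative (intensities stay positive);
    donor-to-donor biological variation is lognormal with CV 20%.
    """

    n_plates: int = 1
    n_study_per_plate: int = 88
    n_features: int = 200
    assay_mode: str = "C18pos"
    block_size: int = 8
    n_conditioning_sqc: int = 10
    n_donors: int | None = None
    replicate_across_plates: bool = False
    drift_amplitude: float = 0.30
    plate_jump: float = 0.20
    noise_cv: float = 0.05
    donor_cv: float = 0.20
    rqc_failure_prob: float = 0.0
    rqc_degraded_fraction: float = 0.8
    forced_failed_rqcs: tuple = ()
    baseline_log10_mean: float = 5.0
    baseline_log10_sd: float = 0.8
    storage_times: tuple = (3.0, 6.0, 12.0, 24.0, 48.0)
    storage_temps: tuple = (4, 25)
    n_storage_donors: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rqc_failure_prob <= 1):
            raise ValueError("rqc_failure_prob must be in [0, 1]")
        for name in ("drift_amplitude", "plate_jump", "noise_cv", "donor_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_study_per_plate > MAX_STUDY_PER_PLATE:
            raise ValueError(f"at most {MAX_STUDY_PER_PLATE} study wells per plate")


@dataclass
class GroundTruth:
    """Everything a test needs to verify the pipeline against construction."""

    true_abundance: pd.DataFrame     # features × samples
    sensitivity: pd.DataFrame        # features × injections (g)
    sample_meta: pd.DataFrame        # per-sample design metadata
    true_marker_ids: list = field(default_factory=list)
    true_discriminative_ids: list = field(default_factory=list)


def make_plate_layout(n_study: int = MAX_STUDY_PER_PLATE) -> pd.DataFrame:
    """96-well plate map: study wells A1–H11 (column-major), QC in column 12
    (A12 RQC, B12 SQC, C12–F12 d2/d4/d8/d16, H12 blank)."""
    if n_study > MAX_STUDY_PER_PLATE:
        raise ValueError(f"at most {MAX_STUDY_PER_PLATE} study wells, got {n_study}")
    wells = [f"{row}{col}" for col in range(1, 12) for row in _ROWS][:n_study]
    rows = [{"well": w, "role": "study", "slot": i + 1} for i, w in enumerate(wells)]
    rows.append({"well": "A12", "role": "RQC", "slot": None})
    rows.append({"well": "B12", "role": "SQC", "slot": None})
    for well, fold in zip(("C12", "D12", "E12", "F12"), (2, 4, 8, 16)):
        rows.append({"well": well, "role": "dQC", "slot": fold})
    rows.append({"well": "H12", "role": "blank", "slot": None})
    return pd.DataFrame(rows).set_index("well")


def make_run_order(cfg: SimulationConfig,
                   sample_ids_by_plate: list[list[str]] | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Injection manifest for a full analytical sequence.

    Ten conditioning SQCs, then per plate repeating blocks of
    [RQC, ``block_size`` randomized study injections, SQC], a closing RQC,
    and the dilution series d16/d8/d4/d2 in triplicate followed by an SQC
    triplet.  Study order within each plate is randomized by the seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if sample_ids_by_plate is None:
        sample_ids_by_plate = [
            [f"P{p + 1}S{s + 1:02d}" for s in range(cfg.n_study_per_plate)]
            for p in range(cfg.n_plates)
        ]
    records = []
    counters = {"SQC": 0, "RQC": 0, "dQC": 0, "study": 0}

    def emit(role, plate_id, sample_id=None, fold=None):
        counters[role] += 1
        inj_id = f"{role}{counters[role]:03d}" if role != "dQC" else f"d{fold}QC_{counters[role]:03d}"
        records.append({
            "injection_id": inj_id, "run_index": len(records), "plate_id": plate_id,
            "role": role, "sample_id": sample_id, "dilution_fold": fold,
        })

    first_plate = "plate1"
    for _ in range(cfg.n_conditioning_sqc):
        emit("SQC", first_plate, fold=1)
    for p, samples in enumerate(sample_ids_by_plate):
        plate_id = f"plate{p + 1}"
        order = list(rng.permutation(samples))
        for i in range(0, len(order), cfg.block_size):
            emit("RQC", plate_id)
            for sid in order[i:i + cfg.block_size]:
                emit("study", plate_id, sample_id=sid)
            emit("SQC", plate_id, fold=1)
    last_plate = f"plate{len(sample_ids_by_plate)}"
    emit("RQC", last_plate)
    for fold in (16, 8, 4, 2):
        for _ in range(3):
            emit("dQC", last_plate, fold=fold)
    for _ in range(3):
        emit("SQC", last_plate, fold=1)
    man = pd.DataFrame(records).set_index("injection_id")
    man["dilution_fold"] = man["dilution_fold"].astype("Int64")
    return man


def _segment_coordinates(manifest: pd.DataFrame) -> list[tuple[int, int, np.ndarray]]:
    """(left RQC positional index, right RQC positional index, n-coordinate
    per inner injection) for each consecutive RQC pair, using the study-rank
    convention shared with the normalizer."""
    roles = manifest["role"].to_numpy()
    rqc_pos = np.flatnonzero(roles == "RQC")
    out = []
    for a, b in zip(rqc_pos[:-1], rqc_pos[1:]):
        inner = np.arange(a + 1, b)
        n = np.cumsum(roles[inner] == "study").astype(float)
        out.append((int(a), int(b), n))
    return out


def _sensitivity(cfg: SimulationConfig, manifest: pd.DataFrame,
                 n_features: int, rng: np.random.Generator) -> np.ndarray:
    """Per-(feature, injection) sensitivity, piecewise linear between RQC nodes."""
    roles = manifest["role"].to_numpy()
    plates = manifest["plate_id"].to_numpy()
    rqc_pos = np.flatnonzero(roles == "RQC")
    g = np.ones((n_features, len(manifest)))
    if len(rqc_pos) == 0:
        return g
    nodes = np.ones((n_features, len(rqc_pos)))
    for k in range(1, len(rqc_pos)):
        step = 1.0 + rng.uniform(-cfg.drift_amplitude, cfg.drift_amplitude, n_features)
        if plates[rqc_pos[k]] != plates[rqc_pos[k - 1]]:
            step = step * (1.0 + rng.uniform(-cfg.plate_jump, cfg.plate_jump, n_features))
        nodes[:, k] = nodes[:, k - 1] * step

    g[:, : rqc_pos[0] + 1] = nodes[:, [0]]
    g[:, rqc_pos[-1]:] = nodes[:, [-1]]
    for k, (a, b, n) in enumerate(_segment_coordinates(manifest)):
        inner = np.arange(a + 1, b)
        if inner.size == 0:
            continue
        S = int((roles[inner] == "study").sum())
        gl, gr = nodes[:, [k]], nodes[:, [k + 1]]
        g[:, inner] = gl + np.outer(gr[:, 0] - gl[:, 0], n) / (S + 1)
        g[:, b] = nodes[:, k + 1]
    return g


def _assemble_run(cfg: SimulationConfig, features: pd.DataFrame,
                  truth: pd.DataFrame, sample_ids_by_plate: list[list[str]],
                  rng: np.random.Generator) -> tuple[FeatureTable, pd.DataFrame]:
    """Build the intensity table for a run from per-sample truths."""
    manifest = make_run_order(cfg, sample_ids_by_plate, rng)
    n_feat = len(features)
    g = _sensitivity(cfg, manifest, n_feat, rng)

    sqc_truth = truth.to_numpy().mean(axis=1)
    rqc_truth = sqc_truth  # reference plasma mixed from pooled QC material
    col_truth = np.empty((n_feat, len(manifest)))
    for j, (inj, row) in enumerate(manifest.iterrows()):
        if row["role"] == "study":
            col_truth[:, j] = truth[row["sample_id"]].to_numpy()
        elif row["role"] == "SQC":
            col_truth[:, j] = sqc_truth
        elif row["role"] == "dQC":
            col_truth[:, j] = sqc_truth / float(row["dilution_fold"])
        elif row["role"] == "RQC":
            col_truth[:, j] = rqc_truth
        else:  # blank
            col_truth[:, j] = 0.0

    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv ** 2)) if cfg.noise_cv > 0 else 0.0
    noise = np.exp(rng.normal(0.0, sigma, col_truth.shape)) if sigma else 1.0
    X = col_truth * g * noise

    # degraded RQC injections: most features become undetectable
    rqc_ids = manifest.index[manifest["role"] == "RQC"].tolist()
    fail = set(int(i) for i in cfg.forced_failed_rqcs)
    for ordinal, inj in enumerate(rqc_ids):
        u = rng.uniform()
        if ordinal in fail or u < cfg.rqc_failure_prob:
            mask = rng.uniform(size=n_feat) < cfg.rqc_degraded_fraction
            j = manifest.index.get_loc(inj)
            X[mask, j] = np.nan

    feat_out = features.drop(columns=[c for c in features.columns if c.startswith("_")])
    Xdf = pd.DataFrame(X, index=features.index, columns=manifest.index)
    table = FeatureTable(feat_out, manifest, Xdf)
    g_df = pd.DataFrame(g, index=features.index, columns=manifest.index)
    return table, g_df


def _random_features(cfg: SimulationConfig, rng: np.random.Generator,
                     prefix: str = "F") -> tuple[pd.DataFrame, np.ndarray]:
    ids = [f"{prefix}{i + 1:04d}" for i in range(cfg.n_features)]
    mz_cap = 950.0 if cfg.assay_mode.startswith("C18") else 700.0
    features = pd.DataFrame({
        "mz": rng.uniform(60.0, mz_cap - 10.0, cfg.n_features),
        "rt": rng.uniform(0.5, 12.0, cfg.n_features),
        "assay_mode": cfg.assay_mode,
        "annotation": pd.Series([None] * cfg.n_features, dtype=object),
    }, index=pd.Index(ids, name="feature_id"))
    baselines = 10 ** rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd, cfg.n_features)
    return features, baselines


def simulate_intensities(cfg: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Simulate a (multi-)plate run of study samples with drift and noise.

    Study-sample truths are lognormal around per-feature baselines.  With
    ``n_donors`` set, samples are replicate aliquots: truth is shared within
    a donor; with ``replicate_across_plates`` the same sample set is injected
    once per plate (the three-plate repeatability design).
    """
    rng = np.random.default_rng(cfg.seed)
    features, baselines = _random_features(cfg, rng)
    sigma_d = math.sqrt(math.log(1.0 + cfg.donor_cv ** 2)) if cfg.donor_cv > 0 else 0.0

    if cfg.n_donors:
        reps = cfg.n_study_per_plate // cfg.n_donors
        if reps * cfg.n_donors != cfg.n_study_per_plate:
            raise ValueError("n_study_per_plate must be a multiple of n_donors")
        donor_truth = baselines[:, None] * np.exp(rng.normal(0, sigma_d, (cfg.n_features, cfg.n_donors)))
        meta, cols = [], {}
        if cfg.replicate_across_plates:
            for d in range(cfg.n_donors):
                for r in range(reps):
                    sid = f"D{d + 1}R{r + 1}"
                    cols[sid] = donor_truth[:, d]
                    meta.append({"sample_id": sid, "donor": d + 1, "replicate": r + 1})
            sample_ids = list(cols)
            sample_ids_by_plate = [sample_ids for _ in range(cfg.n_plates)]
        else:
            sample_ids_by_plate = []
            for p in range(cfg.n_plates):
                plate_sids = []
                for s in range(cfg.n_study_per_plate):
                    d = s % cfg.n_donors
                    sid = f"P{p + 1}D{d + 1}R{s // cfg.n_donors + 1}"
                    cols[sid] = donor_truth[:, d]
                    meta.append({"sample_id": sid, "donor": d + 1, "plate": p + 1})
                    plate_sids.append(sid)
                sample_ids_by_plate.append(plate_sids)
        truth = pd.DataFrame(cols, index=features.index)
        sample_meta = pd.DataFrame(meta).set_index("sample_id")
    else:
        cols, meta = {}, []
        sample_ids_by_plate = []
        for p in range(cfg.n_plates):
            plate_sids = []
            for s in range(cfg.n_study_per_plate):
                sid = f"P{p + 1}S{s + 1:02d}"
                cols[sid] = baselines * np.exp(rng.normal(0, sigma_d, cfg.n_features))
                meta.append({"sample_id": sid, "plate": p + 1})
                plate_sids.append(sid)
            sample_ids_by_plate.append(plate_sids)
        truth = pd.DataFrame(cols, index=features.index)
        sample_meta = pd.DataFrame(meta).set_index("sample_id")

    # replicate injections on several plates need distinct injection ids but
    # identical sample ids — handled by make_run_order emitting unique ids
    table, g_df = _assemble_run(cfg, features, truth, sample_ids_by_plate, rng)
    gt = GroundTruth(true_abundance=truth, sensitivity=g_df, sample_meta=sample_meta)
    return table, gt


_TRUTH_FLOOR_FRAC = 1e-3  # printed trendlines may cross zero inside the window


def _marker_truth(marker: QualityMarker, hours: float, temp: float,
                  baseline: float) -> float:
    """Marker truth for one storage condition; 4 °C and the 0-h control stay
    at the 1-h baseline, 25 °C follows the trendline."""
    if hours <= 0 or temp != 25:
        v = baseline
    else:
        v = float(evaluate_trendline(marker.fit, hours))
    return max(v, _TRUTH_FLOOR_FRAC * baseline)


def simulate_storage_series(cfg: SimulationConfig, markers: list[QualityMarker],
                            n_null_features: int = 0) -> tuple[FeatureTable, GroundTruth]:
    """Simulate the EDTA-blood storage experiment as a full analytical run.

    Each donor contributes a 0-h control plus every (time, temperature)
    condition; marker features follow their 25 °C trendline (multiplicative
    donor effect and noise) and stay at the 1-h baseline at 4 °C, while null
    features are time-independent.  The resulting samples are embedded in the
    standard QC run order with drift, so the full normalize → filter → score
    → select pipeline can be exercised end to end.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, baselines = [], []
    for i, m in enumerate(markers):
        cap = 950.0 if m.assay_mode.startswith("C18") else 700.0
        rows.append({"feature_id": f"mk{i + 1:02d}", "mz": rng.uniform(60.0, cap - 10.0),
                     "rt": rng.uniform(0.5, 12.0), "assay_mode": m.assay_mode,
                     "annotation": m.name})
        baselines.append(float(evaluate_trendline(m.fit, 1.0)))
    modes = ("C18pos", "C18neg", "HILICpos", "HILICneg")
    for i in range(n_null_features):
        mode = modes[i % 4]
        cap = 950.0 if mode.startswith("C18") else 700.0
        rows.append({"feature_id": f"null{i + 1:03d}", "mz": rng.uniform(60.0, cap - 10.0),
                     "rt": rng.uniform(0.5, 12.0), "assay_mode": mode, "annotation": None})
        baselines.append(float(10 ** rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd)))
    features = pd.DataFrame(rows).set_index("feature_id")
    baselines = np.asarray(baselines)
    n_feat = len(features)
    n_markers = len(markers)

    conditions = [(0.0, None)] + [(h, t) for h in cfg.storage_times for t in cfg.storage_temps]
    sigma_d = math.sqrt(math.log(1.0 + cfg.donor_cv ** 2)) if cfg.donor_cv > 0 else 0.0
    donor_eff = np.exp(rng.normal(0, sigma_d, (n_feat, cfg.n_storage_donors)))

    cols, meta = {}, []
    for d in range(cfg.n_storage_donors):
        for hours, temp in conditions:
            sid = f"D{d + 1}H{hours:g}T{temp if temp is not None else 'ctrl'}"
            vals = np.empty(n_feat)
            for i, m in enumerate(markers):
                vals[i] = _marker_truth(m, hours, temp if temp is not None else 4, baselines[i])
            vals[n_markers:] = baselines[n_markers:]
            cols[sid] = vals * donor_eff[:, d]
            meta.append({"sample_id": sid, "donor": d + 1, "storage_hours": hours,
                         "storage_temp": temp if temp is not None else "control"})
    truth = pd.DataFrame(cols, index=features.index)
    sample_meta = pd.DataFrame(meta).set_index("sample_id")

    sample_ids = list(truth.columns)
    per_plate = min(MAX_STUDY_PER_PLATE, cfg.n_study_per_plate)
    sample_ids_by_plate = [sample_ids[i:i + per_plate]
                           for i in range(0, len(sample_ids), per_plate)]
    run_cfg = cfg
    table, g_df = _assemble_run(run_cfg, features, truth, sample_ids_by_plate, rng)
    for col in ("donor", "storage_hours", "storage_temp"):
        table.manifest[col] = table.manifest["sample_id"].map(sample_meta[col])
    gt = GroundTruth(true_abundance=truth, sensitivity=g_df, sample_meta=sample_meta,
                     true_marker_ids=list(features.index[:n_markers]),
                     true_discriminative_ids=list(features.index[:n_markers]))
    return table, gt
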