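"""End-to-end pipeline orchestration: simulate → normalize → filter → score →
select, with a JSON run manifest for reproducibility."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .discovery import impute_half_minimum, opls_da, rank_candidates, s_plot, select_by_pcorr
from .filters import FilterConfig, apply_all_filters
from .normalize import normalize_table
from .scoring import ScoreConfig, load_marker_table, score_table
from .simulate import SimulationConfig, simulate_storage_series
from .table import FeatureTable, read_feature_table, write_feature_table

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run; all randomness flows from `seed`."""

    out_dir: str = "metaboqc_run"
    seed: int = 0
    normalization_mode: str = "anchored"
    rqc_threshold: float = 0.5          # fraction of the feature count
    filter: FilterConfig = field(default_factory=FilterConfig)
    score_mode: str = "direction_aware"
    score_threshold: float = 85.0
    pcorr_threshold: float = 0.7
    n_orthogonal: int = 1
    top_n: int = 40
    marker_variant: str = "printed"
    n_null_features: int = 100
    noise_cv: float = 0.05
    drift_amplitude: float = 0.30


def run_pipeline(cfg: PipelineConfig,
                 table: FeatureTable | None = None) -> dict:
    """Run the whole protocol and write its artifact set to ``cfg.out_dir``.

    Without an input table a storage-series run is simulated first.  Returns a
    dict of artifact paths plus summary numbers.  Stage failures raise with
    the stage name; artifacts written before the failure are kept.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    markers = load_marker_table(variant=cfg.marker_variant)
    stage = "synthetic_data"
    try:
        if table is None:
            sim_cfg = SimulationConfig(seed=cfg.seed, noise_cv=cfg.noise_cv,
                                       drift_amplitude=cfg.drift_amplitude)
            table, gt = simulate_storage_series(sim_cfg, markers,
                                                n_null_features=cfg.n_null_features)
            write_feature_table(table, out / "simulated.csv", out / "manifest.csv")

        stage = "drift_normalization"
        normalized, report = normalize_table(table, cfg.rqc_threshold, cfg.normalization_mode)
        write_feature_table(normalized, out / "normalized.csv", out / "manifest.csv")
        (out / "normalization_report.json").write_text(json.dumps(report.to_dict(), indent=2))

        stage = "qc_filtering"
        filtered, freport = apply_all_filters(normalized, cfg.filter)
        write_feature_table(filtered, out / "filtered.csv", out / "manifest.csv")
        (out / "filter_report.json").write_text(json.dumps(freport.to_dict(), indent=2))

        stage = "quality_scoring"
        scores = score_table(filtered, markers,
                             ScoreConfig(mode=cfg.score_mode, threshold=cfg.score_threshold))
        scores.to_csv(out / "scores.csv")

        stage = "marker_discovery"
        man = filtered.manifest
        study = man[man["role"] == "study"]
        if "storage_hours" in study.columns and "storage_temp" in study.columns:
            ctrl = study.index[study["storage_temp"].astype(str) == "control"]
            stored = study.index[(study["storage_temp"].astype(str) == "25")
                                 & (study["storage_hours"].astype(float) >= 24)]
        else:  # no storage design: contrast first half vs second half of run
            half = len(study) // 2
            ctrl, stored = study.index[:half], study.index[half:]
        sel = list(ctrl) + list(stored)
        X = impute_half_minimum(filtered.X[sel]).T
        labels = [0] * len(ctrl) + [1] * len(stored)
        model = opls_da(X, labels, n_orthogonal=cfg.n_orthogonal)
        points = s_plot(model)
        selected = select_by_pcorr(points, cfg.pcorr_threshold)
        cands = rank_candidates(X, labels, top_n=cfg.top_n,
                                pcorr=points["pcorr1"])
        cand_df = pd.DataFrame([{
            "feature_id": c.feature_id, "p_value": c.p_value,
            "fold_change": c.fold_change, "direction": c.direction,
            "pcorr1": c.pcorr1, "pcorr_selected": c.feature_id in set(selected),
        } for c in cands])
        cand_df.to_csv(out / "candidates.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_manifest = {
        "metaboqc_version": __version__,
        "seed": cfg.seed,
        "parameters": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                       for k, v in asdict(cfg).items()},
        "artifacts": ["normalized.csv", "filter_report.json", "scores.csv", "candidates.csv"],
        "n_features_retained": int(freport.n_retained),
        "n_candidates": len(cand_df),
        "n_pcorr_selected": len(selected),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return run_manifest
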