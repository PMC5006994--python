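"""Plasma quality scoring from storage-time quality markers.

Forty metabolites whose plasma abundance changes reproducibly during
whole-blood storage at 25 °C serve as quality markers: 10 HILIC-positive,
15 HILIC-negative, 10 C18-positive and 5 C18-negative compounds, 30 of which
increase (lysophospholipids, dipeptides, fatty acids, succinic acid, amino
acids) and 10 of which decrease (glucose, uric acid, others).  Each marker k
contributes

    P_k = (100 / 40) * (NLA_k(48 h) − NLA_k(sample)) / NLA_k(48 h)

where NLA_k(48 h) is the marker's reference abundance after 48 h at 25 °C.
The quality score is the sum of P_k over the four assay groups; a sample with
a score below 85 points is triaged as low quality.

Two modes: ``literal`` applies the formula as printed for every marker;
``direction_aware`` flips the sign for decreasing markers so that fresh
samples (abundance above the degraded 48-h reference on a decreasing marker)
are rewarded rather than penalized.  P_k is clamped to ±2.5 (one marker's
full share of the 100-point scale) so a single extreme marker cannot
dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .trendlines import TrendlineFit, evaluate_trendline

log = logging.getLogger(__name__)

GROUP_KEYS = {"C18pos": "CP", "C18neg": "CN", "HILICpos": "HP", "HILICneg": "HN"}
DESIGN_HOURS = (3.0, 6.0, 12.0, 24.0, 48.0)
REFERENCE_HOURS = 48.0


@dataclass
class QualityMarker:
    """One quality-marker row: compound, assay mode, direction of change
    during 25 °C storage, fitted trendline, and 48-h reference abundance."""

    name: str
    assay_mode: str
    direction: str          # "increasing" | "decreasing"
    fit: TrendlineFit       # functional form actually used for arithmetic
    printed_kind: str       # trendline label as printed in the source table
    nla_48h: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"direction must be increasing/decreasing, got {self.direction!r}")
        if pd.isna(self.nla_48h):
            self.nla_48h = reference_nla(self.fit)
        if not self.nla_48h > 0:
            raise ValueError(f"{self.name}: nla_48h must be positive")

    @property
    def key(self) -> tuple[str, str]:
        return (self.assay_mode, self.name)


def reference_nla(fit: TrendlineFit, hours: float = REFERENCE_HOURS) -> float:
    """Reference abundance at the given storage time.

    Defaults to the trendline value at 48 h.  If that value is not positive
    (a printed linear fit can cross zero inside the design window), falls
    back to the smallest positive trendline value over the design times — a
    measured mean may always be supplied instead.
    """
    v = float(evaluate_trendline(fit, hours))
    if v > 0:
        return v
    candidates = [float(evaluate_trendline(fit, h)) for h in DESIGN_HOURS]
    positive = [c for c in candidates if c > 0]
    if not positive:
        raise ValueError("trendline is nonpositive at every design time")
    return min(positive)


def load_marker_table(path=None, variant: str = "printed") -> list[QualityMarker]:
    """Load quality markers from a CSV (packaged table by default).

    The packaged table transcribes the published 40-marker list, which pairs
    two rows (Uric acid, Ribonic acid) with equations whose functional form
    contradicts the printed trendline label.  ``variant="printed"`` keeps the
    coefficients with the row as printed (arithmetic follows the equation's
    actual form); ``variant="swap_corrected"`` swaps the two coefficient sets
    so label and form agree.
    """
    if variant not in ("printed", "swap_corrected"):
        raise ValueError(f"variant must be 'printed' or 'swap_corrected', got {variant!r}")
    if path is None:
        src = resources.files("metaboqc.data").joinpath("quality_markers.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"name", "assay_mode", "direction", "kind", "a", "b", "r2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing column(s): {sorted(missing)}")
    if "form" not in df.columns:
        df["form"] = df["kind"]

    if variant == "swap_corrected":
        df = df.copy()
        mismatched = df.index[df["kind"] != df["form"]].tolist()
        if len(mismatched) == 2:
            i, j = mismatched
            cols = ["a", "b", "r2"]
            df.loc[i, cols], df.loc[j, cols] = df.loc[j, cols].tolist(), df.loc[i, cols].tolist()
            df.loc[mismatched, "form"] = df.loc[mismatched, "kind"]

    markers = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            fit = TrendlineFit(kind=row.form, a=float(row.a), b=float(row.b), r2=float(row.r2))
            markers.append(QualityMarker(row.name, row.assay_mode, row.direction,
                                         fit, printed_kind=row.kind))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"marker table row {row_no}: {exc}") from exc
    names = [(m.assay_mode, m.name) for m in markers]
    if len(set(names)) != len(names):
        raise ValueError("marker names must be unique within each assay mode")
    return markers


@dataclass
class ScoreConfig:
    mode: str = "literal"          # "literal" | "direction_aware"
    threshold: float = 85.0        # pass iff total >= threshold
    clamp: float = 2.5             # per-marker point bound
    rescale_missing: bool = True   # scale 100/40 -> 100/n when markers are missing

    def __post_init__(self) -> None:
        if self.mode not in ("literal", "direction_aware"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")


def compute_pk(marker: QualityMarker, nla_sample: float,
               direction_aware: bool = False, clamp: float = 2.5,
               point_scale: float = 100.0 / 40.0) -> float:
    """Points contributed by one marker.

    Literal: point_scale · (NLA_48h − NLA_sample) / NLA_48h.  Direction-aware
    flips the sign for decreasing markers.  The result is clamped to
    ±``clamp``.
    """
    if nla_sample < 0:
        raise ValueError("sample NLA must be >= 0")
    pk = point_scale * (marker.nla_48h - nla_sample) / marker.nla_48h
    if direction_aware and marker.direction == "decreasing":
        pk = -pk
    return float(min(max(pk, -clamp), clamp))


@dataclass
class QualityScoreResult:
    per_marker_points: dict[tuple[str, str], float]
    subtotals: dict[str, float]     # per assay group: CP, CN, HP, HN
    total: float
    n_markers_used: int
    passed: bool
    threshold: float

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "subtotals": dict(self.subtotals),
            "n_markers_used": self.n_markers_used,
            "passed": self.passed,
            "threshold": self.threshold,
            "per_marker_points": {f"{m}/{n}": p for (m, n), p in self.per_marker_points.items()},
        }


def compute_quality_score(sample_nlas: Mapping[tuple[str, str], float],
                          markers: list[QualityMarker],
                          cfg: ScoreConfig | None = None) -> QualityScoreResult:
    """Quality score of one sample from its per-marker normalized abundances.

    ``sample_nlas`` maps (assay_mode, marker name) → abundance.  Markers with
    no measured abundance are dropped; when fewer than the full marker set
    match and ``rescale_missing`` is set, the per-marker factor 100/40 is
    rescaled to 100/n_matched (reported in ``n_markers_used``).
    """
    cfg = cfg or ScoreConfig()
    matched = [m for m in markers if m.key in sample_nlas and not pd.isna(sample_nlas[m.key])]
    if not matched:
        raise ValueError("no quality marker matched the supplied abundances")
    n = len(matched)
    scale = 100.0 / n if (cfg.rescale_missing and n < len(markers)) else 100.0 / len(markers)
    direction_aware = cfg.mode == "direction_aware"
    per_marker: dict[tuple[str, str], float] = {}
    subtotals = {g: 0.0 for g in GROUP_KEYS.values()}
    clamp = cfg.clamp * scale / (100.0 / len(markers))  # keep clamp at one marker share
    for m in matched:
        pk = compute_pk(m, float(sample_nlas[m.key]), direction_aware,
                        clamp=clamp, point_scale=scale)
        per_marker[m.key] = pk
        subtotals[GROUP_KEYS[m.assay_mode]] += pk
    total = float(sum(subtotals.values()))
    return QualityScoreResult(per_marker, subtotals, total, n,
                              passed=total >= cfg.threshold, threshold=cfg.threshold)


def marker_nlas_from_table(table, markers: list[QualityMarker],
                           injection_id: str) -> dict[tuple[str, str], float]:
    """Extract one injection's marker abundances from an annotated feature
    table (features matched by annotation + assay mode)."""
    f = table.features
    if "annotation" not in f.columns:
        return {}
    out: dict[tuple[str, str], float] = {}
    by_key = {(row.assay_mode, row.annotation): fid
              for fid, row in f.iterrows() if pd.notna(row.annotation)}
    for m in markers:
        fid = by_key.get(m.key)
        if fid is not None:
            out[m.key] = float(table.X.loc[fid, injection_id])
    return out


def score_table(table, markers: list[QualityMarker],
                cfg: ScoreConfig | None = None) -> pd.DataFrame:
    """Score every study injection of an annotated table.

    Returns a DataFrame indexed by injection_id with the total score, the
    four assay-group subtotals, marker count and pass flag.
    """
    cfg = cfg or ScoreConfig()
    rows = []
    for inj in table.injections("study").index:
        nlas = marker_nlas_from_table(table, markers, inj)
        res = compute_quality_score(nlas, markers, cfg)
        rows.append({"injection_id": inj, "score": res.total, **res.subtotals,
                     "n_markers_used": res.n_markers_used, "passed": res.passed})
    return pd.DataFrame(rows).set_index("injection_id")
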