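"""RQC-based sensitivity-drift normalization of feature intensities.

A reference QC plasma (RQC) is injected around every block of eight study
samples.  Assuming instrument sensitivity for each feature drifts linearly
between two neighbouring reliable RQC injections, a study intensity x_n at
segment position n is corrected to

    y = x_n * M1 / ( M1 + n * (M2 - M1) / (S + 1) )

where M1 and M2 are the feature's intensities in the left and right RQC and S
is the number of study injections in the segment (the canonical design has
S = 8, giving the divisor 9).  RQC injections with too many undetectable
features are deemed unreliable and skipped, so their study injections fall
into the enclosing longer segment.

Segment position convention: n counts study injections (1-based) within the
segment; a QC injection lying between two RQCs inherits the rank of the
preceding study injection.  The flanking RQCs sit at n = 0 and n = S + 1.

Two output modes:

``literal``
    Each segment is anchored to its own left RQC — the printed equation as-is.
``anchored`` (default)
    Segment outputs are additionally rescaled per feature by
    M1_first / M1_segment so that intensities are comparable across segments
    and plates (every reliable RQC maps onto the first one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .table import FeatureTable

log = logging.getLogger(__name__)

DEFAULT_RQC_THRESHOLD = 1000


@dataclass
class RQCSegment:
    """Two flanking reliable RQC injections and everything strictly between."""

    left_rqc: str
    right_rqc: str
    injections: list[str]          # all injections strictly between the flanks
    study_injections: list[str]    # the study subset, in run order
    positions: dict[str, int]      # segment coordinate n per inner injection

    @property
    def S(self) -> int:
        return len(self.study_injections)


@dataclass
class NormalizationReport:
    mode: str
    unreliable_rqcs: list[str] = field(default_factory=list)
    uncovered_injections: list[str] = field(default_factory=list)
    fallback_features: int = 0
    n_segments: int = 0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "unreliable_rqcs": list(self.unreliable_rqcs),
            "uncovered_injections": list(self.uncovered_injections),
            "fallback_features": int(self.fallback_features),
            "n_segments": int(self.n_segments),
        }


def count_undetectable(table: FeatureTable, injection_id: str) -> int:
    """Number of features missing *or zero* in an injection.

    A zero intensity is counted as undetected for reliability purposes (it
    carries no quantitative signal) even though it is kept as 0 in arithmetic.
    """
    if injection_id not in table.manifest.index:
        raise KeyError(f"unknown injection {injection_id!r}")
    col = table.X[injection_id]
    return int((col.isna() | (col == 0)).sum())


def _resolve_threshold(threshold: float | int, n_features: int) -> int:
    """A threshold < 1 is a fraction of the feature count (small-table use)."""
    if 0 < threshold < 1:
        return max(1, int(round(threshold * n_features)))
    return int(threshold)


def is_reliable_rqc(table: FeatureTable, injection_id: str,
                    threshold: float | int = DEFAULT_RQC_THRESHOLD) -> bool:
    """True iff the RQC injection has fewer undetectable features than the threshold."""
    role = table.manifest.loc[injection_id, "role"]
    if role != "RQC":
        raise ValueError(f"injection {injection_id!r} has role {role!r}, not RQC")
    thr = _resolve_threshold(threshold, table.n_features)
    return count_undetectable(table, injection_id) < thr


def _segment_between(manifest: pd.DataFrame, left: str, right: str) -> RQCSegment:
    li = manifest.loc[left, "run_index"]
    ri = manifest.loc[right, "run_index"]
    inner = manifest[(manifest["run_index"] > li) & (manifest["run_index"] < ri)]
    study = inner[inner["role"] == "study"].index.tolist()
    positions: dict[str, int] = {}
    rank = 0
    for inj_id, row in inner.iterrows():
        if row["role"] == "study":
            rank += 1
        positions[inj_id] = rank
    return RQCSegment(left, right, inner.index.tolist(), study, positions)


def segment_run(table: FeatureTable,
                threshold: float | int = DEFAULT_RQC_THRESHOLD) -> list[RQCSegment]:
    """Pair consecutive reliable RQC injections into normalization segments.

    Unreliable RQCs are skipped, so the study injections they would have
    bounded fall into the enclosing longer segment.  Raises if fewer than two
    reliable RQCs exist (nothing can be corrected; pass data through raw).
    """
    rqcs = table.injections("RQC").index.tolist()
    reliable = [r for r in rqcs if is_reliable_rqc(table, r, threshold)]
    if len(reliable) < 2:
        raise ValueError(
            "fewer than 2 reliable RQC injections; drift correction is not "
            "possible — pass intensities through raw"
        )
    return [
        _segment_between(table.manifest, a, b)
        for a, b in zip(reliable[:-1], reliable[1:])
    ]


def interpolate_sensitivity(M1: float, M2: float, n: int, S: int) -> float:
    """Linearly interpolated sensitivity at segment position n.

    Returns M1 + n * (M2 - M1) / (S + 1); with the canonical S = 8 the
    divisor is 9.  Endpoints: n = 0 → M1, n = S + 1 → M2.
    """
    if not (0 <= n <= S + 1):
        raise ValueError(f"position n={n} outside [0, {S + 1}]")
    if not (M1 > 0 and M2 > 0):
        raise ValueError("flanking RQC intensities must be positive")
    return M1 + n * (M2 - M1) / (S + 1)


def _rqc_flank_matrix(table: FeatureTable, reliable: list[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Effective per-feature flank intensities with nearest-reliable fallback.

    Returns (left_eff, right_eff) arrays of shape (n_features, n_reliable):
    column j of left_eff is the value used when reliable RQC j is a left
    flank — the feature's own value there, else the nearest reliable RQC
    where it is quantified (search leftward first, then rightward); right_eff
    symmetric.  Also returns the count of (RQC, feature) cells that needed a
    substitute (NaN where no RQC quantifies the feature at all).
    """
    R = table.X[reliable].to_numpy(dtype=float)
    R = np.where(R > 0, R, np.nan)  # unquantified: missing, zero or negative
    n_feat, n_rqc = R.shape

    def ffill(a: np.ndarray) -> np.ndarray:
        idx = np.where(~np.isnan(a), np.arange(n_rqc)[None, :], -1)
        idx = np.maximum.accumulate(idx, axis=1)
        out = np.where(idx >= 0, a[np.arange(n_feat)[:, None], np.maximum(idx, 0)], np.nan)
        return out

    fwd = ffill(R)                      # nearest valid at-or-before
    bwd = ffill(R[:, ::-1])[:, ::-1]    # nearest valid at-or-after
    left_eff = np.where(~np.isnan(fwd), fwd, bwd)
    right_eff = np.where(~np.isnan(bwd), bwd, fwd)
    n_fallback = int(np.isnan(R).sum() - np.isnan(left_eff).sum())
    return left_eff, right_eff, n_fallback


def normalize_table(table: FeatureTable,
                    threshold: float | int = DEFAULT_RQC_THRESHOLD,
                    mode: str = "anchored") -> tuple[FeatureTable, NormalizationReport]:
    """Drift-correct every covered injection of a run.

    Study and QC injections between two reliable RQCs are divided by the
    interpolated per-feature sensitivity (times M1, per the correction
    equation); the flanking RQCs themselves are corrected at their endpoint
    positions.  Injections before the first or after the last reliable RQC
    pass through unchanged and are flagged in the report.  Features that are
    unquantified in a flanking RQC fall back to the nearest reliable RQC that
    does quantify them; failing that they stay raw and are counted.
    """
    if mode not in ("literal", "anchored"):
        raise ValueError(f"mode must be 'literal' or 'anchored', got {mode!r}")
    rqcs = table.injections("RQC").index.tolist()
    reliable = [r for r in rqcs if is_reliable_rqc(table, r, threshold)]
    segments = segment_run(table, threshold)
    unreliable = [r for r in rqcs if r not in reliable]

    Xout = table.X.copy()
    vals = Xout.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(Xout.columns)}

    left_eff, right_eff, _ = _rqc_flank_matrix(table, reliable)
    rqc_ord = {r: j for j, r in enumerate(reliable)}
    # anchor: each feature's value at the first reliable RQC quantifying it
    M_first = left_eff[:, 0]

    fallback_pairs = 0
    raw_R = table.X[reliable].to_numpy(dtype=float)

    for k, seg in enumerate(segments):
        M1 = left_eff[:, rqc_ord[seg.left_rqc]]
        M2 = right_eff[:, rqc_ord[seg.right_rqc]]
        own1 = raw_R[:, rqc_ord[seg.left_rqc]]
        own2 = raw_R[:, rqc_ord[seg.right_rqc]]
        substituted = (~(own1 > 0) | ~(own2 > 0))
        usable = ~np.isnan(M1) & ~np.isnan(M2) & (M1 > 0) & (M2 > 0)
        fallback_pairs += int((substituted & usable).sum()) + int((~usable).sum())

        # columns to correct: inner injections at their coordinate, the left
        # flank at n=0, and (for the final segment) the right flank at n=S+1
        cols = [(seg.left_rqc, 0)] + [(i, seg.positions[i]) for i in seg.injections]
        if k == len(segments) - 1:
            cols.append((seg.right_rqc, seg.S + 1))
        n_vec = np.array([n for _, n in cols], dtype=float)
        denom = M1[:, None] + np.outer(M2 - M1, n_vec) / (seg.S + 1)
        factor = np.where(usable[:, None] & (denom > 0), M1[:, None] / denom, 1.0)
        if mode == "anchored":
            anchor = np.where(usable & (M_first > 0), M_first / M1, 1.0)
            factor = factor * anchor[:, None]
        idx = [col_pos[c] for c, _ in cols]
        vals[:, idx] = vals[:, idx] * factor

    first_ri = table.manifest.loc[reliable[0], "run_index"]
    last_ri = table.manifest.loc[reliable[-1], "run_index"]
    covered = (table.manifest["run_index"] >= first_ri) & (table.manifest["run_index"] <= last_ri)
    uncovered = table.manifest.index[~covered].tolist()

    Xout = pd.DataFrame(vals, index=Xout.index, columns=Xout.columns)
    out = FeatureTable(table.features.copy(), table.manifest.copy(), Xout,
                       validate_on_init=False)
    report = NormalizationReport(
        mode=mode,
        unreliable_rqcs=unreliable,
        uncovered_injections=uncovered,
        fallback_features=fallback_pairs,
        n_segments=len(segments),
    )
    if unreliable:
        log.info("skipped %d unreliable RQC injection(s): %s", len(unreliable), unreliable)
    return out, report


class RQCDriftNormalizer(BaseEstimator):
    """Transformer-style wrapper around :func:`normalize_table`.

    Parameters
    ----------
    mode : {"anchored", "literal"}
        Anchored rescales every segment to the first reliable RQC (intensities
        comparable across plates); literal applies the per-segment equation
        exactly as printed.
    rqc_threshold : int or float
        Undetectable-feature count above which an RQC is unreliable; a value
        in (0, 1) is a fraction of the feature count.
    """

    def __init__(self, mode: str = "anchored",
                 rqc_threshold: float | int = DEFAULT_RQC_THRESHOLD):
        self.mode = mode
        self.rqc_threshold = rqc_threshold

    def fit(self, table: FeatureTable, y=None):
        self.segments_ = segment_run(table, self.rqc_threshold)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        out, report = normalize_table(table, self.rqc_threshold, self.mode)
        self.report_ = report
        return out

    def fit_transform(self, table: FeatureTable, y=None) -> FeatureTable:
        return self.fit(table).transform(table)
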