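"""Feature selection from QC injections: SQC repeatability, dQC dilution
response, and m/z caps.

Three pure predicates over a feature table, each returning the set of failing
feature ids, composed by :func:`apply_all_filters` into an auditable report:

* ``sqc_cv`` — the coefficient of variation over intercalated SQC injections
  exceeds the threshold (default 30%, strictly greater).  The initial
  column-conditioning SQCs and any SQCs after the closing RQC are excluded.
* ``dqc_cv`` / ``dqc_monotonicity`` — within-triplet CV at any dilution fold
  exceeds the threshold, or the mean intensity is not strictly decreasing
  across folds 1 → 2 → 4 → 8 → 16 (dilution-proportional response check).
* ``mz_cap`` — m/z above 950 (C18 modes) or 700 (HILIC modes); such peaks are
  predominantly noise or column contaminants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .table import FeatureTable

log = logging.getLogger(__name__)

DQC_FOLDS = (2, 4, 8, 16)


@dataclass
class FilterConfig:
    """Thresholds for the three QC filters.

    cv_threshold / dqc_cv_threshold are fractions; a CV must be strictly
    greater to fail ("over 30%").  m/z caps are exclusive upper bounds in Da.
    monotonicity_rule: "strict_means" requires strictly decreasing fold means;
    "spearman" requires a perfect negative Spearman rank correlation between
    fold and mean (equivalent on five complete levels).
    """

    cv_threshold: float = 0.30
    dqc_cv_threshold: float = 0.30
    mz_cap_c18: float = 950.0
    mz_cap_hilic: float = 700.0
    monotonicity_rule: str = "strict_means"
    skip_initial_sqc: int = 10

    def __post_init__(self) -> None:
        for name in ("cv_threshold", "dqc_cv_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.mz_cap_c18 <= 0 or self.mz_cap_hilic <= 0:
            raise ValueError("m/z caps must be positive")
        if self.monotonicity_rule not in ("strict_means", "spearman"):
            raise ValueError(f"unknown monotonicity_rule {self.monotonicity_rule!r}")


@dataclass
class FilterReport:
    reasons: dict[str, list[str]]   # removed feature -> reason codes
    counts: dict[str, int]          # per-reason removal counts
    n_total: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return len(self.reasons)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "counts": dict(self.counts),
            "reasons": {k: list(v) for k, v in self.reasons.items()},
        }


def coefficient_of_variation(values) -> float:
    """Sample CV: standard deviation (n−1 denominator) over the mean.

    Returns NaN ("unevaluable") when fewer than two values are present or the
    mean is not positive.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def _eligible_sqcs(table: FeatureTable, cfg: FilterConfig) -> list[str]:
    """Intercalated SQCs: drop the conditioning run-in and any trailing SQCs
    that fall after the last RQC (the end-of-run dilution block)."""
    sqcs = table.injections("SQC")
    sqcs = sqcs.sort_values("run_index")
    eligible = sqcs.iloc[cfg.skip_initial_sqc:]
    rqcs = table.injections("RQC")
    if len(rqcs):
        last_rqc = rqcs["run_index"].max()
        eligible = eligible[eligible["run_index"] < last_rqc]
    return eligible.index.tolist()


def sqc_cv_filter(table: FeatureTable, cfg: FilterConfig | None = None) -> set[str]:
    """Features whose CV over eligible SQC injections exceeds the threshold
    (or cannot be evaluated)."""
    cfg = cfg or FilterConfig()
    cols = _eligible_sqcs(table, cfg)
    if len(cols) < 2:
        raise ValueError("fewer than 2 eligible SQC injections; cannot assess repeatability")
    sub = table.X[cols].to_numpy(dtype=float)
    n_present = (~np.isnan(sub)).sum(axis=1)
    mean = np.nanmean(np.where(np.isnan(sub), np.nan, sub), axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.array([np.nanstd(row[~np.isnan(row)], ddof=1) if (~np.isnan(row)).sum() >= 2 else np.nan
                       for row in sub])
        cv = np.where((n_present >= 2) & (mean > 0), sd / mean, np.nan)
    failing = np.isnan(cv) | (cv > cfg.cv_threshold)
    return set(table.features.index[failing])


def _fold_groups(table: FeatureTable) -> dict[int, list[str]]:
    """Injection columns per dilution fold.  Fold 1 is the trailing SQC
    triplet injected after the dilution series (falls back to all eligible
    intercalated SQCs when absent)."""
    man = table.manifest
    groups: dict[int, list[str]] = {}
    dqc = man[man["role"] == "dQC"]
    for fold in DQC_FOLDS:
        cols = dqc.index[dqc["dilution_fold"].astype("float") == fold].tolist()
        if cols:
            groups[fold] = cols
    sqcs = man[man["role"] == "SQC"].sort_values("run_index")
    if len(dqc):
        last_dqc = dqc["run_index"].max()
        trailing = sqcs[sqcs["run_index"] > last_dqc]
        if len(trailing) >= 2:
            groups[1] = trailing.index.tolist()
    if 1 not in groups and len(sqcs):
        groups[1] = sqcs.index.tolist()
    return groups


def dqc_response_filter(table: FeatureTable, cfg: FilterConfig | None = None) -> set[str]:
    """Features failing the dilution-series response check.

    A feature passes iff (a) the CV within each fold's replicate injections is
    at most ``dqc_cv_threshold`` (reason ``dqc_cv``) and (b) its mean intensity
    decreases strictly across folds 1 → 2 → 4 → 8 → 16 (reason
    ``dqc_monotonicity``).  A feature with an entirely absent fold level is
    unevaluable and removed with reason ``dqc_monotonicity``.
    Use :func:`dqc_response_reasons` for per-feature reason codes.
    """
    reasons = dqc_response_reasons(table, cfg)
    return set(reasons)


def dqc_response_reasons(table: FeatureTable, cfg: FilterConfig | None = None) -> dict[str, list[str]]:
    cfg = cfg or FilterConfig()
    groups = _fold_groups(table)
    folds = sorted(groups)
    required = [1, *DQC_FOLDS]
    if folds != required:
        missing = sorted(set(required) - set(folds))
        raise ValueError(f"dilution series incomplete; missing fold level(s): {missing}")

    X = table.X
    means: dict[int, np.ndarray] = {}
    cv_fail = np.zeros(len(X), dtype=bool)
    unevaluable = np.zeros(len(X), dtype=bool)
    for fold in required:
        sub = X[groups[fold]].to_numpy(dtype=float)
        n_present = (~np.isnan(sub)).sum(axis=1)
        sums = np.nansum(np.where(np.isnan(sub), 0.0, sub), axis=1)
        mean = np.where(n_present > 0, sums / np.maximum(n_present, 1), np.nan)
        means[fold] = mean
        unevaluable |= n_present == 0
        if sub.shape[1] >= 2:
            sd = np.array([np.nanstd(row[~np.isnan(row)], ddof=1) if (~np.isnan(row)).sum() >= 2 else np.nan
                           for row in sub])
            with np.errstate(invalid="ignore"):
                cv = np.where((n_present >= 2) & (mean > 0), sd / mean, np.nan)
            # a completely absent fold is a monotonicity (evaluability) failure,
            # not a repeatability one
            cv_fail |= np.where(n_present == 0, False, np.isnan(cv) | (cv > cfg.dqc_cv_threshold))

    M = np.column_stack([means[f] for f in required])
    if cfg.monotonicity_rule == "strict_means":
        mono_ok = np.all(np.diff(M, axis=1) < 0, axis=1)
    else:
        mono_ok = np.zeros(len(M), dtype=bool)
        for i, row in enumerate(M):
            if np.isnan(row).any():
                continue
            rho = stats.spearmanr(required, row).statistic
            mono_ok[i] = rho <= -1.0 + 1e-9
    mono_fail = unevaluable | np.isnan(M).any(axis=1) | ~mono_ok

    out: dict[str, list[str]] = {}
    for fid, cf, mf in zip(table.features.index, cv_fail, mono_fail):
        codes = []
        if cf:
            codes.append("dqc_cv")
        if mf:
            codes.append("dqc_monotonicity")
        if codes:
            out[fid] = codes
    return out


def mz_cap_filter(table: FeatureTable, cfg: FilterConfig | None = None) -> set[str]:
    """C18 features above the C18 cap and HILIC features above the HILIC cap
    (caps are exclusive: a feature exactly at the cap is retained)."""
    cfg = cfg or FilterConfig()
    f = table.features
    is_c18 = f["assay_mode"].str.startswith("C18")
    failing = (is_c18 & (f["mz"] > cfg.mz_cap_c18)) | (~is_c18 & (f["mz"] > cfg.mz_cap_hilic))
    return set(f.index[failing])


def apply_all_filters(table: FeatureTable,
                      cfg: FilterConfig | None = None) -> tuple[FeatureTable, FilterReport]:
    """Compose the three filters; the output table keeps exactly the features
    failing no rule, and the report accounts for every removal."""
    cfg = cfg or FilterConfig()
    if table.n_features == 0:
        return table.copy(), FilterReport({}, {}, 0, 0)
    sqc_fail = sqc_cv_filter(table, cfg)
    dqc_reasons = dqc_response_reasons(table, cfg)
    mz_fail = mz_cap_filter(table, cfg)

    reasons: dict[str, list[str]] = {}
    for fid in table.features.index:
        codes = []
        if fid in sqc_fail:
            codes.append("sqc_cv")
        codes.extend(dqc_reasons.get(fid, []))
        if fid in mz_fail:
            codes.append("mz_cap")
        if codes:
            reasons[fid] = codes
    counts: dict[str, int] = {}
    for codes in reasons.values():
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
    retained = [fid for fid in table.features.index if fid not in reasons]
    report = FilterReport(reasons, counts, table.n_features, len(retained))
    return table.subset_features(retained), report


class QCFeatureFilter(BaseEstimator):
    """Transformer-style wrapper around :func:`apply_all_filters`."""

    def __init__(self, cv_threshold: float = 0.30, dqc_cv_threshold: float = 0.30,
                 mz_cap_c18: float = 950.0, mz_cap_hilic: float = 700.0,
                 monotonicity_rule: str = "strict_means", skip_initial_sqc: int = 10):
        self.cv_threshold = cv_threshold
        self.dqc_cv_threshold = dqc_cv_threshold
        self.mz_cap_c18 = mz_cap_c18
        self.mz_cap_hilic = mz_cap_hilic
        self.monotonicity_rule = monotonicity_rule
        self.skip_initial_sqc = skip_initial_sqc

    def _config(self) -> FilterConfig:
        return FilterConfig(self.cv_threshold, self.dqc_cv_threshold,
                            self.mz_cap_c18, self.mz_cap_hilic,
                            self.monotonicity_rule, self.skip_initial_sqc)

    def fit(self, table: FeatureTable, y=None):
        _, self.report_ = apply_all_filters(table, self._config())
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        out, self.report_ = apply_all_filters(table, self._config())
        return out

    def fit_transform(self, table: FeatureTable, y=None) -> FeatureTable:
        return self.transform(table)
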