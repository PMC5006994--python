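"""Wide-format LC-MS feature tables and injection manifests.

The feature table is the universal currency of the pipeline: one row per
chromatographic feature (an m/z, retention-time pair detected in one of four
assay modes), one column per injection, with nonnegative intensities and NaN
marking undetected cells.  Injection metadata (run order, plate, QC role,
dilution fold) lives in a companion manifest keyed by injection id.

File dialect: comma-separated UTF-8.  The feature CSV has a leading
``feature_id`` column, metadata columns ``mz``/``rt``/``assay_mode`` (and an
optional ``annotation``), then one column per injection.  The manifest CSV is
keyed by ``injection_id`` with columns ``run_index``, ``plate_id``, ``role``,
``sample_id``, ``dilution_fold``; extra columns (e.g. storage metadata emitted
by the simulator) are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ASSAY_MODES = ("C18pos", "C18neg", "HILICpos", "HILICneg")
ROLES = ("study", "SQC", "dQC", "RQC", "blank")
DILUTION_FOLDS = (1, 2, 4, 8, 16)

_FEATURE_META = ("mz", "rt", "assay_mode", "annotation")
_MANIFEST_COLS = ("run_index", "plate_id", "role", "sample_id", "dilution_fold")


@dataclass
class FeatureTable:
    """Feature × injection intensity matrix plus feature and injection metadata.

    Parameters
    ----------
    features : pd.DataFrame
        Indexed by ``feature_id``; columns ``mz``, ``rt``, ``assay_mode`` and
        optionally ``annotation``.
    manifest : pd.DataFrame
        Indexed by ``injection_id``; columns ``run_index``, ``plate_id``,
        ``role``, ``sample_id``, ``dilution_fold``.
    X : pd.DataFrame
        Intensities, rows aligned to ``features``, columns to ``manifest``
        sorted by ``run_index``.  NaN marks an undetected cell; a literal 0 is
        retained in arithmetic but counted as undetected for RQC reliability.
    """

    features: pd.DataFrame
    manifest: pd.DataFrame
    X: pd.DataFrame
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        # keep a canonical injection order (by run_index) everywhere
        self.manifest = self.manifest.sort_values("run_index")
        self.X = self.X.loc[self.features.index, self.manifest.index]
        if self.validate_on_init:
            self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        f, m, X = self.features, self.manifest, self.X
        if not f.index.is_unique:
            dup = f.index[f.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature_id(s): {dup}")
        if not m.index.is_unique:
            dup = m.index[m.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate injection_id(s): {dup}")
        for col in ("mz", "rt", "assay_mode"):
            if col not in f.columns:
                raise ValueError(f"feature metadata missing column {col!r}")
        if (f["mz"] <= 0).any():
            raise ValueError("mz must be > 0 for every feature")
        if (f["rt"] < 0).any():
            raise ValueError("rt must be >= 0 for every feature")
        bad_mode = set(f["assay_mode"]) - set(ASSAY_MODES)
        if bad_mode:
            raise ValueError(f"unknown assay_mode(s): {sorted(bad_mode)}")
        for col in ("run_index", "role"):
            if col not in m.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if m["run_index"].duplicated().any():
            dup = m.loc[m["run_index"].duplicated(), "run_index"].tolist()
            raise ValueError(f"duplicate run_index values: {dup}")
        bad_role = set(m["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown role(s): {sorted(bad_role)}")
        if "dilution_fold" in m.columns:
            qc = m["role"].isin(("SQC", "dQC"))
            folds = m.loc[qc, "dilution_fold"]
            if folds.isna().any():
                missing = folds.index[folds.isna()].tolist()
                raise ValueError(f"SQC/dQC injections missing dilution_fold: {missing}")
            bad = set(folds.astype(int)) - set(DILUTION_FOLDS)
            if bad:
                raise ValueError(f"dilution_fold must be one of {DILUTION_FOLDS}, got {sorted(bad)}")
            if (m.loc[m["role"] == "SQC", "dilution_fold"].astype(int) != 1).any():
                raise ValueError("SQC injections must have dilution_fold == 1")
        elif m["role"].isin(("SQC", "dQC")).any():
            raise ValueError("manifest has SQC/dQC injections but no dilution_fold column")
        if X.shape != (len(f), len(m)):
            raise ValueError(f"intensity matrix shape {X.shape} != ({len(f)}, {len(m)})")
        vals = X.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be >= 0 (use NaN for undetected)")

    # -- conveniences ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return len(self.manifest)

    def injections(self, role: str | None = None) -> pd.DataFrame:
        """Manifest rows (sorted by run order), optionally restricted to a role."""
        if role is None:
            return self.manifest
        return self.manifest[self.manifest["role"] == role]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.manifest.copy(), self.X.copy(),
            validate_on_init=False,
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = [fid for fid in self.features.index if fid in set(feature_ids)]
        return FeatureTable(
            self.features.loc[ids].copy(), self.manifest.copy(), self.X.loc[ids].copy(),
            validate_on_init=False,
        )


def _coerce_intensities(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Parse intensity cells to float; unparseable or negative cells → NaN."""
    X = raw.apply(pd.to_numeric, errors="coerce")
    nonempty = raw.notna() & raw.astype(str).apply(lambda s: s.str.strip() != "")
    n_unparseable = int((X.isna() & nonempty).sum().sum())
    neg = X < 0
    n_bad = n_unparseable + int(neg.sum().sum())
    X = X.mask(neg)
    return X.astype(float), n_bad


def read_feature_table(path, manifest_path) -> FeatureTable:
    """Read a feature-table CSV and its injection manifest CSV.

    Every intensity column must have a manifest entry; a missing entry or a
    duplicated run_index is a hard error.  Unparseable or negative cells
    become NaN with a logged warning count.
    """
    df = pd.read_csv(path, dtype={"feature_id": str})
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: first column must be feature_id")
    df = df.set_index("feature_id")
    meta_cols = [c for c in _FEATURE_META if c in df.columns]
    features = df[meta_cols].copy()
    features["mz"] = pd.to_numeric(features["mz"])
    features["rt"] = pd.to_numeric(features["rt"])
    inj_cols = [c for c in df.columns if c not in _FEATURE_META]

    manifest = pd.read_csv(manifest_path, dtype={"injection_id": str, "plate_id": str, "sample_id": str})
    if "injection_id" not in manifest.columns:
        raise ValueError(f"{manifest_path}: missing injection_id column")
    manifest = manifest.set_index("injection_id")
    missing = [c for c in inj_cols if c not in manifest.index]
    if missing:
        raise ValueError(f"manifest has no entry for intensity column(s): {missing}")
    manifest = manifest.loc[inj_cols]
    manifest["run_index"] = pd.to_numeric(manifest["run_index"]).astype(int)
    if manifest["run_index"].duplicated().any():
        dup = manifest.loc[manifest["run_index"].duplicated(), "run_index"].tolist()
        raise ValueError(f"duplicate run_index in manifest: {dup}")
    if "dilution_fold" in manifest.columns:
        manifest["dilution_fold"] = pd.to_numeric(manifest["dilution_fold"], errors="coerce").astype("Int64")

    X, n_bad = _coerce_intensities(df[inj_cols])
    if n_bad:
        log.warning("%s: %d unparseable/negative cells set to missing", path, n_bad)
    return FeatureTable(features, manifest, X)


def write_feature_table(table: FeatureTable, path, manifest_path) -> None:
    """Write a table and manifest as CSV; round-trips values and missingness."""
    out = pd.concat([table.features, table.X], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path)
    man = table.manifest.copy()
    man.index.name = "injection_id"
    man.to_csv(manifest_path)


def merge_plates(tables: list[FeatureTable]) -> FeatureTable:
    """Concatenate per-plate tables into one analytical sequence.

    Feature lists must be identical (same ids, same order); injection ids must
    be disjoint and run indices globally consistent.
    """
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if list(t.features.index) != list(first.features.index):
            diff = set(t.features.index) ^ set(first.features.index)
            raise ValueError(f"feature lists differ; symmetric difference: {sorted(diff)}")
    manifest = pd.concat([t.manifest for t in tables], axis=0)
    if not manifest.index.is_unique:
        dup = manifest.index[manifest.index.duplicated()].unique().tolist()
        raise ValueError(f"injection_id(s) shared between plates: {dup}")
    X = pd.concat([t.X for t in tables], axis=1)
    return FeatureTable(first.features.copy(), manifest, X)
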