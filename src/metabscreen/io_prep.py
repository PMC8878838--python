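"""Peak-table I/O, prevalence filtering, transformation and splitting.

The transformation chain follows untargeted GC-MS practice: peak areas are
normalised to the internal-standard (IS) area of the same injection, missing
values are imputed as half the per-feature minimum observed normalised area,
the ratios are log-transformed and finally autoscaled (mean-centred, divided
by the sample standard deviation) using parameters estimated on the training
split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from metabscreen.simulate import SyntheticCohort

MISSING_SENTINELS = ("", "NA", "NaN", "nan", "N/A")

#: train fraction reproducing a 133/67 split of 200 subjects
DEFAULT_TRAIN_FRACTION = 133 / 200


@dataclass
class PeakTable:
    """Raw per-sample peak areas plus the internal-standard channel."""

    areas: pd.DataFrame  # sample_id index x feature columns, NaN = missing
    is_area: pd.Series  # positive IS area per sample

    def __post_init__(self) -> None:
        if self.areas.index.duplicated().any():
            dups = self.areas.index[self.areas.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.areas.columns.duplicated().any():
            dups = self.areas.columns[self.areas.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if not self.is_area.index.equals(self.areas.index):
            raise ValueError("internal-standard series does not cover all samples")
        if self.is_area.isna().any() or (self.is_area <= 0).any():
            bad = self.is_area.index[~(self.is_area > 0)].tolist()
            raise ValueError(f"non-positive or missing internal-standard area for {bad}")
        if (self.areas < 0).any().any():
            raise ValueError("negative peak areas")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.columns)

    def normalized(self) -> pd.DataFrame:
        """IS-normalised areas (missing entries stay missing)."""
        return self.areas.div(self.is_area, axis=0)

    def subset(self, samples=None, features=None) -> "PeakTable":
        areas = self.areas
        if samples is not None:
            areas = areas.loc[list(samples)]
        if features is not None:
            areas = areas[list(features)]
        return PeakTable(areas=areas.copy(), is_area=self.is_area.loc[areas.index].copy())


@dataclass
class FeatureMatrix:
    """Transformed sample x feature values with provenance and split tags."""

    values: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)
    split: pd.Series | None = None  # 'train' | 'test' | 'none' per sample

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def rows(self, tag: str) -> pd.DataFrame:
        if self.split is None:
            raise ValueError("no split tags attached")
        keep = self.split[self.split == tag].index
        return self.values.loc[keep]


def read_peak_table(path, metadata_path) -> tuple[PeakTable, pd.DataFrame]:
    """Read a peak-table CSV (sample_id, IS_area, features...) and metadata CSV."""
    df = pd.read_csv(path, na_values=list(MISSING_SENTINELS), keep_default_na=True)
    if "sample_id" not in df.columns or "IS_area" not in df.columns:
        raise ValueError("peak table must contain 'sample_id' and 'IS_area' columns")
    df = df.set_index("sample_id")
    feats = [c for c in df.columns if c != "IS_area"]
    areas = df[feats].apply(pd.to_numeric, errors="raise")
    table = PeakTable(areas=areas, is_area=df["IS_area"].astype(float))

    meta = pd.read_csv(metadata_path, dtype={"sample_id": str}, keep_default_na=False)
    required = {"sample_id", "group", "batch", "qc_role"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    absent = set(table.sample_ids) - set(meta["sample_id"])
    if absent:
        raise ValueError(f"samples missing from metadata: {sorted(absent)}")
    return table, meta


def write_peak_table(table: PeakTable, path) -> None:
    out = table.areas.copy()
    out.insert(0, "IS_area", table.is_area)
    out.index.name = "sample_id"
    out.to_csv(path)


def table_from_cohort(cohort: SyntheticCohort) -> tuple[PeakTable, pd.DataFrame]:
    """View a synthetic cohort as a PeakTable + metadata pair."""
    df = cohort.peak_table
    feats = [c for c in df.columns if c != "IS_area"]
    return (
        PeakTable(areas=df[feats], is_area=df["IS_area"]),
        cohort.metadata,
    )


def prevalence_filter(
    table: PeakTable, min_fraction: float, study_ids=None
) -> PeakTable:
    """Retain features observed in at least ``min_fraction`` of study samples.

    QC injections are excluded from the prevalence count when ``study_ids``
    is given. A feature present in exactly ``min_fraction`` of samples is
    retained (>= comparison); e.g. 79 of 100 fails a 0.80 threshold.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction={min_fraction} outside (0, 1]")
    areas = table.areas if study_ids is None else table.areas.loc[list(study_ids)]
    frac = areas.notna().mean(axis=0)
    keep = frac[frac >= min_fraction].index
    if len(keep) == 0:
        raise ValueError("prevalence filter removed every feature")
    return table.subset(features=keep)


class LogAutoscaler(TransformerMixin, BaseEstimator):
    """Impute, log-transform and autoscale IS-normalised peak areas.

    Operates on a DataFrame of IS-normalised areas (ratios). ``fit`` learns,
    from the training rows only: the per-feature half-minimum imputation
    value, the post-log column means, and the sample (n-1) standard
    deviations. Constant columns (sd below ``sd_tol``) are dropped with a
    note in ``dropped_``. ``transform`` applies those frozen parameters, so
    test-set values never depend on test-set composition.
    """

    def __init__(self, sd_tol: float = 1e-12):
        self.sd_tol = sd_tol

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if (X <= 0).any().any():
            raise ValueError("non-positive normalised areas; check IS channel")
        self.halfmin_ = X.min(axis=0, skipna=True) / 2.0
        if self.halfmin_.isna().any():
            bad = self.halfmin_.index[self.halfmin_.isna()].tolist()
            raise ValueError(f"features with no observed value in training rows: {bad}")
        logged = np.log(X.fillna(self.halfmin_))
        sd = logged.std(axis=0, ddof=1)
        self.dropped_ = sd.index[sd <= self.sd_tol].tolist()
        kept = sd.index[sd > self.sd_tol]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.features_ = list(kept)
        self.mean_ = logged[kept].mean(axis=0)
        self.scale_ = sd[kept]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "features_")
        X = pd.DataFrame(X)
        missing = set(self.features_) - set(X.columns)
        if missing:
            raise ValueError(f"input lacks fitted features: {sorted(missing)}")
        X = X[self.features_]
        logged = np.log(X.fillna(self.halfmin_[self.features_]))
        return (logged - self.mean_) / self.scale_


def normalize_transform(
    table: PeakTable, fit_ids=None, transform_ids=None
) -> tuple[FeatureMatrix, LogAutoscaler]:
    """Build the transformed feature matrix for a peak table.

    ``fit_ids`` (default: all rows) designate the rows whose statistics set
    the imputation and scaling parameters; ``transform_ids`` (default: all
    rows) are the rows returned.
    """
    ratios = table.normalized()
    fit_rows = ratios if fit_ids is None else ratios.loc[list(fit_ids)]
    scaler = LogAutoscaler().fit(fit_rows)
    rows = ratios if transform_ids is None else ratios.loc[list(transform_ids)]
    values = scaler.transform(rows)
    fm = FeatureMatrix(
        values=values,
        transform_log=[
            "normalize_to_internal_standard",
            "impute_half_minimum",
            "log",
            "autoscale_train_params",
        ],
    )
    return fm, scaler


def pool_controls(groups: pd.Series) -> pd.Series:
    """Map HS and BCRT to the pooled CTRL class; CRC stays CRC."""
    return groups.replace({"HS": "CTRL", "BCRT": "CTRL"})


def split_train_test(
    metadata: pd.DataFrame,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> pd.Series:
    """Stratified train/test tags over study samples; QC rows tagged 'none'.

    With the 200-subject default cohort and the default fraction the split is
    133 train / 67 test.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction={train_fraction} outside (0, 1)")
    study = metadata[metadata["qc_role"] == "study"]
    y = pool_controls(study["group"])
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need both CTRL and CRC present to split")
    if counts.min() < 2:
        raise ValueError(f"class with <2 members: {counts.to_dict()}")
    train_ids, test_ids = train_test_split(
        study["sample_id"].to_numpy(),
        train_size=train_fraction,
        stratify=y.to_numpy(),
        random_state=seed,
    )
    tags = pd.Series("none", index=metadata["sample_id"], name="split")
    tags.loc[train_ids] = "train"
    tags.loc[test_ids] = "test"
    return tags
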