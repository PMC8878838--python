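"""Seeded synthetic serum-metabolomics cohorts.

The generator emulates the statistical structure of an untargeted GC-MS
screening study: right-skewed (log-normal) peak areas normalised to a spiked
internal standard, three clinical groups (healthy subjects HS, benign
colorectal disease BCRT, colorectal cancer CRC), a planted differential
subset acting multiplicatively on CRC areas, injection batches carrying the
four quality-control injections (solvent blank, standard mixture, pooled
sample, duplicate), and completely-at-random missingness.

Every draw is governed by a single integer seed so downstream stages are
testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QC_ROLES = ("blank", "standard_mix", "pooled", "duplicate")

#: number of compounds in the analytical standard mixture
N_STANDARDS = 15

#: corruption flags understood by :func:`simulate_qc_batch`
CORRUPTIONS = ("blank", "standard_drift", "duplicate_drift", "pooled_shift")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic screening cohort.

    Defaults mirror the study conditions the pipeline assumes: 50 healthy
    subjects, 50 benign-disease subjects and 100 cancer patients; 243
    consistently detected signals of which 24 are truly differential with
    |log2 fold change| between 1 and 2.5; multiplicative noise with a 30%
    coefficient of variation; injection batches of 25 study samples.
    """

    n_hs: int = 50
    n_bcrt: int = 50
    n_crc: int = 100
    n_features: int = 243
    n_differential: int = 24
    log2fc_range: tuple[float, float] = (1.0, 2.5)
    cv_noise: float = 0.3
    missing_rate: float = 0.04
    batch_size: int = 25
    seed: int = 0
    # hyperprior for per-feature log-mean areas; IS nominal area and its CV
    meanlog_loc: float = 13.0
    meanlog_scale: float = 1.2
    is_nominal: float = 5e5
    is_cv: float = 0.05
    # "mnar" switches missingness to intensity-dependent (low areas censored)
    missing_mode: str = "mcar"

    def validate(self) -> None:
        if min(self.n_hs, self.n_bcrt, self.n_crc) < 1:
            raise ValueError("group sizes must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_differential <= self.n_features:
            raise ValueError(
                f"n_differential={self.n_differential} exceeds n_features={self.n_features}"
            )
        lo, hi = self.log2fc_range
        if lo < 0.5:
            raise ValueError(f"log2fc_range lower bound {lo} is below 0.5")
        if hi < lo:
            raise ValueError("log2fc_range upper bound below lower bound")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate={self.missing_rate} outside [0, 1)")
        if self.cv_noise <= 0:
            raise ValueError("cv_noise must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.missing_mode not in ("mcar", "mnar"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")

    def n_study(self) -> int:
        return self.n_hs + self.n_bcrt + self.n_crc


@dataclass
class SyntheticCohort:
    """A generated cohort: peak table, metadata and planted ground truth."""

    peak_table: "pd.DataFrame"  # sample_id index, IS_area + feature columns
    metadata: pd.DataFrame  # sample_id, group, batch, qc_role, duplicate_of
    truth: pd.DataFrame  # feature_id, true_log2fc (CRC relative to controls)
    standard_expected: pd.Series  # expected IS-normalised area per standard feature

    @property
    def feature_ids(self) -> list[str]:
        return [c for c in self.peak_table.columns if c != "IS_area"]

    def study_ids(self) -> list[str]:
        m = self.metadata
        return m.loc[m["qc_role"] == "study", "sample_id"].tolist()


def _feature_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"M{i:0{width}d}" for i in range(1, n + 1)]


def _sdlog(cv: float) -> float:
    # CV of a log-normal: sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv**2)))


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort with QC injections, reproducibly for a fixed seed.

    Study-sample peak areas are log-normal per feature (log-means drawn from a
    common hyperprior), differential features are shifted multiplicatively in
    the CRC group by ``2**log2fc`` with a random sign recorded in ``truth``,
    and the internal-standard channel is present (and never missing) for every
    injection.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    feats = _feature_ids(spec.n_features)
    n_study = spec.n_study()
    sdlog = _sdlog(spec.cv_noise)

    meanlog = rng.normal(spec.meanlog_loc, spec.meanlog_scale, size=spec.n_features)

    groups = np.array(
        ["HS"] * spec.n_hs + ["BCRT"] * spec.n_bcrt + ["CRC"] * spec.n_crc
    )
    order = rng.permutation(n_study)  # enrollment order -> batch assignment
    groups = groups[order]
    counters = {"HS": 0, "BCRT": 0, "CRC": 0}
    sample_ids = []
    for g in groups:
        counters[g] += 1
        sample_ids.append(f"{g}{counters[g]:03d}")

    # planted differential effects (CRC vs pooled controls), multiplicative
    diff_idx = rng.choice(spec.n_features, size=spec.n_differential, replace=False)
    lo, hi = spec.log2fc_range
    magnitudes = rng.uniform(lo, hi, size=spec.n_differential)
    signs = rng.choice([-1.0, 1.0], size=spec.n_differential)
    log2fc = magnitudes * signs

    shift = np.zeros((n_study, spec.n_features))
    crc_mask = groups == "CRC"
    for j, fc in zip(diff_idx, log2fc):
        shift[crc_mask, j] = fc * np.log(2.0)

    log_areas = (
        meanlog[None, :] + shift + rng.normal(0.0, sdlog, size=(n_study, spec.n_features))
    )
    areas = np.exp(log_areas)

    is_sdlog = _sdlog(spec.is_cv)

    def draw_is(n: int) -> np.ndarray:
        return np.exp(rng.normal(np.log(spec.is_nominal), is_sdlog, size=n))

    study_df = pd.DataFrame(areas, index=sample_ids, columns=feats)

    # missingness on study cells only; IS channel never missing
    if spec.missing_rate > 0:
        if spec.missing_mode == "mcar":
            miss = rng.random(study_df.shape) < spec.missing_rate
        else:  # intensity-dependent: censor the lowest areas preferentially
            ranks = study_df.rank(axis=0, pct=True).to_numpy()
            prob = spec.missing_rate * 2.0 * (1.0 - ranks)
            miss = rng.random(study_df.shape) < prob
        study_df = study_df.mask(miss)

    study_is = draw_is(n_study)

    n_batches = int(np.ceil(n_study / spec.batch_size))
    batch_of = np.arange(n_study) // spec.batch_size + 1

    meta_rows = [
        {
            "sample_id": sid,
            "group": g,
            "batch": int(b),
            "qc_role": "study",
            "duplicate_of": "",
        }
        for sid, g, b in zip(sample_ids, groups, batch_of)
    ]

    # expected IS-normalised areas of the standard mixture compounds
    std_feats = feats[:N_STANDARDS] if spec.n_features >= N_STANDARDS else feats
    standard_expected = pd.Series(
        np.exp(meanlog[: len(std_feats)]) / spec.is_nominal, index=std_feats
    )

    qc_frames: list[pd.DataFrame] = []
    qc_is: list[float] = []
    blank_scale = 1e-6  # instrument-noise floor relative to typical areas
    for b in range(1, n_batches + 1):
        in_batch = np.flatnonzero(batch_of == b)
        bid = f"B{b:02d}"

        blank = rng.exponential(blank_scale * np.exp(spec.meanlog_loc), size=spec.n_features)
        std = np.zeros(spec.n_features)
        std_is = draw_is(1)[0]
        for k, f in enumerate(std_feats):
            # observed area = expected ratio * this injection's IS, +-2% noise
            std[feats.index(f)] = (
                standard_expected[f] * std_is * np.exp(rng.normal(0.0, 0.02))
            )
        pooled = np.exp(meanlog + rng.normal(0.0, 0.03, size=spec.n_features))
        dup_src = sample_ids[int(rng.choice(in_batch))]
        dup = study_df.loc[dup_src].to_numpy(copy=True)
        dup = np.where(np.isnan(dup), np.nan, dup * np.exp(rng.normal(0.0, 0.02, dup.shape)))

        frame = pd.DataFrame(
            np.vstack([blank, std, pooled, dup]),
            index=[f"{bid}_blank", f"{bid}_std", f"{bid}_pool", f"{bid}_dup"],
            columns=feats,
        )
        qc_frames.append(frame)
        dup_is = study_is[sample_ids.index(dup_src)] * np.exp(rng.normal(0.0, 0.01))
        qc_is.extend([draw_is(1)[0], std_is, draw_is(1)[0], dup_is])
        for role, sid in zip(QC_ROLES, frame.index):
            meta_rows.append(
                {
                    "sample_id": sid,
                    "group": "QC",
                    "batch": b,
                    "qc_role": role,
                    "duplicate_of": dup_src if role == "duplicate" else "",
                }
            )

    table = pd.concat([study_df] + qc_frames)
    table.insert(0, "IS_area", np.concatenate([study_is, np.array(qc_is)]))
    table.index.name = "sample_id"

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        {"feature_id": [feats[j] for j in diff_idx], "true_log2fc": log2fc}
    ).sort_values("feature_id", ignore_index=True)

    return SyntheticCohort(
        peak_table=table,
        metadata=metadata,
        truth=truth,
        standard_expected=standard_expected,
    )


def simulate_qc_batch(
    spec: CohortSpec, corrupt: frozenset[str] | set[str] = frozenset()
) -> tuple[SyntheticCohort, int]:
    """Generate a cohort whose *first* batch carries the requested QC failures.

    Each flag makes exactly one validation rule fail on batch 1:

    - ``"blank"``: the solvent blank contains a large contaminating peak;
    - ``"standard_drift"``: one standard's IS-normalised area drifts by 25%
      (outside the 10% tolerance);
    - ``"duplicate_drift"``: five of the duplicate's top-100 peaks drift by
      30% (outside the 15% tolerance);
    - ``"pooled_shift"``: the pooled injection is displaced far from the
      other pooled samples in the sample model.
    """
    corrupt = frozenset(corrupt)
    unknown = corrupt - set(CORRUPTIONS)
    if unknown:
        raise ValueError(f"unknown corruption flag(s): {sorted(unknown)}")

    cohort = simulate_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    table = cohort.peak_table
    feats = cohort.feature_ids

    if "blank" in corrupt:
        j = feats[len(feats) // 2]
        table.loc["B01_blank", j] = float(np.exp(spec.meanlog_loc))
    if "standard_drift" in corrupt:
        f = cohort.standard_expected.index[0]
        table.loc["B01_std", f] *= 1.25
    if "duplicate_drift" in corrupt:
        dup_meta = cohort.metadata.query("batch == 1 and qc_role == 'duplicate'").iloc[0]
        orig = dup_meta["duplicate_of"]
        ratios = (
            table.loc[orig, feats].astype(float) / table.loc[orig, "IS_area"]
        ).dropna()
        top = ratios.sort_values(ascending=False).index[:100]
        hit = rng.choice(len(top), size=min(5, len(top)), replace=False)
        for k in hit:
            table.loc["B01_dup", top[k]] *= 1.30
    if "pooled_shift" in corrupt:
        table.loc["B01_pool", feats] = table.loc["B01_pool", feats].astype(float) * np.exp(
            rng.normal(0.0, 1.0, size=len(feats)) + 1.5
        )
    return cohort, 1


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write peak table, metadata and truth to ``outdir`` as CSV/TSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": str(out / "peaks.csv"),
        "metadata": str(out / "metadata.csv"),
        "truth": str(out / "truth.tsv"),
    }
    cohort.peak_table.to_csv(paths["peaks"])
    cohort.metadata.to_csv(paths["metadata"], index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
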