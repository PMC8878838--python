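"""Per-batch quality-control validation.

Each injection batch carries four control injections — a solvent blank, a
standard mixture, a pooled sample and a duplicate of one study sample — and
passes only if all four rules hold:

1. the blank contains no peak above a (relative) area threshold;
2. every standard's IS-normalised area is within 10% of its expected value;
3. among the 100 largest IS-normalised peaks of the duplicated study
   injection, the duplicate's areas are within 15% of the original;
4. the batch's pooled injection sits inside the Hotelling T-squared 95%
   ellipse of the other pooled samples in a 2-component principal-component
   model built from all study samples.

Rule 4 operationalises "allocated in the same area of the other pooled
samples" as a score-space ellipse test; the statistic and its bound are
reported so the tolerance can be tightened or relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from metabscreen.io_prep import LogAutoscaler, PeakTable

RULES = ("blank", "standard_ratio", "duplicate", "pooled")


@dataclass
class RuleResult:
    passed: bool
    statistic: float  # measured value on the rule's own scale
    bound: float  # the tolerance it was compared against
    note: str = ""


@dataclass
class QcReport:
    batch: int
    valid: bool = True  # False when a control injection is missing
    rules: dict[str, RuleResult] = field(default_factory=dict)
    note: str = ""

    @property
    def passed(self) -> bool:
        return self.valid and all(r.passed for r in self.rules.values())


@dataclass
class QcContext:
    """Study-wide quantities the per-batch rules compare against."""

    blank_threshold: float  # absolute area bound for rule 1
    standard_expected: pd.Series | None  # expected IS-normalised standard areas
    pooled_scores: pd.DataFrame  # PCA scores of every pooled injection
    study_scores: pd.DataFrame | None = None  # PCA scores of the study samples
    standard_tol: float = 0.10
    duplicate_tol: float = 0.15
    pooled_alpha: float = 0.05
    # ellipse scale: 'study' = covariance of the full sample model,
    # 'pooled' = covariance of the other pooled injections
    pooled_reference: str = "study"


def build_context(
    table: PeakTable,
    metadata: pd.DataFrame,
    standard_expected: pd.Series | None = None,
    blank_rel_threshold: float = 1e-3,
    standard_tol: float = 0.10,
    duplicate_tol: float = 0.15,
    pooled_alpha: float = 0.05,
    pooled_reference: str = "study",
    n_pca_components: int = 2,
) -> QcContext:
    """Precompute the study-level model the four rules reference.

    The blank threshold is ``blank_rel_threshold`` times the median total ion
    area of study samples. When ``standard_expected`` is None the expected
    standard ratios are the medians over all standard-mixture injections.
    The pooled-sample model is a PCA fit on the transformed study samples;
    pooled injections are projected into it.
    """
    study_ids = metadata.loc[metadata["qc_role"] == "study", "sample_id"]
    total_ion = table.areas.loc[study_ids].sum(axis=1, skipna=True)
    blank_threshold = blank_rel_threshold * float(total_ion.median())

    if standard_expected is None:
        std_ids = metadata.loc[metadata["qc_role"] == "standard_mix", "sample_id"]
        ratios = table.normalized().loc[std_ids]
        # standards are the channels consistently present in the mixture
        # injections; channels at instrument-noise level are excluded
        floor = 1e-6 * float(ratios.max().max())
        present = ratios.columns[(ratios > floor).all()]
        standard_expected = ratios[present].median()

    scaler = LogAutoscaler()
    study_ratios = table.normalized().loc[study_ids]
    z = scaler.fit(study_ratios).transform(study_ratios)
    pca = PCA(n_components=n_pca_components, random_state=0).fit(z)

    pooled_ids = metadata.loc[metadata["qc_role"] == "pooled", "sample_id"]
    pooled_ids = [s for s in pooled_ids if s in table.areas.index]
    pooled_z = scaler.transform(table.normalized().loc[pooled_ids])
    pooled_scores = pd.DataFrame(
        pca.transform(pooled_z), index=pooled_ids,
        columns=[f"PC{i+1}" for i in range(n_pca_components)],
    )
    batch_of = metadata.set_index("sample_id")["batch"]
    pooled_scores["batch"] = batch_of.loc[pooled_scores.index].to_numpy()
    study_scores = pd.DataFrame(
        pca.transform(z), index=study_ids,
        columns=[f"PC{i+1}" for i in range(n_pca_components)],
    )
    return QcContext(
        blank_threshold=blank_threshold,
        standard_expected=standard_expected,
        pooled_scores=pooled_scores,
        study_scores=study_scores,
        standard_tol=standard_tol,
        duplicate_tol=duplicate_tol,
        pooled_alpha=pooled_alpha,
        pooled_reference=pooled_reference,
    )


def _hotelling_t2_bound(n: int, p: int, alpha: float) -> float:
    # T2 ~ p(n^2-1)/(n(n-p)) * F(p, n-p) for a new observation vs n references
    if n <= p:
        return np.inf
    f = stats.f.ppf(1 - alpha, p, n - p)
    return p * (n + 1) * (n - 1) / (n * (n - p)) * f


def validate_batch(
    table: PeakTable,
    metadata: pd.DataFrame,
    batch: int,
    context: QcContext,
    top_n: int = 100,
) -> QcReport:
    """Evaluate the four QC rules for one batch. Rules are independent, so
    the report does not depend on evaluation order."""
    meta_b = metadata[metadata["batch"] == batch]
    roles = meta_b.set_index("qc_role")["sample_id"]
    report = QcReport(batch=batch)
    for role in ("blank", "standard_mix", "pooled", "duplicate"):
        if role not in roles.index:
            report.valid = False
            report.note = f"missing control injection: {role}"
            return report

    ratios = table.normalized()

    # rule 1 — blank: no peak above the threshold area
    blank_max = float(table.areas.loc[roles["blank"]].max(skipna=True))
    report.rules["blank"] = RuleResult(
        passed=blank_max <= context.blank_threshold,
        statistic=blank_max,
        bound=context.blank_threshold,
    )

    # rule 2 — standard mixture: each IS-normalised area within tolerance
    exp = context.standard_expected
    if exp is None or len(exp) == 0:
        dev = 0.0
    else:
        obs = ratios.loc[roles["standard_mix"], exp.index]
        dev = float((obs / exp - 1.0).abs().max())
    report.rules["standard_ratio"] = RuleResult(
        passed=dev <= context.standard_tol, statistic=dev, bound=context.standard_tol
    )

    # rule 3 — duplicate: top-N peaks of the original within tolerance
    dup_row = meta_b[meta_b["qc_role"] == "duplicate"].iloc[0]
    orig_id = dup_row.get("duplicate_of", "") or ""
    if not orig_id or orig_id not in table.areas.index:
        report.valid = False
        report.note = "duplicate injection has no resolvable source sample"
        return report
    orig = ratios.loc[orig_id].dropna()
    top = orig.sort_values(ascending=False).index[:top_n]
    dup = ratios.loc[roles["duplicate"], top]
    dup_dev = float((dup / orig[top] - 1.0).abs().max())
    report.rules["duplicate"] = RuleResult(
        passed=dup_dev <= context.duplicate_tol,
        statistic=dup_dev,
        bound=context.duplicate_tol,
    )

    # rule 4 — pooled sample inside the 95% ellipse around the other pooled
    # samples; the ellipse scale comes from the all-sample score model by
    # default ('study'), or from the other pooled injections ('pooled')
    scores = context.pooled_scores
    pcs = [c for c in scores.columns if c != "batch"]
    here = scores.loc[scores["batch"] == batch, pcs]
    others = scores.loc[scores["batch"] != batch, pcs]
    use_study = context.pooled_reference == "study" and context.study_scores is not None
    ref = context.study_scores[pcs] if use_study else others
    if len(here) == 0 or len(others) < 1 or len(ref) < len(pcs) + 2:
        # not enough reference injections to define the ellipse
        report.rules["pooled"] = RuleResult(
            passed=True, statistic=0.0, bound=np.inf,
            note="insufficient reference pooled injections; rule not evaluable",
        )
    else:
        # median centre: robust to one wild pooled injection elsewhere
        mu = others.median().to_numpy()
        cov = np.cov(ref.to_numpy(), rowvar=False)
        z = here.iloc[0].to_numpy() - mu
        t2 = float(z @ np.linalg.solve(cov, z))
        bound = _hotelling_t2_bound(len(ref), len(pcs), context.pooled_alpha)
        report.rules["pooled"] = RuleResult(
            passed=t2 <= bound, statistic=t2, bound=bound
        )
    return report


def validate_all_batches(
    table: PeakTable,
    metadata: pd.DataFrame,
    standard_expected: pd.Series | None = None,
    **kwargs,
) -> list[QcReport]:
    context = build_context(table, metadata, standard_expected=standard_expected, **kwargs)
    batches = sorted(metadata.loc[metadata["qc_role"] != "study", "batch"].unique())
    return [validate_batch(table, metadata, b, context) for b in batches]


def report_to_dict(report: QcReport) -> dict:
    return {
        "batch": int(report.batch),
        "valid": bool(report.valid),
        "passed": bool(report.passed),
        "note": report.note,
        "rules": {
            name: {
                "passed": bool(r.passed),
                "statistic": float(r.statistic),
                "bound": float(r.bound),
                "note": r.note,
            }
            for name, r in report.rules.items()
        },
    }
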