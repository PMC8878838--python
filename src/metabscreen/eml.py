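"""The ensemble machine-learning (EML) vote score.

Each trained classifier casts a signed vote for every sample:
``+cv_accuracy * confidence`` when it predicts the positive (CRC) class,
``-cv_accuracy * confidence`` when it predicts the control class. The EML
score is the sum of the votes; a sample is called CRC when its score
exceeds the cut-off (0 by default, optionally optimised on training scores
by Youden's J). A sample can therefore only be misclassified if models
carrying more than half of the total accuracy-times-confidence mass err on
it together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from metabscreen.model_zoo import TrainedModel

POSITIVE = "CRC"
NEGATIVE = "CTRL"


@dataclass
class EmlResult:
    votes: pd.DataFrame  # sample x model signed scores
    scores: pd.Series  # per-sample EML score (sum of votes)
    cutoff: float
    predicted: pd.Series  # POSITIVE iff score > cutoff
    confidence: pd.Series  # |score| / sum of model cv accuracies


def _signed_votes(models: list[TrainedModel], positive: str = POSITIVE) -> pd.DataFrame:
    cols = {}
    index = None
    for m in models:
        if m.predictions is None:
            raise ValueError(f"model {m.kind} has no predictions attached")
        pred = m.predictions
        if index is None:
            index = pred.index
        elif not index.equals(pred.index):
            missing = index.difference(pred.index).tolist()
            raise ValueError(f"model {m.kind} missing predictions for {missing}")
        sign = np.where(pred["class"].astype(str) == positive, 1.0, -1.0)
        cols[m.kind] = sign * m.cv_accuracy * pred["confidence"].to_numpy()
    return pd.DataFrame(cols, index=index)


def eml_scores(
    models: list[TrainedModel], positive: str = POSITIVE
) -> pd.DataFrame:
    """Per-sample votes and their sum for a list of trained models."""
    votes = _signed_votes(models, positive)
    votes["eml_score"] = votes.sum(axis=1)
    return votes


def eml_score(models: list[TrainedModel], sample_id: str, positive: str = POSITIVE) -> float:
    """Signed ensemble score for a single sample."""
    votes = _signed_votes(models, positive)
    if sample_id not in votes.index:
        raise ValueError(f"no predictions for sample {sample_id!r}")
    return float(votes.loc[sample_id].sum())


def optimize_cutoff(scores: pd.Series, labels: pd.Series, positive: str = POSITIVE) -> float:
    """Cut-off maximising Youden's J (sensitivity + specificity - 1).

    Candidates are the midpoints between consecutive distinct scores plus 0;
    among ties the cut-off closest to 0 wins (then the smaller one).
    """
    s = np.asarray(scores, dtype=float)
    y = (np.asarray(labels).astype(str) == positive)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to optimise the cut-off")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.unique(np.concatenate([mids, [0.0], uniq]))
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best_j, best_c = -np.inf, 0.0
    for c in candidates:
        called = s > c
        sens = (called & y).sum() / n_pos
        spec = (~called & ~y).sum() / n_neg
        j = sens + spec - 1.0
        better = j > best_j + 1e-12
        tie = abs(j - best_j) <= 1e-12 and (
            abs(c) < abs(best_c) - 1e-15 or (abs(c) == abs(best_c) and c < best_c)
        )
        if better or tie:
            best_j, best_c = j, float(c)
    return best_c


def classify(
    models: list[TrainedModel],
    cutoff: float = 0.0,
    positive: str = POSITIVE,
    negative: str = NEGATIVE,
) -> EmlResult:
    """Score and classify every sample the models have predictions for.

    A score strictly above the cut-off calls the positive class; a score at
    the cut-off calls the control class (favouring specificity).
    """
    votes = _signed_votes(models, positive)
    scores = votes.sum(axis=1)
    scores.name = "eml_score"
    total_acc = sum(m.cv_accuracy for m in models)
    predicted = pd.Series(
        np.where(scores > cutoff, positive, negative), index=scores.index, name="predicted"
    )
    confidence = (scores.abs() / total_acc) if total_acc > 0 else scores * 0.0
    confidence.name = "eml_confidence"
    return EmlResult(
        votes=votes, scores=scores, cutoff=float(cutoff),
        predicted=predicted, confidence=confidence,
    )
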