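"""Relief nearest-neighbor scoring and multi-tube score fusion.

The Relief score of a test sample is the distance to its nearest *normal*
training sample minus the distance to its nearest *AML* training sample.  A
normal test sample sits close to some normal neighbor, so its score is
negative; an AML sample's score is positive.  The class is read off the sign
(AML iff score > 0; an exact 0 predicts normal, for determinism).

Each staining tube yields its own EMD matrix and hence its own score vector;
the final prediction sums the per-tube scores with equal weight and compares
the sum against 0.  ``|summed score|`` serves as a confidence proxy.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .emd import EmdMatrix
from .errors import ConfigurationError, SchemaError

__all__ = [
    "relief_score",
    "predict_single_tube",
    "training_scores",
    "combine_tubes",
    "ReliefClassifier",
]

POSITIVE = "AML"
NEGATIVE = "normal"

# a |score| below this fraction of the cohort's median |score| is flagged as
# a low-confidence call (advisory only; the sign still decides the class)
LOW_CONFIDENCE_FRACTION = 0.1


def _train_split(labels: Mapping[str, str]):
    normals = [s for s, lab in labels.items() if lab == NEGATIVE]
    amls = [s for s, lab in labels.items() if lab == POSITIVE]
    if not normals or not amls:
        raise ConfigurationError(
            f"training set needs both classes; got {len(normals)} normal, "
            f"{len(amls)} AML"
        )
    return normals, amls


def relief_score(test_id: str, emd: EmdMatrix, labels: Mapping[str, str]) -> float:
    """``min_j d(test, normal_j) - min_j d(test, AML_j)`` over training samples.

    If ``test_id`` itself appears in ``labels`` (scoring a training sample
    for diagnostics), its self-distance is excluded.
    """
    normals, amls = _train_split(labels)
    row = emd.row(test_id)
    normals = [s for s in normals if s != test_id]
    amls = [s for s in amls if s != test_id]
    if not normals or not amls:
        raise ConfigurationError("excluding self left a training class empty")
    return float(row[normals].min() - row[amls].min())


def _score_frame(scores: dict[str, float], tube_id: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {"sample_id": list(scores), "score": list(scores.values())}
    ).sort_values("score", kind="stable", ignore_index=True)
    df["prediction"] = np.where(df["score"] > 0, POSITIVE, NEGATIVE)
    df["confidence"] = df["score"].abs()
    cutoff = LOW_CONFIDENCE_FRACTION * df["confidence"].median()
    df["low_confidence"] = df["confidence"] < cutoff
    df.insert(0, "tube_id", tube_id)
    return df


def predict_single_tube(
    emd: EmdMatrix, labels: Mapping[str, str], test_ids: Sequence[str]
) -> pd.DataFrame:
    """Score and classify test samples from one tube's EMD matrix.

    Returns a frame sorted by score with columns ``tube_id, sample_id,
    score, prediction, confidence, low_confidence``.
    """
    scores = {t: relief_score(t, emd, labels) for t in test_ids}
    return _score_frame(scores, emd.tube_id)


def training_scores(emd: EmdMatrix, labels: Mapping[str, str]) -> pd.DataFrame:
    """Leave-self-out Relief scores of the training samples (diagnostics)."""
    return _score_frame(
        {t: relief_score(t, emd, labels) for t in labels}, emd.tube_id
    )


def combine_tubes(
    per_tube_scores: Sequence[pd.DataFrame],
    included_tubes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Sum per-tube scores (equal weight) and classify by the sign of the sum.

    ``per_tube_scores`` are frames from :func:`predict_single_tube`; all must
    cover the same test samples.  ``included_tubes`` restricts the sum (e.g.
    tubes 2-7 to drop the control panels); default is every tube present.

    Returns one row per test sample, sorted by summed score, with one
    ``tube_<id>`` column per included tube plus ``score_sum, prediction,
    confidence``.
    """
    if not per_tube_scores:
        raise ConfigurationError("no per-tube scores to combine")
    wide = {}
    for df in per_tube_scores:
        tube = int(df["tube_id"].iloc[0])
        if included_tubes is not None and tube not in set(included_tubes):
            continue
        wide[f"tube_{tube}"] = df.set_index("sample_id")["score"]
    if not wide:
        raise ConfigurationError("included_tubes excluded every tube")
    table = pd.DataFrame(wide)
    if table.isna().any().any():
        raise SchemaError("test samples differ between tubes")
    table["score_sum"] = table.sum(axis=1)
    table["prediction"] = np.where(table["score_sum"] > 0, POSITIVE, NEGATIVE)
    table["confidence"] = table["score_sum"].abs()
    table = table.sort_values("score_sum", kind="stable")
    table.index.name = "sample_id"
    return table.reset_index()


class ReliefClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-neighbor difference-of-distances classifier on precomputed
    distances.

    Follows the scikit-learn ``metric="precomputed"`` convention:

    * ``fit(X, y)`` — ``X`` is the (n_train, n_train) distance matrix (only
      its shape is consulted) and ``y`` the binary labels.
    * ``predict(X)`` / ``decision_function(X)`` — ``X`` is (n_query,
      n_train): distances from each query sample to the training samples.

    The decision value is ``min dist to negative-class - min dist to
    positive-class``; positive values predict ``positive_label``.
    """

    def __init__(self, positive_label: str = POSITIVE, negative_label: str = NEGATIVE):
        self.positive_label = positive_label
        self.negative_label = negative_label

    def fit(self, X, y) -> "ReliefClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != X.shape[1] or X.shape[0] != y.shape[0]:
            raise SchemaError(
                "fit expects a square (n_train, n_train) precomputed distance "
                "matrix and matching labels"
            )
        labels = set(y.tolist())
        if labels != {self.positive_label, self.negative_label}:
            raise ConfigurationError(
                f"labels {sorted(map(str, labels))} do not match "
                f"{{{self.negative_label!r}, {self.positive_label!r}}}"
            )
        self.classes_ = np.unique(y)
        self._pos_mask = y == self.positive_label
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "_pos_mask")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._pos_mask.size:
            raise SchemaError(
                f"expected distances to {self._pos_mask.size} training samples, "
                f"got {X.shape[1]}"
            )
        return X[:, ~self._pos_mask].min(axis=1) - X[:, self._pos_mask].min(axis=1)

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, self.positive_label, self.negative_label)
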