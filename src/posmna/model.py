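"""PASS-style naive Bayes over PoSMNA descriptors.

The classifier treats each of the seven CYP interaction activities
one-vs-rest: for activity *a* the positives are the training pairs labeled
*a* and the negatives are all other training pairs.  Per-descriptor counts
``n_d`` (pairs containing descriptor *d*) and ``n_ad`` (pairs containing *d*
and labeled *a*) give a smoothed conditional probability

    P(a | d) = (n_ad + k * p_a) / (n_d + k),        p_a = N_a / N

which falls back to the prior ``p_a`` for descriptors unseen in training.
A pair's raw score for activity *a* is the mean arcsine-transformed
conditional probability over its descriptor set D:

    S_a(D) = (1/|D|) * sum_{d in D} arcsin(2 * P(a|d) - 1)

The combiner is strictly increasing in every term; because the calibrated
outputs below are rank-based, any strictly monotone combiner yields the same
Pa/Pi and the same IAP (AUC), so the arcsine choice is a documented,
swappable convention rather than a load-bearing formula.

Pa ("probability to be active") and Pi ("to be inactive") are tie-adjusted
empirical ranks of the raw score against the leave-one-out score
distributions of the training actives and inactives for that activity.  The
leave-one-out scores are computed analytically by excluding each pair's own
contribution from the counts, which is exactly equivalent to refitting
without the pair.  This construction makes the IAP validation criterion
(probability that a random active outscores a random inactive) identical to
the AUC ROC by definition.

Prediction output per pair is the list of the seven activities with
(S, Pa, Pi, dP = Pa − Pi), ranked by dP descending; the qualitative call is
"interaction predicted" for activities with dP above the decision threshold
(default 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .chemgraph import MolecularGraph
from .descriptors import DEFAULT_LEVEL, pair_descriptors
from .errors import ModelError

#: The seven CYP isoform interaction classes modeled by default.
CYP_ACTIVITIES = (
    "CYP1A2",
    "CYP2B6",
    "CYP2C19",
    "CYP2C8",
    "CYP2C9",
    "CYP2D6",
    "CYP3A4",
)

FORMAT_VERSION = "posmna-model/1"


def pair_key(id_a: str, id_b: str) -> tuple[str, str]:
    """Canonical unordered key for a molecule pair."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


@dataclass(frozen=True)
class PairRecord:
    """One training pair: unordered ids, its labels and its PoSMNA set."""

    key: tuple[str, str]
    labels: frozenset[str]
    descriptors: frozenset[str]


@dataclass
class TrainingTable:
    """Resolved training data: unique unordered pairs with >=1 label each."""

    pairs: list[PairRecord]
    activities: tuple[str, ...] = CYP_ACTIVITIES

    def __post_init__(self):
        seen = set()
        for p in self.pairs:
            if p.key in seen:
                raise ModelError(f"duplicate pair key {p.key}")
            seen.add(p.key)
            if not p.labels:
                raise ModelError(f"pair {p.key} carries no activity label")
            unknown = p.labels - set(self.activities)
            if unknown:
                raise ModelError(
                    f"pair {p.key} has unknown activities {sorted(unknown)}"
                )
            if not p.descriptors:
                raise ModelError(f"pair {p.key} has an empty descriptor set")

    def label_matrix(self) -> np.ndarray:
        y = np.zeros((len(self.pairs), len(self.activities)), dtype=np.int64)
        index = {a: j for j, a in enumerate(self.activities)}
        for i, p in enumerate(self.pairs):
            for a in p.labels:
                y[i, index[a]] = 1
        return y


@dataclass(frozen=True)
class ActivityPrediction:
    activity: str
    score: float
    pa: float
    pi: float
    dp: float


@dataclass(frozen=True)
class PredictionRecord:
    """Per-activity (S, Pa, Pi, dP) rows for one pair, ranked by dP descending."""

    pair_id: tuple[str | None, str | None]
    rows: tuple[ActivityPrediction, ...]

    def top(self) -> ActivityPrediction:
        return self.rows[0]

    def classify(self, threshold: float = 0.0) -> set[str]:
        return {r.activity for r in self.rows if r.dp > threshold}


class PairInteractionClassifier(BaseEstimator, ClassifierMixin):
    """Naive Bayes activity-spectrum classifier for molecule pairs.

    Parameters
    ----------
    smoothing : float, default 1.0
        Strength ``k`` of the prior pull in the conditional-probability
        estimate; ``k = 0`` gives raw frequencies.
    activities : sequence of str, optional
        Label vocabulary; defaults to the seven CYP isoform classes.
    threshold : float, default 0.0
        dP cutoff for the qualitative YES/NO call in :meth:`predict`.

    Attributes
    ----------
    activities_ : tuple of str
    n_pairs_ : int
        N, total training pairs.
    n_active_ : ndarray (n_activities,)
        N_a per activity.
    descriptor_index_ : dict str -> int
    n_with_descriptor_ : ndarray (n_descriptors,)
        n_d counts.
    n_active_with_descriptor_ : ndarray (n_descriptors, n_activities)
        n_ad counts.
    loo_scores_ : ndarray (n_pairs, n_activities)
        Analytic leave-one-out score of every training pair.
    calibration_active_, calibration_inactive_ : list of sorted ndarray
        Per-activity LOO score distributions of actives / inactives.
    """

    def __init__(self, smoothing: float = 1.0, activities=None, threshold: float = 0.0):
        self.smoothing = smoothing
        self.activities = activities
        self.threshold = threshold

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        """Fit counts and leave-one-out calibration distributions.

        ``X`` is a sequence of descriptor collections (one PoSMNA set per
        pair); ``y`` is a binary indicator array of shape
        ``(n_pairs, n_activities)`` or a sequence of label collections.
        """
        if self.smoothing < 0:
            raise ModelError("smoothing must be >= 0")
        sets = [frozenset(d) for d in X]
        if len(sets) < 2:
            raise ModelError("need at least 2 training pairs")
        if any(not s for s in sets):
            raise ModelError("empty descriptor set in training data")
        acts = tuple(self.activities) if self.activities is not None else CYP_ACTIVITIES
        Y = self._as_label_matrix(y, acts, len(sets))

        n_act = len(acts)
        n_a = Y.sum(axis=0)
        for j, a in enumerate(acts):
            if n_a[j] == 0:
                raise ModelError(f"activity {a!r} has no positive training pair")
            if n_a[j] == len(sets):
                raise ModelError(f"activity {a!r} has no negative training pair")

        vocab: dict[str, int] = {}
        rows: list[np.ndarray] = []
        for s in sets:
            idx = np.empty(len(s), dtype=np.int64)
            for t, d in enumerate(sorted(s)):
                j = vocab.get(d)
                if j is None:
                    j = vocab[d] = len(vocab)
                idx[t] = j
            rows.append(idx)

        n_d = np.zeros(len(vocab), dtype=np.int64)
        n_ad = np.zeros((len(vocab), n_act), dtype=np.int64)
        for i, idx in enumerate(rows):
            n_d[idx] += 1
            n_ad[idx] += Y[i]

        self.activities_ = acts
        self.classes_ = np.asarray(acts, dtype=object)
        self.n_pairs_ = len(sets)
        self.n_active_ = n_a
        self.descriptor_index_ = vocab
        self.n_with_descriptor_ = n_d
        self.n_active_with_descriptor_ = n_ad
        self._train_rows = rows
        self._train_labels = Y

        self.loo_scores_ = np.vstack(
            [self._loo_score_row(i) for i in range(len(sets))]
        )
        self.calibration_active_ = []
        self.calibration_inactive_ = []
        for j in range(n_act):
            mask = Y[:, j].astype(bool)
            self.calibration_active_.append(np.sort(self.loo_scores_[mask, j]))
            self.calibration_inactive_.append(np.sort(self.loo_scores_[~mask, j]))
        return self

    @staticmethod
    def _as_label_matrix(y, acts, n) -> np.ndarray:
        try:
            arr = np.asarray(y)
        except ValueError:  # ragged label collections
            arr = np.empty(0)
        if arr.ndim == 2 and (
            np.issubdtype(arr.dtype, np.number) or arr.dtype == bool
        ):
            if arr.shape != (n, len(acts)):
                raise ModelError(
                    f"label matrix shape {arr.shape} != ({n}, {len(acts)})"
                )
            return (arr != 0).astype(np.int64)
        index = {a: j for j, a in enumerate(acts)}
        Y = np.zeros((n, len(acts)), dtype=np.int64)
        for i, labels in enumerate(y):
            if isinstance(labels, str):
                labels = [labels]
            for a in labels:
                if a not in index:
                    raise ModelError(f"unknown activity label {a!r} in row {i}")
                Y[i, index[a]] = 1
        return Y

    # -------------------------------------------------------------- scoring

    def _check_fitted(self):
        if not hasattr(self, "descriptor_index_"):
            raise ModelError("model is not fitted")

    def conditional_probability(self, activity: str, descriptor: str) -> float:
        """Smoothed P(activity | descriptor); the prior p_a for unseen descriptors."""
        self._check_fitted()
        j = self.activities_.index(activity)
        p_a = self.n_active_[j] / self.n_pairs_
        i = self.descriptor_index_.get(descriptor)
        if i is None or self.n_with_descriptor_[i] == 0:
            return float(p_a)
        k = self.smoothing
        num = self.n_active_with_descriptor_[i, j] + k * p_a
        den = self.n_with_descriptor_[i] + k
        if den == 0:  # k == 0 and n_d == 0, already handled above
            return float(p_a)
        return float(num / den)

    def _score_matrix(self, descriptor_sets) -> np.ndarray:
        """Raw scores S for each input set x each activity."""
        self._check_fitted()
        k = self.smoothing
        p = self.n_active_ / self.n_pairs_  # (n_act,)
        out = np.empty((len(descriptor_sets), len(self.activities_)))
        for r, D in enumerate(descriptor_sets):
            D = frozenset(D)
            if not D:
                raise ModelError("cannot score an empty descriptor set")
            seen = [self.descriptor_index_.get(d) for d in sorted(D)]
            idx = np.array([i for i in seen if i is not None], dtype=np.int64)
            n_unseen = len(D) - len(idx)
            if len(idx):
                num = self.n_active_with_descriptor_[idx] + k * p
                den = (self.n_with_descriptor_[idx] + k)[:, None]
                with np.errstate(invalid="ignore", divide="ignore"):
                    cond = np.where(den > 0, num / den, p)
            else:
                cond = np.empty((0, len(p)))
            total = np.arcsin(2.0 * cond - 1.0).sum(axis=0)
            total = total + n_unseen * np.arcsin(2.0 * p - 1.0)
            out[r] = total / len(D)
        return out

    def decision_function(self, X) -> np.ndarray:
        """Raw scores, shape ``(n_samples, n_activities)``; values in [-pi/2, pi/2]."""
        return self._score_matrix([frozenset(d) for d in X])

    def score_pair(self, activity: str, descriptors) -> float:
        """Raw score of one descriptor set for one activity."""
        j = self.activities_.index(activity)
        return float(self._score_matrix([frozenset(descriptors)])[0, j])

    def _loo_score_row(self, i: int) -> np.ndarray:
        """Analytic leave-one-out scores of training pair ``i`` (all activities).

        Exactly equals refitting without pair ``i``: every count the pair
        contributed to (N, N_a, n_d, n_ad) is decremented before scoring.
        """
        idx = self._train_rows[i]
        y_i = self._train_labels[i]
        k = self.smoothing
        n = self.n_pairs_ - 1
        n_a = self.n_active_ - y_i
        p = n_a / n
        n_d = self.n_with_descriptor_[idx] - 1
        n_ad = self.n_active_with_descriptor_[idx] - y_i[None, :]
        num = n_ad + k * p
        den = (n_d + k)[:, None].astype(float)
        prior_term = np.broadcast_to(p, num.shape)
        unseen = np.broadcast_to((n_d == 0)[:, None], num.shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(unseen, prior_term, np.where(den > 0, num / den, 1.0))
        return np.arcsin(2.0 * cond - 1.0).mean(axis=0)

    def loo_score(self, activity: str, i: int) -> float:
        """Leave-one-out raw score of training pair ``i`` for ``activity``."""
        self._check_fitted()
        j = self.activities_.index(activity)
        return float(self.loo_scores_[i, j])

    # ---------------------------------------------------------- calibration

    def pa_pi(self, activity: str, score: float) -> tuple[float, float]:
        """Tie-adjusted empirical (Pa, Pi) of a raw score for one activity."""
        self._check_fitted()
        j = self.activities_.index(activity)
        return self._pa_pi_j(j, score)

    def _pa_pi_j(self, j: int, score: float) -> tuple[float, float]:
        act = self.calibration_active_[j]
        inact = self.calibration_inactive_[j]
        lo = np.searchsorted(act, score, side="left")
        hi = np.searchsorted(act, score, side="right")
        pa = (lo + 0.5 * (hi - lo)) / len(act)
        lo = np.searchsorted(inact, score, side="left")
        hi = np.searchsorted(inact, score, side="right")
        pi = ((len(inact) - hi) + 0.5 * (hi - lo)) / len(inact)
        return float(pa), float(pi)

    # ----------------------------------------------------------- prediction

    def predict_record(
        self, descriptors, pair_id: tuple[str | None, str | None] = (None, None)
    ) -> PredictionRecord:
        """Full ranked activity spectrum for one PoSMNA descriptor set."""
        scores = self._score_matrix([frozenset(descriptors)])[0]
        rows = []
        for j, a in enumerate(self.activities_):
            pa, pi = self._pa_pi_j(j, scores[j])
            rows.append(ActivityPrediction(a, float(scores[j]), pa, pi, pa - pi))
        rows.sort(key=lambda r: (-r.dp, r.activity))
        return PredictionRecord(pair_id=pair_id, rows=tuple(rows))

    def predict(self, X) -> np.ndarray:
        """Qualitative calls: boolean matrix of dP > threshold per activity."""
        self._check_fitted()
        out = np.zeros((len(X), len(self.activities_)), dtype=bool)
        for i, D in enumerate(X):
            rec = self.predict_record(D)
            hits = rec.classify(self.threshold)
            for j, a in enumerate(self.activities_):
                out[i, j] = a in hits
        return out


# --------------------------------------------------------------------------
# Thin functional surface over the estimator (the operation-level API).
# --------------------------------------------------------------------------

def fit(table: TrainingTable, smoothing: float = 1.0) -> PairInteractionClassifier:
    """Fit the pair classifier from a resolved training table."""
    clf = PairInteractionClassifier(smoothing=smoothing, activities=table.activities)
    X = [p.descriptors for p in table.pairs]
    y = table.label_matrix()
    clf.fit(X, y)
    clf.pair_keys_ = [p.key for p in table.pairs]
    return clf


def cond_prob(m: PairInteractionClassifier, activity: str, descriptor: str) -> float:
    return m.conditional_probability(activity, descriptor)


def score(m: PairInteractionClassifier, activity: str, descriptors) -> float:
    return m.score_pair(activity, descriptors)


def loo_score(m: PairInteractionClassifier, activity: str, i: int) -> float:
    return m.loo_score(activity, i)


def pa_pi(m: PairInteractionClassifier, activity: str, s: float) -> tuple[float, float]:
    return m.pa_pi(activity, s)


def predict(
    m: PairInteractionClassifier,
    ga: MolecularGraph,
    gb: MolecularGraph,
    level: int = DEFAULT_LEVEL,
) -> PredictionRecord:
    """Ranked activity spectrum for a pair of prepared molecular graphs."""
    D = pair_descriptors(ga, gb, level)
    return m.predict_record(D.descriptors, pair_id=D.pair_id)


def classify(record: PredictionRecord, threshold: float = 0.0) -> set[str]:
    """Activities predicted YES: those with dP strictly above the threshold."""
    return record.classify(threshold)
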