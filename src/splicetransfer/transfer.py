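"""Iterative semi-supervised random-forest label transfer.

The core algorithm: a random forest is trained on labelled cell lines,
class probabilities are computed for every unlabelled patient, and the
patients predicted with highest confidence (probability of the second
class above ``prob_high`` or below ``prob_low``) are admitted into the
training set with their predicted label.  Each such admission step is a
*round*; at most ``per_round_cap_base * r`` new patients enter at round
``r``, so the model adapts to the patient domain gradually instead of
overfitting to its own early guesses.  The loop stops when no patient
clears a threshold (or ``max_rounds`` is hit); patients never admitted
end up *unclassified*.  Admitted patients keep their label — the scheme
is self-training without relabelling.

Class probability is, by default, the forest's mean leaf probability
(sklearn's ``predict_proba``); a per-tree majority-vote fraction is
available via ``probability="vote"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IterativeTransferClassifier",
    "TransferResult",
    "fit_forest",
    "scale_per_domain",
    "run_transfer",
    "importance_trajectory",
]

UNLABELLED = -1


def _column_standardize(block: np.ndarray) -> np.ndarray:
    """Standardize columns to mean 0, sd 1 (population sd); constant -> 0."""
    mean = np.nanmean(block, axis=0, keepdims=True)
    sd = np.nanstd(block, axis=0, keepdims=True)
    out = np.where(sd > 0, (block - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    out[np.isnan(block)] = np.nan
    return out


def scale_per_domain(cells: pd.DataFrame, patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each feature independently within each domain.

    Cell lines and patients live on systematically shifted scales
    (culture vs tumour, purity dilution); scaling each domain separately
    removes the global offset so the forest splits on within-domain
    structure.  Idempotent; features constant within a domain map to
    zeros in that domain.
    """
    if list(cells.columns) != list(patients.columns):
        raise ValueError("cell and patient matrices must share the same feature set")
    c = _column_standardize(cells.to_numpy(dtype=float))
    p = _column_standardize(patients.to_numpy(dtype=float))
    return (
        pd.DataFrame(c, index=cells.index, columns=cells.columns),
        pd.DataFrame(p, index=patients.index, columns=patients.columns),
    )


def fit_forest(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    n_trees: int = 1000,
    seed: int | None = None,
) -> RandomForestClassifier:
    """Fit a random forest; Gini importances normalised to sum 1 by sklearn.

    Raises on a single-class training set (no probability contrast).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(np.asarray(features, dtype=float), y)
    return rf


def _prob_second_class(rf: RandomForestClassifier, X: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean_leaf":
        return rf.predict_proba(X)[:, 1]
    if mode == "vote":
        votes = np.zeros(len(X))
        for tree in rf.estimators_:
            votes += tree.predict_proba(X).argmax(axis=1) == 1
        return votes / len(rf.estimators_)
    raise ValueError(f"unknown probability mode '{mode}'")


class IterativeTransferClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised self-training random forest for domain transfer.

    Follows the scikit-learn semi-supervised convention: ``fit(X, y)``
    where ``y`` holds the two source-domain labels and ``-1`` for every
    unlabelled target-domain sample.  Labelled rows are the cell-line
    domain; unlabelled rows the patient domain.

    Parameters
    ----------
    n_estimators : trees per forest (1000 mirrors the reference setup).
    prob_high, prob_low : admission thresholds on the probability of the
        second class (``classes_[1]``).  A patient is a candidate when
        its probability is ``> prob_high`` (second class) or
        ``< prob_low`` (first class).  Use (0.55, 0.45) for mixed
        expression+splicing features.
    per_round_cap_base : at most ``per_round_cap_base * r`` NEW patients
        are admitted at round ``r`` (``cap_mode="per_round"``); with
        ``cap_mode="cumulative"`` the cap bounds the cumulative total.
    max_rounds : safety valve; typical runs stop on their own in ~10-12
        rounds.
    scale_per_domain : standardize every feature within each domain
        (labelled vs unlabelled rows) once, before the loop.
    probability : "mean_leaf" (sklearn predict_proba) or "vote"
        (fraction of trees voting for the class).
    impute : missing features are filled with the training-set median,
        recomputed each round from the current training rows.

    Attributes
    ----------
    classes_ : the two source labels, sorted.
    transduction_ : final label per sample (original labels kept for the
        labelled rows; admitted patients get their assigned label;
        ``-1`` for unclassified patients).
    assignment_round_ : 0 for seed-labelled rows, round of admission for
        admitted patients, ``-1`` for unclassified.
    probability_history_ : DataFrame (rounds x samples) of the
        second-class probability of every unlabelled-domain sample at
        every round.
    importance_history_ : DataFrame (rounds x features) of normalised
        Gini importances (rows sum to 1).
    admitted_per_round_ : list of arrays of admitted row indices.
    n_rounds_ : number of rounds executed.
    estimator_ : forest fitted on the final training set.
    """

    def __init__(
        self,
        n_estimators: int = 1000,
        prob_high: float = 0.6,
        prob_low: float = 0.4,
        per_round_cap_base: int = 10,
        max_rounds: int = 50,
        cap_mode: str = "per_round",
        scale_per_domain: bool = False,
        probability: str = "mean_leaf",
        impute: str = "median",
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.prob_high = prob_high
        self.prob_low = prob_low
        self.per_round_cap_base = per_round_cap_base
        self.max_rounds = max_rounds
        self.cap_mode = cap_mode
        self.scale_per_domain = scale_per_domain
        self.probability = probability
        self.impute = impute
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if np.isinf(X).any():
            raise ValueError("non-finite feature values")
        if not (0.0 < self.prob_low < self.prob_high < 1.0):
            raise ValueError("need 0 < prob_low < prob_high < 1")
        labelled = y != UNLABELLED
        classes = np.unique(y[labelled])
        if len(classes) != 2:
            raise ValueError("exactly two labelled classes are required")
        if (~labelled).sum() == 0:
            raise ValueError("no unlabelled samples to transfer to")
        return X, y, labelled, classes

    def fit(self, X, y):
        X, y, labelled, classes = self._validate(X, y)
        self.classes_ = classes
        n = len(y)
        rng_seeds = np.random.SeedSequence(self.random_state).generate_state(self.max_rounds + 1) % (2**31)

        if self.scale_per_domain:
            X = X.copy()
            X[labelled] = _column_standardize(X[labelled])
            X[~labelled] = _column_standardize(X[~labelled])

        in_training = labelled.copy()
        assigned = y.copy()
        assignment_round = np.where(labelled, 0, UNLABELLED)
        patient_rows = np.flatnonzero(~labelled)

        prob_hist: list[np.ndarray] = []
        imp_hist: list[np.ndarray] = []
        admitted_per_round: list[np.ndarray] = []

        for r in range(1, self.max_rounds + 1):
            train = np.flatnonzero(in_training)
            med = np.nanmedian(X[train], axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            Ximp = np.where(np.isnan(X), med[None, :], X)

            rf = fit_forest(Ximp[train], assigned[train], self.n_estimators, int(rng_seeds[r - 1]))
            prob_b = _prob_second_class(rf, Ximp[patient_rows], self.probability)

            imp = rf.feature_importances_
            if imp.sum() <= 0:
                imp = np.full(X.shape[1], 1.0 / X.shape[1])
            prob_hist.append(prob_b)
            imp_hist.append(imp)

            pending = ~in_training[patient_rows]
            is_b = prob_b > self.prob_high
            is_a = prob_b < self.prob_low
            candidate = pending & (is_a | is_b)
            if self.cap_mode == "per_round":
                cap = self.per_round_cap_base * r
            elif self.cap_mode == "cumulative":
                cap = self.per_round_cap_base * r - int((assignment_round[patient_rows] > 0).sum())
            else:
                raise ValueError(f"unknown cap_mode '{self.cap_mode}'")
            if cap <= 0 or not candidate.any():
                admitted_per_round.append(np.array([], dtype=int))
                self._final_rf = rf
                break

            conf = np.maximum(prob_b, 1.0 - prob_b)
            cand_idx = np.flatnonzero(candidate)
            # confidence descending; ties broken by stable row (= id) order
            order = cand_idx[np.argsort(-conf[cand_idx], kind="stable")]
            take = order[:cap]
            rows = patient_rows[take]
            assigned[rows] = np.where(is_b[take], classes[1], classes[0])
            in_training[rows] = True
            assignment_round[rows] = r
            admitted_per_round.append(rows)
            self._final_rf = rf
        n_rounds = len(prob_hist)

        # refit on the final training set so predict() reflects the final model
        train = np.flatnonzero(in_training)
        med = np.nanmedian(X[train], axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        self._medians = med
        Ximp = np.where(np.isnan(X), med[None, :], X)
        self.estimator_ = fit_forest(Ximp[train], assigned[train], self.n_estimators, int(rng_seeds[-1]))

        self.transduction_ = np.where(in_training, assigned, UNLABELLED)
        self.assignment_round_ = assignment_round
        self.n_rounds_ = n_rounds
        self.admitted_per_round_ = admitted_per_round
        self.patient_rows_ = patient_rows
        self.probability_history_ = pd.DataFrame(
            np.vstack(prob_hist), index=pd.RangeIndex(1, n_rounds + 1, name="round"), columns=patient_rows
        )
        self.importance_history_ = pd.DataFrame(
            np.vstack(imp_hist), index=pd.RangeIndex(1, n_rounds + 1, name="round"),
            columns=pd.RangeIndex(X.shape[1], name="feature"),
        )
        self.final_prob_b_ = pd.Series(prob_hist[-1], index=patient_rows)
        return self

    # ------------------------------------------------------------------

    def _prepare(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if self.scale_per_domain:
            X = _column_standardize(X)
        return np.where(np.isnan(X), self._medians[None, :], X)

    def predict(self, X):
        return self.estimator_.predict(self._prepare(X))

    def predict_proba(self, X):
        return self.estimator_.predict_proba(self._prepare(X))


# ---------------------------------------------------------------- wrappers


@dataclass
class TransferResult:
    """Named-sample view of a fitted :class:`IterativeTransferClassifier`."""

    assignments: pd.DataFrame        # patient_id: assignment, assignment_round, prob_b
    probability_history: pd.DataFrame  # round x patient_id
    importance_history: pd.DataFrame   # round x feature_id
    admitted_per_round: list[list[str]]
    estimator: IterativeTransferClassifier


def run_transfer(
    cell_features: pd.DataFrame,
    cell_labels: pd.Series,
    patient_features: pd.DataFrame,
    **params,
) -> TransferResult:
    """Run the transfer on named samples-x-features matrices.

    ``cell_labels`` must have exactly two values (e.g. ``A``/``B``);
    assignments are reported as ``<label>_like`` or ``unclassified``.
    Patients are processed in lexicographic id order so confidence ties
    break reproducibly.
    """
    if list(cell_features.columns) != list(patient_features.columns):
        raise ValueError("cell and patient matrices must share the same feature columns")
    if len(patient_features) == 0:
        raise ValueError("empty patient set")
    patient_features = patient_features.sort_index()
    X = np.vstack([cell_features.to_numpy(dtype=float), patient_features.to_numpy(dtype=float)])
    y = np.concatenate(
        [cell_labels.loc[cell_features.index].to_numpy(), np.full(len(patient_features), UNLABELLED, dtype=object)]
    )
    est = IterativeTransferClassifier(**params).fit(X, y)

    patient_ids = patient_features.index.to_numpy()
    row_to_id = {row: patient_ids[i] for i, row in enumerate(est.patient_rows_)}
    trans = est.transduction_[est.patient_rows_]
    assignment = np.where(trans == UNLABELLED, "unclassified", np.char.add(trans.astype(str), "_like"))
    assignments = pd.DataFrame(
        {
            "assignment": assignment,
            "assignment_round": est.assignment_round_[est.patient_rows_],
            "prob_b": est.final_prob_b_.to_numpy(),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    prob_hist = est.probability_history_.copy()
    prob_hist.columns = [row_to_id[c] for c in prob_hist.columns]
    imp_hist = est.importance_history_.copy()
    imp_hist.columns = list(cell_features.columns)
    admitted = [[row_to_id[r] for r in rows] for rows in est.admitted_per_round_]
    return TransferResult(assignments, prob_hist, imp_hist, admitted, est)


def importance_trajectory(importance_history: pd.DataFrame, top_k: int = 10) -> dict:
    """Long-format importance table plus first/last-round top-k overlap."""
    long = importance_history.reset_index().melt(
        id_vars="round", var_name="feature_id", value_name="importance"
    )
    first = importance_history.iloc[0].nlargest(top_k).index
    last = importance_history.iloc[-1].nlargest(top_k).index
    return {
        "table": long,
        "top_first": list(first),
        "top_last": list(last),
        "overlap": len(set(first) & set(last)),
    }
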