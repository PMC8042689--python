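"""Consensus all-relevant feature selection (Boruta) for a minimal signature.

Boruta augments the feature matrix with *shadow* features — per-column
permutations that preserve each feature's marginal distribution while
destroying its relation to the labels — fits a random forest, and asks
whether a real feature's Gini importance beats the best shadow.  Hits
are accumulated over iterations and tested against Binomial(k, 1/2)
with a Bonferroni correction over the still-undecided features:
features with significantly many hits are *confirmed*, significantly
few *rejected*, and the rest remain *tentative*.

Because a single run depends on its random state, the consensus
selector repeats the procedure ``n_runs`` times with distinct seeds and
keeps features confirmed in at least ``min_hits`` runs (defaults 10 and
7).  The result is a small, stable signature without any arbitrary
importance threshold.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["BorutaConsensus", "boruta_single_run", "signature_psi_summary", "build_signature_table"]


def boruta_single_run(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_estimators: int = 1000,
    max_iter: int = 50,
    alpha: float = 0.05,
    perc: float = 100.0,
) -> np.ndarray:
    """One Boruta run; returns per-feature status in {confirmed, rejected, tentative}.

    ``perc`` is the percentile of shadow importances used as the hit
    threshold (100 = strict maximum-shadow rule).  Rejected features are
    dropped from later forest fits; the run stops early once every
    feature is decided.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_samples, n_features = X.shape
    rng = np.random.default_rng(seed)
    status = np.full(n_features, "tentative", dtype=object)
    hits = np.zeros(n_features, dtype=int)
    trials = np.zeros(n_features, dtype=int)

    for _ in range(max_iter):
        undecided = status == "tentative"
        if not undecided.any():
            break
        active = status != "rejected"
        act_idx = np.flatnonzero(active)
        Xa = X[:, act_idx]
        shadow = rng.permuted(Xa, axis=0)
        # keep at least 5 shadow columns so the max-shadow reference is stable
        while shadow.shape[1] < 5:
            extra = rng.permuted(Xa, axis=0)
            shadow = np.hstack([shadow, extra[:, : min(extra.shape[1], 5 - shadow.shape[1])]])
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        rf.fit(np.hstack([Xa, shadow]), y)
        imp = rf.feature_importances_
        imp_real = imp[: Xa.shape[1]]
        threshold = np.percentile(imp[Xa.shape[1]:], perc)
        hits[act_idx] += imp_real > threshold
        trials[act_idx] += 1

        m = int(undecided.sum())
        for j in np.flatnonzero(undecided):
            p_confirm = stats.binom.sf(hits[j] - 1, trials[j], 0.5)
            p_reject = stats.binom.cdf(hits[j], trials[j], 0.5)
            if p_confirm * m < alpha:
                status[j] = "confirmed"
            elif p_reject * m < alpha:
                status[j] = "rejected"
    return status


class BorutaConsensus(SelectorMixin, BaseEstimator):
    """Consensus Boruta selector: keep features confirmed in >= min_hits of n_runs.

    Parameters
    ----------
    n_runs, min_hits : number of independent Boruta runs and the hit
        threshold for consensus selection (defaults 10 and 7).
    n_estimators : trees in each internal forest (kept equal to the
        transfer classifier's forest for coherence).
    max_iter, alpha, perc : per-run Boruta controls (iteration budget,
        binomial-test level, shadow-importance percentile).
    count_tentative : if True, tentative features also count as hits
        (lenient reading; default counts only confirmed).
    random_state : run ``i`` uses seed ``random_state + i`` semantics
        via a spawned seed sequence.

    Attributes
    ----------
    hits_ : per-feature number of runs in which the feature scored.
    support_ : boolean mask, ``hits_ >= min_hits``.
    run_statuses_ : (n_runs x n_features) array of per-run statuses.
    """

    def __init__(
        self,
        n_runs: int = 10,
        min_hits: int = 7,
        n_estimators: int = 1000,
        max_iter: int = 50,
        alpha: float = 0.05,
        perc: float = 100.0,
        count_tentative: bool = False,
        random_state: int | None = None,
    ):
        self.n_runs = n_runs
        self.min_hits = min_hits
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.alpha = alpha
        self.perc = perc
        self.count_tentative = count_tentative
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_runs < self.min_hits:
            raise ValueError(
                f"inconsistent config: min_hits={self.min_hits} can never be reached with n_runs={self.n_runs}"
            )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.isnan(X).any():
            med = np.nanmedian(X, axis=0)
            X = np.where(np.isnan(X), np.where(np.isnan(med), 0.0, med)[None, :], X)
        self.n_features_in_ = X.shape[1]
        seeds = np.random.SeedSequence(self.random_state).generate_state(self.n_runs) % (2**31)
        statuses = np.vstack(
            [
                boruta_single_run(
                    X, y, int(s), self.n_estimators, self.max_iter, self.alpha, self.perc
                )
                for s in seeds
            ]
        )
        scoring = ("confirmed", "tentative") if self.count_tentative else ("confirmed",)
        self.run_statuses_ = statuses
        self.hits_ = np.isin(statuses, scoring).sum(axis=0)
        self.support_ = self.hits_ >= self.min_hits
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def signature_psi_summary(
    psi: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature group means, standard errors and delta (second - first group).

    Means and SEs are pairwise-complete (missing samples dropped per
    feature); SE = sd / sqrt(n) with sample sd (ddof=1).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups expected")
    if features is not None:
        absent = [f for f in features if f not in psi.index]
        if absent:
            raise KeyError(f"features absent from PSI matrix: {absent}")
        psi = psi.loc[list(features)]
    (name_a, cols_a), (name_b, cols_b) = groups.items()
    out = pd.DataFrame(index=psi.index)
    for name, cols in ((name_a, cols_a), (name_b, cols_b)):
        block = psi[list(cols)]
        n = block.notna().sum(axis=1)
        out[f"mean_{name}"] = block.mean(axis=1, skipna=True)
        out[f"se_{name}"] = block.std(axis=1, ddof=1, skipna=True) / np.sqrt(n)
    out["delta_psi"] = out[f"mean_{name_b}"] - out[f"mean_{name_a}"]
    return out


def build_signature_table(
    selector: BorutaConsensus,
    feature_ids: Sequence[str],
    event_info: pd.DataFrame,
    psi: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Assemble the signature report: hits, selection flag, coordinates, PSI summary."""
    check_is_fitted(selector, "support_")
    feature_ids = list(feature_ids)
    if len(feature_ids) != selector.n_features_in_:
        raise ValueError("feature_ids length does not match the fitted selector")
    table = pd.DataFrame(
        {"hits": selector.hits_, "selected": selector.support_},
        index=pd.Index(feature_ids, name="event_id"),
    )
    table = table.join(event_info, how="left")
    summary = signature_psi_summary(psi.loc[feature_ids], groups)
    return table.join(summary)
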