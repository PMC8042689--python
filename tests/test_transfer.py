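"""Iterative semi-supervised forest: admission dynamics, invariants, recovery."""

import numpy as np
import pandas as pd
import pytest

from splicetransfer.transfer import (
    IterativeTransferClassifier,
    fit_forest,
    importance_trajectory,
    run_transfer,
    scale_per_domain,
)


def separable_data(n_per_class=10, n_features=6, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b[:, 0] += gap  # one separating feature
    X = np.vstack([a, b])
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, y


class TestFitForest:
    def test_separating_feature_dominates_importance(self):
        """The single informative feature carries the top Gini importance,
        reproducibly across independent fits."""
        wins = 0
        for seed in range(10):
            X, y = separable_data(gap=5.0, seed=seed)
            rf = fit_forest(X, y, n_trees=100, seed=seed)
            wins += int(np.argmax(rf.feature_importances_) == 0)
        assert wins >= 9

    def test_importances_sum_to_one(self):
        X, y = separable_data()
        rf = fit_forest(X, y, n_trees=50, seed=1)
        assert rf.feature_importances_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_training_probabilities_track_labels(self):
        X, y = separable_data(gap=6.0, seed=2)
        rf = fit_forest(X, y, n_trees=200, seed=2)
        prob_b = rf.predict_proba(X)[:, 1]
        assert (prob_b[y == "B"] > 0.5).all()
        assert (prob_b[y == "A"] < 0.5).all()

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            fit_forest(X, np.array(["A"] * 4), n_trees=10, seed=0)


class TestScalePerDomain:
    def test_per_domain_moments(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(rng.normal(5, 2, (20, 4)), columns=list("wxyz"))
        pats = pd.DataFrame(rng.normal(-3, 7, (30, 4)), columns=list("wxyz"))
        sc, sp = scale_per_domain(cells, pats)
        for block in (sc, sp):
            assert np.allclose(block.mean(axis=0), 0.0, atol=1e-12)
            # population sd, matching StandardScaler semantics
            assert np.allclose(block.to_numpy().std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_zeroed_only_in_its_domain(self):
        cells = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        pats = pd.DataFrame({"f": [4.0, 4.0, 4.0]})
        sc, sp = scale_per_domain(cells, pats)
        assert (sp["f"] == 0.0).all()
        assert sc["f"].std() > 0

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cells = pd.DataFrame(rng.normal(size=(10, 3)))
        pats = pd.DataFrame(rng.normal(size=(12, 3)))
        s1c, s1p = scale_per_domain(cells, pats)
        s2c, s2p = scale_per_domain(s1c, s1p)
        assert np.allclose(s1c, s2c) and np.allclose(s1p, s2p)

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scale_per_domain(pd.DataFrame({"a": [1.0]}), pd.DataFrame({"b": [1.0]}))


def run_copied_cohort(n_cells=8, n_feat=5, seed=0, **params):
    rng = np.random.default_rng(seed)
    Xc = np.vstack(
        [rng.normal(0, 0.3, (n_cells, n_feat)), rng.normal(2, 0.3, (n_cells, n_feat))]
    )
    cells = pd.DataFrame(Xc, index=[f"c{i:02d}" for i in range(2 * n_cells)])
    labels = pd.Series(["A"] * n_cells + ["B"] * n_cells, index=cells.index)
    patients = cells.copy()
    patients.index = [f"p{i:02d}" for i in range(2 * n_cells)]
    res = run_transfer(cells, labels, patients, n_estimators=100, random_state=seed, **params)
    return res, labels


class TestRunTransfer:
    def test_copied_patients_fully_recovered(self):
        """Patients identical to cell lines inherit their source labels."""
        res, labels = run_copied_cohort()
        expected = (labels.str[-1] + "_like").to_numpy()
        got = res.assignments.sort_index()["assignment"].to_numpy()
        assert (got == expected).all()

    def test_pure_noise_stops_immediately(self):
        """Features carrying no label signal leave every patient in the
        (prob_low, prob_high) dead zone: zero admissions, stop at round 1."""
        # a feature carrying zero signal (constant) pins every class
        # probability at the balanced prior 0.5, inside the dead zone
        cells = pd.DataFrame({"f": np.zeros(20)}, index=[f"c{i:02d}" for i in range(20)])
        labels = pd.Series(["A", "B"] * 10, index=cells.index)
        patients = pd.DataFrame({"f": np.zeros(15)}, index=[f"p{i:02d}" for i in range(15)])
        res = run_transfer(cells, labels, patients, n_estimators=100, random_state=3)
        assert res.estimator.n_rounds_ == 1
        assert (res.assignments["assignment"] == "unclassified").all()
        assert res.admitted_per_round == [[]]

    def test_admission_cap_schedule(self):
        """With 35+ immediately eligible patients the cap admits at most
        10, 20, 30... per round and the training set grows monotonically."""
        rng = np.random.default_rng(4)
        n = 40
        cells = pd.DataFrame(
            np.vstack([rng.normal(0, 0.2, (6, 3)), rng.normal(3, 0.2, (6, 3))]),
            index=[f"c{i:02d}" for i in range(12)],
        )
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=cells.index)
        patients = pd.DataFrame(
            np.vstack([rng.normal(0, 0.2, (n // 2, 3)), rng.normal(3, 0.2, (n // 2, 3))]),
            index=[f"p{i:02d}" for i in range(n)],
        )
        res = run_transfer(cells, labels, patients, n_estimators=100, random_state=4)
        sizes = [len(r) for r in res.admitted_per_round]
        for r, s in enumerate(sizes, start=1):
            assert s <= 10 * r
        assert sum(sizes) <= n
        # monotone non-decreasing training set, admitted never relabelled
        rounds = res.assignments["assignment_round"]
        admitted = rounds[rounds > 0]
        assert (np.sort(admitted.unique()) == np.arange(1, admitted.max() + 1)).all()

    def test_determinism(self):
        r1, _ = run_copied_cohort(seed=5)
        r2, _ = run_copied_cohort(seed=5)
        pd.testing.assert_frame_equal(r1.assignments, r2.assignments)
        pd.testing.assert_frame_equal(r1.probability_history, r2.probability_history)
        pd.testing.assert_frame_equal(r1.importance_history, r2.importance_history)

    def test_termination_bound(self):
        res, _ = run_copied_cohort(seed=6)
        n_patients = len(res.assignments)
        assert res.estimator.n_rounds_ <= int(np.ceil(n_patients / 10)) + 1

    def test_empty_patients_rejected(self):
        cells = pd.DataFrame(np.zeros((4, 2)))
        labels = pd.Series(["A", "A", "B", "B"], index=cells.index)
        with pytest.raises(ValueError):
            run_transfer(cells, labels, cells.iloc[:0])

    def test_nonfinite_features_rejected(self):
        cells = pd.DataFrame([[0.0], [0.0], [1.0], [np.inf]])
        labels = pd.Series(["A", "A", "B", "B"], index=cells.index)
        patients = pd.DataFrame([[0.5]], index=["p0"])
        with pytest.raises(ValueError):
            run_transfer(cells, labels, patients)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            run_copied_cohort(prob_high=0.4, prob_low=0.6)

    def test_missing_values_imputed(self):
        res, labels = run_copied_cohort(seed=7)
        rng = np.random.default_rng(7)
        Xc = np.vstack([rng.normal(0, 0.3, (8, 5)), rng.normal(2, 0.3, (8, 5))])
        cells = pd.DataFrame(Xc, index=[f"c{i:02d}" for i in range(16)])
        lab = pd.Series(["A"] * 8 + ["B"] * 8, index=cells.index)
        patients = cells.copy()
        patients.index = [f"p{i:02d}" for i in range(16)]
        patients.iloc[0, 0] = np.nan  # a hole the median imputation must fill
        res = run_transfer(cells, lab, patients, n_estimators=100, random_state=7)
        assert (res.assignments["assignment"] != "unclassified").all()


class TestImportanceTrajectory:
    def test_shape_row_sums_and_overlap(self):
        res, _ = run_copied_cohort(seed=8)
        hist = res.importance_history
        assert np.allclose(hist.sum(axis=1), 1.0, atol=1e-9)
        traj = importance_trajectory(hist, top_k=3)
        assert len(traj["table"]) == hist.shape[0] * hist.shape[1]
        assert 0 <= traj["overlap"] <= 3

    def test_zero_shift_keeps_top_features(self):
        """Without domain shift the informative features stay on top:
        large first/last top-10 overlap across seeds."""
        overlaps = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n_feat = 15
            Xc = np.vstack([rng.normal(0, 0.5, (8, n_feat)), rng.normal(0, 0.5, (8, n_feat))])
            Xc[8:, :5] += 3.0  # five informative features
            cells = pd.DataFrame(Xc, index=[f"c{i:02d}" for i in range(16)])
            lab = pd.Series(["A"] * 8 + ["B"] * 8, index=cells.index)
            Xp = np.vstack([rng.normal(0, 0.5, (10, n_feat)), rng.normal(0, 0.5, (10, n_feat))])
            Xp[10:, :5] += 3.0
            patients = pd.DataFrame(Xp, index=[f"p{i:02d}" for i in range(20)])
            res = run_transfer(cells, lab, patients, n_estimators=150, random_state=seed)
            if res.estimator.n_rounds_ < 2:
                continue
            traj = importance_trajectory(res.importance_history, top_k=5)
            overlaps.append(traj["overlap"])
        assert np.mean(overlaps) >= 4.0
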