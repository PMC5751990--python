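"""Balanced-subset SVM protocol: subsets, grid, SFS, consensus, LOO."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from qusrm.classify import (DEFAULT_C_GRID, DEFAULT_GAMMA_GRID,
                            ClassifierConfig, SelectionResult,
                            balanced_subsets, consensus_features,
                            grid_search_svm, loo_accuracy, loo_evaluate,
                            run_response_classification, sfs_select)

SMALL_CONFIG = ClassifierConfig(
    c_grid=tuple(2.0 ** np.array([8.0, 12.0, 15.0])),
    gamma_grid=tuple(2.0 ** np.array([-18.0, -10.0, -5.0])),
    n_subsets=5, n_selected=3, seed=0)


def blobs(n_per_class=10, n_features=2, sep=6.0, seed=0, classes=("A", "B", "C")):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, c in enumerate(classes):
        X.append(rng.standard_normal((n_per_class, n_features))
                 + sep * k)
        y += [c] * n_per_class
    return pd.DataFrame(np.vstack(X),
                        columns=[f"f{i}" for i in range(n_features)]), np.array(y)


class TestBalancedSubsets:
    def test_imbalanced_cohort_balances_to_minimum(self):
        labels = np.array(["CR"] * 21 + ["PR"] * 52 + ["NR"] * 23)
        plan = balanced_subsets(labels, 10, seed=1)
        assert len(plan.subsets) == 10
        for idx in plan.subsets:
            assert len(idx) == 63
            counts = Counter(labels[idx])
            assert counts == {"CR": 21, "PR": 21, "NR": 21}
            assert len(set(idx)) == 63  # without replacement

    def test_already_balanced_uses_full_set(self):
        labels = np.array(["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        plan = balanced_subsets(labels, 4, seed=0)
        for idx in plan.subsets:
            assert sorted(idx) == list(range(15))

    def test_deterministic_under_seed(self):
        labels = np.array(["A"] * 8 + ["B"] * 4)
        a = balanced_subsets(labels, 6, seed=9)
        b = balanced_subsets(labels, 6, seed=9)
        for ia, ib in zip(a.subsets, b.subsets):
            assert np.array_equal(ia, ib)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            balanced_subsets(np.array(["A"] * 5), 3, seed=0)


class TestGridSearch:
    def test_default_grid_cardinality(self):
        assert len(DEFAULT_C_GRID) == 8        # 2^8 .. 2^15
        assert len(DEFAULT_GAMMA_GRID) == 14   # 2^-18 .. 2^-5
        assert DEFAULT_C_GRID[0] == 2 ** 8 and DEFAULT_C_GRID[-1] == 2 ** 15
        assert DEFAULT_GAMMA_GRID[0] == 2 ** -18
        assert DEFAULT_GAMMA_GRID[-1] == 2 ** -5

    def test_separable_data_reaches_perfect_loo(self):
        X, y = blobs(n_per_class=8, sep=8.0)
        C, gamma = grid_search_svm(X, y, SMALL_CONFIG)
        assert loo_accuracy(X.to_numpy(), y, C, gamma) == 1.0

    def test_single_class_rejected(self):
        X, y = blobs(classes=("A",))
        with pytest.raises(ValueError, match="two classes"):
            grid_search_svm(X, y, SMALL_CONFIG)


class TestSfs:
    def test_planted_feature_chosen_first(self):
        # one perfectly separating feature among 9 noise features
        rng = np.random.default_rng(4)
        first_hits = 0
        for rep in range(10):
            n = 12
            y = np.array(["A"] * n + ["B"] * n + ["C"] * n)
            X = pd.DataFrame(
                rng.standard_normal((3 * n, 10)),
                columns=[f"f{i}" for i in range(10)])
            X["f3"] = np.repeat([0.0, 8.0, 16.0], n) + \
                rng.standard_normal(3 * n) * 0.3
            sel = sfs_select(X, y, SMALL_CONFIG, C=2 ** 10, gamma=2 ** -8)
            first_hits += int(sel[0] == "f3")
        assert first_hits >= 9

    def test_selects_requested_count(self):
        X, y = blobs(n_per_class=6, n_features=8)
        cfg = ClassifierConfig(c_grid=(1024.0,), gamma_grid=(2 ** -10,),
                               n_selected=6)
        sel = sfs_select(X, y, cfg, C=1024.0, gamma=2 ** -10)
        assert len(sel) == 6
        assert len(set(sel)) == 6

    def test_duplicate_informative_feature_not_forced_in(self):
        rng = np.random.default_rng(7)
        n = 10
        y = np.array(["A"] * n + ["B"] * n)
        info = np.repeat([0.0, 6.0], n) + rng.standard_normal(2 * n) * 0.2
        X = pd.DataFrame({"dup1": info,
                          "n1": rng.standard_normal(2 * n),
                          "n2": rng.standard_normal(2 * n),
                          "dup2": info.copy()})
        cfg = ClassifierConfig(c_grid=(1024.0,), gamma_grid=(2 ** -10,),
                               n_selected=2)
        sel = sfs_select(X, y, cfg, C=1024.0, gamma=2 ** -10)
        # exactly one of the duplicates enters first; the other adds nothing
        assert sel[0] in ("dup1", "dup2")
        assert not set(sel) >= {"dup1", "dup2"}

    def test_fewer_candidates_than_target_warns_and_selects_all(self):
        X, y = blobs(n_per_class=6, n_features=2)
        cfg = ClassifierConfig(c_grid=(1024.0,), gamma_grid=(2 ** -10,),
                               n_selected=6)
        with pytest.warns(UserWarning, match="selecting all"):
            sel = sfs_select(X, y, cfg, C=1024.0, gamma=2 ** -10)
        assert sorted(sel) == ["f0", "f1"]


class TestConsensus:
    ORDER = ("HER2", "dSI", "dAAC-ENE", "ER", "dMBF", "SAS-CON0",
             "x1", "x2", "x3")

    def test_reported_histogram_recovers_top_six(self):
        hist = Counter({"HER2": 8, "dSI": 7, "dAAC-ENE": 7, "ER": 7,
                        "dMBF": 5, "SAS-CON0": 4, "x1": 3, "x2": 2, "x3": 1})
        sel = SelectionResult([], hist, self.ORDER)
        top = consensus_features(sel, 6)
        assert set(top) == {"HER2", "dSI", "dAAC-ENE", "ER", "dMBF",
                            "SAS-CON0"}
        assert top[0] == "HER2"

    def test_all_tied_falls_back_to_fixed_order(self):
        hist = Counter({n: 2 for n in self.ORDER})
        sel = SelectionResult([], hist, self.ORDER)
        with pytest.warns(UserWarning, match="tie"):
            top = consensus_features(sel, 4)
        assert top == list(self.ORDER[:4])

    def test_k_exceeding_distinct_features_warns(self):
        hist = Counter({"a": 2, "b": 1})
        sel = SelectionResult([], hist, ("a", "b"))
        with pytest.warns(UserWarning, match="exceeds"):
            top = consensus_features(sel, 5)
        assert top == ["a", "b"]

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            consensus_features(SelectionResult([], Counter(), ()), 3)


class TestLooEvaluate:
    def test_fold_count_is_sample_count(self):
        X, y = blobs(n_per_class=5)
        m = loo_evaluate(X, y, list(X.columns), C=1024.0, gamma=2 ** -8)
        assert m.confusion.to_numpy().sum() == 15

    def test_separable_blobs_perfect(self):
        X, y = blobs(n_per_class=8, sep=10.0)
        m = loo_evaluate(X, y, list(X.columns), C=1024.0, gamma=2 ** -8)
        assert m.accuracy == 100.0
        assert all(v == 100.0 for v in m.sensitivity.values())
        assert all(v == 100.0 for v in m.specificity.values())

    def test_confusion_rows_sum_to_class_sizes(self):
        X, y = blobs(n_per_class=7, sep=1.0)
        m = loo_evaluate(X, y, list(X.columns), C=2 ** 8, gamma=2 ** -12)
        for c in ("A", "B", "C"):
            assert m.confusion.loc[c].sum() == 7

    def test_permutation_null_near_chance(self):
        # balanced 3 classes: permuted labels give ~33% LOO accuracy
        rng = np.random.default_rng(11)
        X, y = blobs(n_per_class=10, sep=5.0, seed=2)
        accs = []
        for _ in range(30):
            perm = rng.permutation(y)
            accs.append(loo_accuracy(X.to_numpy(), perm, 2 ** 10, 2 ** -5))
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 1 / 3) < max(3 * se, 0.06)


class TestProtocol:
    def _cohort(self, seed=0, n=(10, 12, 10), effect=2.5):
        rng = np.random.default_rng(seed)
        labels = np.repeat(["CR", "PR", "NR"], n)
        total = sum(n)
        X = pd.DataFrame(rng.standard_normal((total, 8)),
                         columns=[f"f{i}" for i in range(8)])
        shift = np.repeat([2 * effect, effect, 0.0], n)
        X["f1"] += shift
        X["f5"] += -shift
        df = X.copy()
        df.insert(0, "label", labels)
        return df

    def test_protocol_recovers_planted_features(self):
        cfg = ClassifierConfig(
            c_grid=(2 ** 8, 2 ** 12), gamma_grid=(2 ** -14, 2 ** -8),
            n_subsets=5, n_selected=3, seed=1)
        res = run_response_classification(self._cohort(seed=3), cfg)
        top3 = consensus_features(res["selection"], 3)
        assert len(set(top3) & {"f1", "f5"}) >= 2

    def test_deterministic_under_seed(self):
        cfg = ClassifierConfig(c_grid=(2 ** 10,), gamma_grid=(2 ** -10,),
                               n_subsets=3, n_selected=2, seed=5)
        a = run_response_classification(self._cohort(), cfg)
        b = run_response_classification(self._cohort(), cfg)
        assert a["mean_accuracy"] == b["mean_accuracy"]
        assert a["selection"].per_subset == b["selection"].per_subset

    def test_binary_task_merges_responders(self):
        cfg = ClassifierConfig(c_grid=(2 ** 10,), gamma_grid=(2 ** -10,),
                               n_subsets=2, n_selected=2, seed=0,
                               task="responder_vs_nonresponder")
        res = run_response_classification(self._cohort(), cfg)
        classes = res["subset_plan"].classes
        assert set(classes) == {"R", "NR"}
        # balanced at the NR size (10): subsets of 20
        assert all(len(idx) == 20 for idx in res["subset_plan"].subsets)

    def test_histogram_total_is_subsets_times_selected(self):
        cfg = ClassifierConfig(c_grid=(2 ** 10,), gamma_grid=(2 ** -10,),
                               n_subsets=4, n_selected=3, seed=2)
        res = run_response_classification(self._cohort(), cfg)
        assert res["selection"].total == 12


class TestSfsGreedyOptimality:
    def test_each_step_maximizes_the_criterion(self):
        # every selected feature attains the best LOO accuracy among the
        # remaining candidates given the already-selected set (the greedy
        # guarantee; the accuracy sequence itself may dip when a forced
        # extra feature only adds noise)
        rng = np.random.default_rng(13)
        n = 8
        y = np.array(["A"] * n + ["B"] * n + ["C"] * n)
        X = pd.DataFrame(rng.standard_normal((3 * n, 6)),
                         columns=[f"f{i}" for i in range(6)])
        X["f2"] += np.repeat([0, 3, 6], n)
        C, gamma = 2 ** 10, 2 ** -8
        cfg = ClassifierConfig(c_grid=(C,), gamma_grid=(gamma,), n_selected=4)
        sel = sfs_select(X, y, cfg, C=C, gamma=gamma)
        Xa = X.to_numpy()
        ci = {c: i for i, c in enumerate(X.columns)}
        for step in range(len(sel)):
            chosen = [ci[s] for s in sel[:step]]
            acc_chosen = loo_accuracy(Xa[:, chosen + [ci[sel[step]]]], y,
                                      C, gamma)
            for c in X.columns:
                if c in sel[:step + 1]:
                    continue
                acc_other = loo_accuracy(Xa[:, chosen + [ci[c]]], y, C, gamma)
                assert acc_chosen >= acc_other - 1e-12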