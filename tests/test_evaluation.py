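"""Metric formulas, cross-validation reporting, ranking protocols."""

import numpy as np
import pytest

from lncdap.evaluation import (
    RankedPredictions,
    all_metrics,
    confusion_metrics,
    cross_validate,
    leave_disease_out,
    ranking_metrics,
    select_best_model,
    view_ablation,
)

from oracles import allpairs_auc, step_aupr


def vectors_from_counts(tp, tn, fp, fn):
    y = np.r_[np.ones(tp), np.ones(fn), np.zeros(tn), np.zeros(fp)].astype(int)
    p = np.r_[np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)].astype(int)
    return y, p


class TestConfusionMetrics:
    def test_hand_values(self):
        y, p = vectors_from_counts(5, 5, 0, 0)
        cm = confusion_metrics(y, p)
        assert (cm.ACC, cm.MCC, cm.F1) == (1.0, 1.0, 1.0)
        y, p = vectors_from_counts(1, 1, 1, 1)
        cm = confusion_metrics(y, p)
        assert cm.ACC == 0.5 and cm.MCC == 0.0 and cm.F1 == 0.5

    def test_mcc_zero_denominator_convention(self):
        y, p = vectors_from_counts(4, 0, 0, 0)  # all positive, all predicted positive
        assert confusion_metrics(y, p).MCC == 0.0

    def test_enumeration_against_vector_level_oracle(self):
        """Every confusion table with cells <= 6 against metrics computed
        directly from the label vectors (correlation for MCC, conditional
        means for precision/recall)."""
        for tp in range(7):
            for tn in range(7):
                for fp in range(7):
                    for fn in range(7):
                        if tp + tn + fp + fn == 0:
                            continue
                        y, p = vectors_from_counts(tp, tn, fp, fn)
                        cm = confusion_metrics(y, p)
                        assert cm.ACC == pytest.approx((y == p).mean())
                        expect_prec = y[p == 1].mean() if (p == 1).any() else 0.0
                        expect_rec = p[y == 1].mean() if (y == 1).any() else 0.0
                        assert cm.precision == pytest.approx(expect_prec)
                        assert cm.recall == pytest.approx(expect_rec)
                        if np.std(y) > 0 and np.std(p) > 0:
                            assert cm.MCC == pytest.approx(np.corrcoef(y, p)[0, 1])
                        if tp + 0.5 * (fp + fn) > 0:
                            assert cm.F1 == pytest.approx(tp / (tp + 0.5 * (fp + fn)))

    def test_spot_check_against_sklearn(self, rng):
        from sklearn.metrics import f1_score, matthews_corrcoef
        for _ in range(50):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            if y.sum() in (0, 30):
                continue
            cm = confusion_metrics(y, p)
            assert cm.MCC == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)
            assert cm.F1 == pytest.approx(f1_score(y, p, zero_division=0), abs=1e-12)

    def test_empty_and_mismatched_inputs(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])


class TestRankingMetrics:
    def test_perfect_and_reversed(self):
        y = np.array([1, 1, 0, 0])
        auc, aupr = ranking_metrics(y, [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0 and aupr == 1.0
        auc, _ = ranking_metrics(y, [0.1, 0.2, 0.8, 0.9])
        assert auc == 0.0

    def test_hand_value_from_pair_counting(self):
        auc, _ = ranking_metrics([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3])
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_allpairs_and_step_oracles(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=50)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        s = np.round(rng.random(50), 1)  # coarse scores force ties
        auc, aupr = ranking_metrics(y, s)
        assert auc == pytest.approx(allpairs_auc(y, s), abs=1e-10)
        assert aupr == pytest.approx(step_aupr(y, s), abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.random(40)
        auc1, _ = ranking_metrics(y, s)
        auc2, _ = ranking_metrics(y, np.exp(5 * s) + 7)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ranking_metrics([1, 1, 1], [0.1, 0.2, 0.3])


class _ConstantModel:
    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.full((len(X), 2), 0.5)


class TestCrossValidate:
    def _data(self, rng, n=100):
        X = np.vstack([rng.normal(1, 1, (n // 2, 4)), rng.normal(-1, 1, (n // 2, 4))])
        y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
        return X, y

    def test_constant_model_degenerate_report(self, rng):
        X, y = self._data(rng)
        rep = cross_validate(X, y, _ConstantModel, seed=0)
        assert rep.mean["ACC"] == pytest.approx(0.5)
        assert rep.mean["AUC"] == pytest.approx(0.5)   # midrank convention on ties
        # all folds identical -> population variance exactly 0
        assert all(v == 0.0 for v in rep.variance.values())

    def test_report_structure_and_determinism(self, rng):
        from sklearn.linear_model import LogisticRegression
        X, y = self._data(rng)
        factory = lambda: LogisticRegression(max_iter=200)
        a = cross_validate(X, y, factory, seed=4)
        b = cross_validate(X, y, factory, seed=4)
        assert a.per_fold == b.per_fold and a.mean == b.mean
        for m in ("ACC", "MCC", "F1", "precision", "recall", "AUC", "AUPR"):
            assert len(a.per_fold[m]) == 5
            assert a.variance[m] >= 0
            assert a.mean[m] == pytest.approx(np.mean(a.per_fold[m]))
            assert a.variance[m] == pytest.approx(np.var(a.per_fold[m]))


class TestRankedPredictions:
    def test_rejects_non_monotone_scores(self):
        with pytest.raises(ValueError):
            RankedPredictions("d", ["a", "b"], [0.2, 0.9])


class TestLeaveDiseaseOut:
    def test_excludes_target_pairs_and_ranks_hidden_partners(self, bundle,
                                                             pipeline_result):
        res = pipeline_result
        A = bundle.A_observed
        # a disease with hidden positives and observed associations
        per_disease = {}
        for d, l in bundle.hidden_pairs:
            per_disease.setdefault(d, []).append(l)
        target = max(per_disease, key=lambda d: len(per_disease[d]))
        disease_id = A.disease_ids[target]
        ranked, dataset = leave_disease_out(
            disease_id, A, res.F_disease, res.F_lncrna,
            res.denoising.reliable_indices, res.samples, seed=0,
            enabled=("xgboost", "lightgbm"), return_details=True)
        assert len(ranked.lncrna_ids) == min(30, A.n_lncrnas)
        # leakage check: no training pair involves the target disease
        train_idx = np.concatenate([dataset.pool_indices, dataset.holdout_indices])
        assert not (res.samples.disease_idx[train_idx] == target).any()
        top = set(ranked.lncrna_ids)
        hidden_ids = {A.lncrna_ids[l] for l in per_disease[target]}
        assert len(top & hidden_ids) >= len(hidden_ids) / 2

    def test_unknown_or_empty_disease_rejected(self, bundle, pipeline_result):
        from lncdap.datatypes import IdentifierError
        res = pipeline_result
        with pytest.raises(IdentifierError):
            leave_disease_out("nope", bundle.A_observed, res.F_disease, res.F_lncrna,
                              res.denoising.reliable_indices, res.samples)


class TestViewAblation:
    def test_validates_subsets(self):
        with pytest.raises(ValueError):
            view_ablation(lambda v: {"AUC": 1, "AUPR": 1}, [()])
        with pytest.raises(ValueError, match="disease view"):
            view_ablation(lambda v: {"AUC": 1, "AUPR": 1}, [("LGS", "LFS")])

    def test_table_rows_and_seeded_repeatability(self, small_bundle):
        from lncdap.pipeline import PipelineConfig, run_pipeline_core

        def run_subset(views):
            cfg = PipelineConfig(views=views, seed=3, epochs=30,
                                 k_range=(2, 4), base_learners=("xgboost", "lightgbm"))
            r = run_pipeline_core(small_bundle.A_observed, small_bundle.dag,
                                  small_bundle.sequences, cfg)
            return r.heldout_metrics

        rows = view_ablation(run_subset, [("DGS", "LGS"), ("DGS", "LGS")])
        assert rows[0]["views"] == "DGS+LGS"
        assert rows[0]["AUC"] == rows[1]["AUC"]
        assert rows[0]["AUPR"] == rows[1]["AUPR"]


class TestModelSelection:
    def test_winner_comes_from_table(self, pipeline_result):
        winner, table = pipeline_result.best_model_name, pipeline_result.model_selection_table
        assert winner in table
        assert set(table["stacking"]) == {"AUC", "AUPR"}
        best_auc = max(v["AUC"] for v in table.values())
        assert table[winner]["AUC"] == best_auc
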