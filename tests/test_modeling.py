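"""Split, metrics, ROC/AUC, DeLong, DCA, SVM training, and orchestration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from shellrad import (
    HCConfig,
    NineModelConfig,
    confusion_from_scores,
    dca_curve,
    delong_test,
    make_split,
    metrics_from_confusion,
    roc_auc,
    run_nine_models,
    select_cutoff,
    train_svm,
)
from shellrad.modeling import ConfusionMatrix, _round2


def _labels(n_pos: int, n_neg: int) -> pd.Series:
    ids = [f"r{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    return pd.Series([1] * n_pos + [0] * n_neg, index=ids)


class TestSplit:
    def test_326_at_one_fifth_gives_35_30(self):
        """Largest-remainder apportionment of a 175/151 cohort at 0.2."""
        sp = make_split(_labels(175, 151), ratio=0.2, seed=0)
        assert len(sp.test_ids) == 65
        n_pos_test = sum(i.startswith("r") for i in sp.test_ids)
        assert n_pos_test == 35
        assert len(sp.test_ids) - n_pos_test == 30
        assert len(sp.train_ids) == 261

    def test_partition_and_determinism(self):
        y = _labels(20, 15)
        a = make_split(y, 0.2, seed=5)
        b = make_split(y, 0.2, seed=5)
        c = make_split(y, 0.2, seed=6)
        assert sorted(a.train_ids + a.test_ids) == sorted(y.index)
        assert not set(a.train_ids) & set(a.test_ids)
        assert (a.train_ids, a.test_ids) == (b.train_ids, b.test_ids)
        assert a.test_ids != c.test_ids

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="ratio"):
            make_split(_labels(20, 20), ratio=0.0)
        with pytest.raises(ValueError, match="10 subjects"):
            make_split(_labels(5, 20), ratio=0.2)


class TestMetrics:
    def test_counts_match_explicit_loop(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        cm = confusion_from_scores(s, y, 0.5)
        tp = sum(1 for si, yi in zip(s, y) if si >= 0.5 and yi == 1)
        fp = sum(1 for si, yi in zip(s, y) if si >= 0.5 and yi == 0)
        assert (cm.tp, cm.fp) == (tp, fp)
        assert cm.total == 50
        rep = metrics_from_confusion(cm)
        assert rep.accuracy == pytest.approx((cm.tp + cm.tn) / 50)
        assert rep.sensitivity == pytest.approx(cm.tp / (cm.tp + cm.fn))
        assert rep.specificity == pytest.approx(cm.tn / (cm.tn + cm.fp))

    def test_no_predicted_positives_warns(self):
        cm = ConfusionMatrix(tp=0, fn=5, tn=5, fp=0)
        with pytest.warns(UserWarning, match="precision"):
            rep = metrics_from_confusion(cm)
        assert rep.precision == 0.0 and rep.f1 == 0.0

    def test_rounding_is_half_up(self):
        assert _round2(0.125) == 0.13
        assert _round2(0.845) == 0.85
        assert _round2(0.8449) == 0.84


def _brute_force_auc(s: np.ndarray, y: np.ndarray) -> float:
    """Pairwise win fraction with half-credit ties."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_auc_matches_pairwise_count(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            n = 12
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            s = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            rep = roc_auc(s, y)
            assert rep.auc == pytest.approx(_brute_force_auc(s, y))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        a = roc_auc(s, y)
        b = roc_auc(np.exp(s), y)
        assert a.auc == pytest.approx(b.auc)
        assert a.ci95 == pytest.approx(b.ci95)

    def test_perfect_and_reversed(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc([0.1, 0.2, 0.8, 0.9], y).auc == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], y).auc == 0.0

    def test_ci_contains_auc_and_is_clipped(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        rep = roc_auc([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], y)
        lo, hi = rep.ci95
        assert 0.0 <= lo <= rep.auc <= hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_roc_curve_endpoints(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 10)
        rep = roc_auc(rng.uniform(size=20), y)
        assert rep.tpr[0] == 1.0 and rep.fpr[0] == 1.0  # lowest threshold
        assert rep.tpr[-1] == 0.0 and rep.fpr[-1] == 0.0  # highest threshold


class TestCutoff:
    def test_maximizes_youden_by_enumeration(self):
        rng = np.random.default_rng(4)
        s = np.round(rng.uniform(size=30), 1)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        rep = roc_auc(s, y)
        cut = select_cutoff(rep)
        yn = np.asarray(y)

        def j(c: float) -> float:
            cm = confusion_from_scores(s, yn, c)
            return cm.tp / (cm.tp + cm.fn) - cm.fp / (cm.fp + cm.tn)

        best = max(j(c) for c in rep.thresholds)
        assert j(cut) == pytest.approx(best)
        # ties break toward the lowest threshold
        for c in rep.thresholds:
            if j(c) == pytest.approx(best):
                assert cut <= c
                break


class TestDelong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 10)
        s = rng.uniform(size=20)
        res = delong_test(s, s, y)
        assert res.p == 1.0 and res.z == 0.0

    def test_monotone_transform_gives_p_one(self):
        rng = np.random.default_rng(6)
        y = np.array([0, 1] * 10)
        s = rng.normal(size=20)
        res = delong_test(s, 1.0 / (1.0 + np.exp(-s)), y)
        assert res.p == 1.0
        assert res.auc_a == pytest.approx(res.auc_b)

    def test_variance_halves_on_duplicated_cohort(self):
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 12)
        a = rng.uniform(size=24)
        b = rng.uniform(size=24)
        r1 = delong_test(a, b, y)
        r2 = delong_test(np.tile(a, 2), np.tile(b, 2), np.tile(y, 2))
        assert r2.auc_a == pytest.approx(r1.auc_a)
        # doubling every subject doubles m and n with (nearly) unchanged
        # component variances, so S shrinks by about half
        assert r2.var_a == pytest.approx(r1.var_a / 2, rel=0.1)

    def test_opposite_perfect_scores_significant(self):
        y = np.array([0] * 10 + [1] * 10)
        s = np.linspace(0, 1, 20)
        res = delong_test(s, 1.0 - s, y)
        assert res.auc_a == 1.0 and res.auc_b == 0.0
        assert res.p < 0.05


class TestDCA:
    def test_perfect_predictor_net_benefit_is_prevalence(self):
        y = np.array([0] * 6 + [1] * 4)
        curve = dca_curve(y.astype(float), y)
        assert curve.prevalence == pytest.approx(0.4)
        assert np.allclose(curve.net_benefit, 0.4)

    def test_treat_all_closed_form(self):
        rng = np.random.default_rng(8)
        y = np.array([0, 1] * 10)
        curve = dca_curve(rng.uniform(size=20), y)
        pi = curve.prevalence
        expected = pi - (1 - pi) * curve.thresholds / (1 - curve.thresholds)
        assert np.allclose(curve.treat_all, expected)
        assert np.all(curve.treat_none == 0.0)

    def test_net_benefit_never_exceeds_prevalence(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=40)
        curve = dca_curve(rng.uniform(size=40), y)
        assert np.all(curve.net_benefit <= curve.prevalence + 1e-12)

    def test_grid_bounds_enforced(self):
        with pytest.raises(ValueError):
            dca_curve([0.5], [1], grid=np.array([0.0, 0.5]))


class TestTrainSVM:
    def _separable(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        n = 40
        y = np.array([0, 1] * (n // 2))
        x = rng.normal(size=(n, 3))
        x[:, 0] += y * 6.0
        return pd.DataFrame(x, columns=["a", "b", "c"]), y

    def test_separable_data_learned(self):
        x, y = self._separable()
        tm = train_svm(x, y, folds=5, seed=0)
        assert tm.cv_auc > 0.95
        pred = tm.model.predict(x.to_numpy())
        assert np.mean(pred == y) == 1.0
        scores = tm.predict_scores(x)
        assert scores.shape == (40,)
        assert np.all((0 <= scores) & (scores <= 1))

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(60, 4)))
        y = np.array([0, 1] * 30)
        tm = train_svm(x, y, folds=5, seed=0)
        assert 0.2 < tm.cv_auc < 0.8

    def test_determinism(self):
        x, y = self._separable(2)
        a = train_svm(x, y, folds=5, seed=3)
        b = train_svm(x, y, folds=5, seed=3)
        assert np.array_equal(a.cv_scores, b.cv_scores)
        assert a.cv_auc == b.cv_auc

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            train_svm(pd.DataFrame(index=range(4)), [0, 1, 0, 1])
        x = pd.DataFrame(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="both classes"):
            train_svm(x, [1, 1, 1, 0])


def test_run_nine_models_shell_subset(tiny_cohort):
    cfg = NineModelConfig(hc_config=HCConfig.reduced(), seed=0)
    res = run_nine_models(tiny_cohort, cfg, strategies=("shell_3_6", "shell_9_12"))
    assert set(res.reports) == {"shell_3_6", "shell_9_12"}
    assert len(res.split.test_ids) == round(24 * 0.2)
    p = res.delong_p
    assert np.allclose(p.to_numpy(), p.to_numpy().T)
    assert np.all(np.diag(p.to_numpy()) == 1.0)
    for rep in res.reports.values():
        d = rep.to_dict()
        assert 0.0 <= d["test_auc"] <= 1.0
        assert d["n_selected"] >= 1
        assert sum(d["confusion"].values()) == len(res.split.test_ids)
    # the planted signal lives in the 9-12 mm band
    assert res.reports["shell_9_12"].cv_auc > res.reports["shell_3_6"].cv_auc

    with pytest.raises(ValueError, match="unknown"):
        run_nine_models(tiny_cohort, cfg, strategies=("bogus",))
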