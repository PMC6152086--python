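"""Classification metrics, ROC/AUC, cross-validation orchestration."""

import io

import numpy as np
import pandas as pd
import pytest

import ppilm as P
from ppilm.evaluation import METRIC_COLUMNS
from conftest import make_blobs, BLOB_THETA


class TestConfusion:
    def test_all_correct_positive(self):
        y = np.ones(5, dtype=int)
        c = P.confusion(y, y)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 0, 0)

    def test_all_wrong(self):
        y = np.array([1, 1, -1, -1])
        c = P.confusion(y, -y)
        assert (c.tp, c.tn) == (0, 0)
        assert (c.fp, c.fn) == (2, 2)

    def test_hand_enumerated_case(self):
        c = P.confusion([1, 1, -1, -1], [1, -1, 1, -1])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            P.confusion([1, -1], [1])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.choice([-1, 1], size=50)
        p = rng.choice([-1, 1], size=50)
        perm = rng.permutation(50)
        a = P.metrics(P.confusion(y, p))
        b = P.metrics(P.confusion(y[perm], p[perm]))
        assert a == b


class TestMetrics:
    def test_perfect_classifier(self):
        m = P.metrics(P.confusion([1, 1, -1, -1], [1, 1, -1, -1]))
        assert m == {"acc": 1.0, "sn": 1.0, "pe": 1.0, "mcc": 1.0}

    def test_hand_computed_case(self):
        # TP=3, FP=1, TN=4, FN=2 -> Acc 0.7, Sn 0.6, Pe 0.75,
        # MCC = (12-2)/sqrt(5*5*4*6)
        m = P.metrics(P.ConfusionSummary(tp=3, fp=1, tn=4, fn=2))
        assert m["acc"] == pytest.approx(0.7)
        assert m["sn"] == pytest.approx(0.6)
        assert m["pe"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx(10 / np.sqrt(600))
        assert m["mcc"] == pytest.approx(0.4082, abs=5e-5)

    def test_random_predictions_have_near_zero_mcc(self):
        rng = np.random.default_rng(1)
        n = 10_000
        y = rng.choice([-1, 1], size=n)
        p = rng.choice([-1, 1], size=n)
        m = P.metrics(P.confusion(y, p))
        assert abs(m["mcc"]) < 0.05

    def test_undefined_metric_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = P.metrics(P.ConfusionSummary(tp=0, fp=0, tn=4, fn=0))
        assert np.isnan(m["sn"]) and np.isnan(m["pe"])
        assert m["acc"] == 1.0


def auc_paircount_oracle(y, s):
    """Exhaustive Mann-Whitney count: P(s+ > s-) + P(s+ = s-)/2."""
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == -1]
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        y = np.array([-1, -1, 1, 1])
        auc, fpr, tpr = P.roc_auc(y, [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_anti_ordered_scores(self):
        auc, _, _ = P.roc_auc([-1, -1, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 0.0

    @pytest.mark.parametrize("n,seed", [(20, 0), (100, 1), (200, 2)])
    def test_matches_paircount_oracle_exactly(self, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.choice([-1, 1], size=n)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        # coarse scores force ties to exercise midrank handling
        s = rng.integers(0, 5, size=n).astype(float)
        auc, _, _ = P.roc_auc(y, s)
        assert auc == pytest.approx(auc_paircount_oracle(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            P.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


@pytest.fixture(scope="module")
def small_cv_report(small_synthetic):
    _, pssms, pairs, _ = small_synthetic
    config = P.PipelineConfig(n_components=40, svm_baseline=True)
    return P.kfold_cv(pairs, pssms, config, k=3, seed=0)


@pytest.fixture(scope="module")
def medium_cv_report(medium_synthetic):
    _, pssms, pairs, _ = medium_synthetic
    return P.kfold_cv(pairs, pssms, P.PipelineConfig(), k=3, seed=0)


class TestKfoldCV:
    def test_separable_synthetic_pairs_recovered(self, medium_cv_report):
        assert medium_cv_report.mean["acc"] >= 0.9

    def test_fold_partition_is_exact(self, small_synthetic):
        from sklearn.model_selection import StratifiedKFold

        _, _, pairs, _ = small_synthetic
        y = np.array([lab for _, _, lab in pairs])
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        seen = np.concatenate([te for _, te in skf.split(np.zeros(len(y)), y)])
        assert sorted(seen) == list(range(len(pairs)))

    def test_same_seed_identical_report(self, small_synthetic, small_cv_report):
        _, pssms, pairs, _ = small_synthetic
        config = P.PipelineConfig(n_components=40, svm_baseline=True)
        again = P.kfold_cv(pairs, pssms, config, k=3, seed=0)
        pd.testing.assert_frame_equal(again.folds, small_cv_report.folds)

    def test_mean_sd_recomputable_from_folds(self, small_cv_report):
        folds = small_cv_report.folds
        for c in METRIC_COLUMNS:
            assert small_cv_report.mean[c] == pytest.approx(folds[c].mean(), abs=1e-12)
            assert small_cv_report.std[c] == pytest.approx(folds[c].std(ddof=1), abs=1e-12)

    def test_table_layout(self, small_cv_report):
        table = small_cv_report.to_table()
        lines = table.strip().splitlines()
        assert lines[0].startswith("Testing Set\tAcc (%)")
        assert lines[-1].startswith("Average\t")
        assert "±" in lines[-1]
        assert len(lines) == 2 + len(small_cv_report.folds)

    def test_roc_points_and_plot(self, small_cv_report, tmp_path):
        small_cv_report.save_roc_points(tmp_path)
        files = sorted(tmp_path.glob("roc_fold*.tsv"))
        assert len(files) == len(small_cv_report.folds)
        df = pd.read_csv(files[0], sep="\t")
        assert list(df.columns) == ["fpr", "tpr"]
        assert df["fpr"].iloc[-1] == 1.0 and df["tpr"].iloc[-1] == 1.0
        small_cv_report.plot_roc(tmp_path / "roc.png")
        assert (tmp_path / "roc.png").stat().st_size > 0

    def test_svm_baseline_runs_on_identical_features(self, small_cv_report):
        base = small_cv_report.baseline
        assert base is not None
        assert base.params["c"] == 0.02 and base.params["g"] == 0.03
        assert len(base.folds) == len(small_cv_report.folds)


class TestCrossSpecies:
    def test_within_distribution_transfer(self, medium_synthetic, medium_cv_report):
        _, pssms_tr, pairs_tr, _ = medium_synthetic
        cfg_te = P.SynthConfig(n_proteins=240, n_pairs=300, delta=1.0, sigma=0.1,
                               length_range=(30, 60), seed=12)
        pssms_te, pairs_te, _ = P.simulate_dataset(cfg_te)
        row = P.cross_species_eval(pairs_tr, pssms_tr, pairs_te, pssms_te,
                                   P.PipelineConfig())
        assert abs(row["acc"] - medium_cv_report.mean["acc"]) <= 0.05

    def test_empty_test_set_rejected(self, small_synthetic):
        _, pssms, pairs, _ = small_synthetic
        with pytest.raises(ValueError, match="empty"):
            P.cross_species_eval(pairs, pssms, [], pssms, P.PipelineConfig())

    def test_label_shuffled_test_set_scores_at_chance(self):
        cfg = P.SynthConfig(n_proteins=400, n_pairs=500, delta=1.0, sigma=0.1,
                            length_range=(30, 60), seed=13)
        pssms, pairs, _ = P.simulate_dataset(cfg)
        rng = np.random.default_rng(0)
        split = 300
        train, test = pairs[:split], pairs[split:]
        labels = np.array([lab for _, _, lab in test])
        rng.shuffle(labels)
        shuffled = [(a, b, int(l)) for (a, b, _), l in zip(test, labels)]
        config = P.PipelineConfig(n_components=40)
        row = P.cross_species_eval(train, pssms, shuffled, pssms, config)
        assert abs(row["acc"] - 0.5) <= 0.1


class TestSvmBaseline:
    def test_separable_blobs(self):
        rng = np.random.default_rng(3)
        Xtr, ytr = make_blobs(80, rng)
        Xte, yte = make_blobs(100, rng)
        row = P.svm_baseline(Xtr, ytr, Xte, yte)
        assert row["acc"] >= 0.95
        assert row["c"] == 0.02 and row["g"] == 0.03
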