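import numpy as np
import pandas as pd
import pytest

from seedhsi.exceptions import InputError
from seedhsi.hypercube import SpectraTable
from seedhsi.models import (
    ANNConfig,
    SVMConfig,
    ann_fit,
    ann_predict,
    class_indicators,
    evaluate_model,
    kennard_stone_split,
    plsda_cv,
    plsda_fit,
    pls_compress,
    svm_fit,
    svm_predict,
    venetian_blinds,
)
from seedhsi.simulate import Group, SimSpec, make_spectra


def brute_force_kennard_stone(X, n_cal):
    """Naive max-min reference implementation (recomputes everything each step)."""
    X = np.asarray(X, float)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best[0]:
                best = (D[i, j], (i, j))
    selected = list(best[1]) if best[1] else [0, 1]
    while len(selected) < n_cal:
        best_cand, best_dist = None, -1.0
        for cand in range(n):
            if cand in selected:
                continue
            d = min(D[cand, s] for s in selected)
            if d > best_dist:
                best_cand, best_dist = cand, d
        selected.append(best_cand)
    return sorted(selected)


class TestKennardStone:
    def test_line_example(self):
        plan = kennard_stone_split(np.array([[0.0], [1.0], [10.0]]), 2 / 3)
        assert plan.calibration_indices.tolist() == [0, 2]
        assert plan.prediction_indices.tolist() == [1]

    def test_deterministic(self, rng):
        X = rng.random((30, 4))
        a = kennard_stone_split(X, 0.8)
        b = kennard_stone_split(X, 0.8)
        np.testing.assert_array_equal(a.calibration_indices, b.calibration_indices)

    def test_matches_brute_force_30_points(self, rng):
        X = rng.random((30, 2))
        plan = kennard_stone_split(X, 0.8)
        assert plan.calibration_indices.tolist() == brute_force_kennard_stone(X, 24)

    def test_matches_brute_force_small_n_many_draws(self):
        # 50 random datasets with n <= 12
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            X = rng.random((n, int(rng.integers(1, 5))))
            frac = float(rng.uniform(0.3, 0.9))
            n_cal = min(max(int(np.ceil(frac * n)), 2), n - 1)
            plan = kennard_stone_split(X, frac)
            assert plan.calibration_indices.tolist() == brute_force_kennard_stone(X, n_cal)

    def test_duplicate_only_dataset_tie_break(self):
        plan = kennard_stone_split(np.ones((5, 3)), 0.6)
        assert plan.calibration_indices.tolist() == [0, 1, 2]

    def test_sizes_within_one_row_of_fraction(self, rng):
        for n in (10, 57, 200):
            plan = kennard_stone_split(rng.random((n, 3)), 0.95)
            assert abs(len(plan.calibration_indices) - 0.95 * n) <= 1

    def test_partition_property(self, rng):
        X = rng.random((25, 3))
        plan = kennard_stone_split(X, 0.7)
        union = np.sort(np.r_[plan.calibration_indices, plan.prediction_indices])
        np.testing.assert_array_equal(union, np.arange(25))

    def test_bad_fraction(self):
        with pytest.raises(InputError):
            kennard_stone_split(np.zeros((5, 2)), 1.2)


class TestVenetianBlinds:
    def test_20_rows_10_splits(self):
        plan = venetian_blinds(20, 10)
        for f in range(10):
            np.testing.assert_array_equal(
                np.flatnonzero(plan.assignment == f), [f, f + 10]
            )

    def test_leave_one_out_pattern(self):
        plan = venetian_blinds(10, 10)
        assert all((plan.assignment == f).sum() == 1 for f in range(10))

    @pytest.mark.parametrize("n", [7, 23, 100])
    def test_folds_partition(self, n):
        plan = venetian_blinds(n, 10)
        seen = np.concatenate([val for _, val in plan.folds()])
        np.testing.assert_array_equal(np.sort(seen), np.arange(n))
        sizes = [(plan.assignment == f).sum() for f in range(10)]
        assert max(sizes) - min(sizes) <= 1


def separable_table(seed=7, separation=5.0, n=60, n_bands=288):
    """Two Gaussian classes separated by `separation` noise-sd along 20 bands."""
    rng = np.random.default_rng(seed)
    sd = 0.01
    X = rng.normal(scale=sd, size=(n, n_bands))
    y = np.array(["E+"] * (n // 2) + ["E-"] * (n // 2))
    X[: n // 2, 50:70] += separation * sd
    return X, y


class TestPLSDA:
    def test_separable_zero_calibration_error(self):
        X, y = separable_table(seed=7, separation=5.0)
        model = plsda_fit(X, y, n_lv=2)
        assert (model.predict(X) != y).mean() == 0.0

    def test_one_lv_recovers_discriminating_direction(self):
        rng = np.random.default_rng(3)
        t = np.r_[rng.normal(-2, 0.1, 30), rng.normal(2, 0.1, 30)]
        X = np.outer(t, np.ones(10)) + rng.normal(scale=0.01, size=(60, 10))
        y = np.array(["A"] * 30 + ["B"] * 30)
        model = plsda_fit(X, y, n_lv=1)
        scores = model.core_.scores(model.chain.apply(X))[:, 0]
        code = (y == "A").astype(float)
        corr = np.corrcoef(scores, code)[0, 1]
        assert abs(corr) > 0.99

    def test_duplication_invariance(self):
        X, y = separable_table(seed=5, n=40, n_bands=30)
        a = plsda_fit(X, y, n_lv=2)
        b = plsda_fit(np.vstack([X, X]), np.r_[y, y], n_lv=2)
        np.testing.assert_allclose(a.core_.W, b.core_.W, atol=1e-8)
        np.testing.assert_allclose(a.core_.P, b.core_.P, atol=1e-8)

    def test_score_orthogonality(self):
        X, y = separable_table(seed=9, n=50, n_bands=40)
        model = plsda_fit(X, y, n_lv=5)
        T = model.x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            plsda_fit(np.random.default_rng(0).random((5, 4)), ["A"] * 5, 1)

    def test_every_sample_assigned_one_class(self):
        X, y = separable_table(seed=11, separation=0.5)
        model = plsda_fit(X, y, n_lv=3)
        pred = model.predict(X)
        assert set(pred) <= {"E+", "E-"}
        assert len(pred) == len(y)


class TestPLSDACV:
    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(400, 50))
        # shuffled labels: alternating labels would correlate with the blinds
        y = rng.permutation(np.array(["A", "B"] * 200))
        _, table = plsda_cv(X, y, (), [2], venetian_blinds(400))
        assert table["cv_class_error"].iloc[0] == pytest.approx(50.0, abs=8.0)

    def test_separable_selects_small_lv_with_low_error(self):
        X, y = separable_table(seed=7, separation=5.0, n=100)
        n_lv, table = plsda_cv(X, y, (), range(1, 8), venetian_blinds(100))
        assert table["cv_class_error"].min() < 2.0
        assert n_lv <= 3

    def test_invariant_to_label_renaming(self):
        X, y = separable_table(seed=13, separation=1.0, n=60, n_bands=40)
        cv = venetian_blinds(60)
        _, t1 = plsda_cv(X, y, (), [1, 2], cv)
        renamed = np.where(y == "E+", "zebra", "aard")
        _, t2 = plsda_cv(X, renamed, (), [1, 2], cv)
        np.testing.assert_allclose(
            t1["cv_class_error"].to_numpy(), t2["cv_class_error"].to_numpy()
        )

    def test_lv_grid_trimmed_with_warning(self):
        X, y = separable_table(seed=2, n=20, n_bands=10)
        with pytest.warns(UserWarning, match="trimmed"):
            plsda_cv(X, y, (), [1, 2, 50], venetian_blinds(20))


class TestPLSCompression:
    def test_projection_reproduces_calibration_scores(self):
        X, y = separable_table(seed=4, n=40, n_bands=30)
        comp = pls_compress(X, y, 3)
        np.testing.assert_allclose(comp.transform(X), comp.scores_, atol=1e-10)

    def test_full_rank_lossless_reconstruction(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 5))
        y = np.array(["A", "B"] * 6)
        comp = pls_compress(X, y, 5)
        T = comp.scores_
        Xc = X - X.mean(axis=0)
        # project back through the loadings: T P' must rebuild centred X
        recon = T @ comp.core_.P.T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_scores_feed_linear_classifier_consistently(self):
        X, y = separable_table(seed=6, separation=5.0)
        comp = pls_compress(X, y, 2)
        plsda = plsda_fit(X, y, 2)
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression().fit(comp.scores_, y)
        assert (clf.predict(comp.transform(X)) == plsda.predict(X)).mean() == 1.0


class TestSVM:
    def test_separable_large_c(self):
        rng = np.random.default_rng(5)
        scores = np.vstack([rng.normal(-3, 0.2, (20, 2)), rng.normal(3, 0.2, (20, 2))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        model = svm_fit(scores, y, SVMConfig(C=1e6, gamma=0.5))
        assert (svm_predict(model, scores) != y).sum() == 0

    def test_xor_pattern(self):
        scores = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["A", "A", "B", "B"])
        model = svm_fit(scores, y, SVMConfig(C=1e6, gamma=2.0))
        assert (svm_predict(model, scores) == y).all()

    def test_permutation_invariance(self, rng):
        scores = rng.normal(size=(30, 3))
        y = rng.choice(["A", "B"], 30)
        perm = rng.permutation(30)
        m1 = svm_fit(scores, y, SVMConfig())
        m2 = svm_fit(scores[perm], y[perm], SVMConfig())
        probe = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(svm_predict(m1, probe), svm_predict(m2, probe))

    def test_config_validation(self):
        with pytest.raises(InputError):
            SVMConfig(C=-1.0)
        with pytest.raises(InputError):
            SVMConfig(gamma=0.0)


class TestANN:
    def test_seeded_determinism(self, rng):
        scores = rng.normal(size=(40, 3))
        y = rng.choice(["A", "B"], 40)
        cfg = ANNConfig(seed=42)
        p1 = ann_predict(ann_fit(scores, y, cfg), scores)
        p2 = ann_predict(ann_fit(scores, y, cfg), scores)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_zero_training_error(self):
        rng = np.random.default_rng(17)
        scores = np.vstack([rng.normal(-2, 0.2, (25, 2)), rng.normal(2, 0.2, (25, 2))])
        y = np.array(["A"] * 25 + ["B"] * 25)
        model = ann_fit(scores, y, ANNConfig(seed=0))
        assert (ann_predict(model, scores) != y).sum() == 0

    def test_capacity_does_not_hurt_training_error(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=(60, 4))
        y = np.array(["A", "B"] * 30)
        errs = []
        for hidden in (2, 10, 30):
            model = ann_fit(scores, y, ANNConfig(hidden_nodes=hidden, seed=1))
            errs.append((ann_predict(model, scores) != y).mean())
        assert errs[2] <= errs[0] + 0.1

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            ann_fit(np.array([[np.nan, 1.0]]), ["A"], ANNConfig())

    def test_config_validation(self):
        with pytest.raises(InputError):
            ANNConfig(hidden_nodes=0)


def build_table(X, y):
    labels = pd.DataFrame(
        {
            "object_id": np.arange(1, len(y) + 1),
            "cultivar": "Trojan",
            "endophyte_status": y,
            "batch_date": "b1",
        }
    )
    return SpectraTable(X, np.linspace(1000, 2500, X.shape[1]), labels)


@pytest.fixture(scope="module")
def separable_setup():
    X, y = separable_table(seed=7, separation=6.0, n=80, n_bands=60)
    order = np.arange(80).reshape(2, 40).T.ravel()  # interleave the classes
    X, y = X[order], np.asarray(y)[order]
    table = build_table(X, y)
    split = kennard_stone_split(X, 0.8)
    cv = venetian_blinds(len(split.calibration_indices), 10)
    return table, split, cv


class TestEvaluateModel:
    def test_perfect_classifier_report(self, separable_setup):
        table, split, cv = separable_setup
        report = evaluate_model(
            {"classifier": "plsda", "n_lv": 2, "chain": ()}, table, split, cv
        )
        assert report.overall_accuracy == pytest.approx(100.0)
        assert (report.table["sensitivity_pred"] == 1.0).all()
        assert (report.table["class_error_cv"] == 0.0).all()
        assert list(report.table.columns) == report.COLUMNS

    def test_report_reproducible(self, separable_setup):
        table, split, cv = separable_setup
        spec = {"classifier": "annda", "n_lv": 2, "seed": 3, "chain": ()}
        r1 = evaluate_model(spec, table, split, cv)
        r2 = evaluate_model(spec, table, split, cv)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_svm_route(self, separable_setup):
        table, split, cv = separable_setup
        report = evaluate_model(
            {"classifier": "csvm", "C": 100.0, "gamma": 0.5, "n_compress_lv": 2,
             "chain": ()},
            table, split, cv,
        )
        assert report.overall_accuracy > 90.0

    def test_auto_lv_selection(self, separable_setup):
        table, split, cv = separable_setup
        report = evaluate_model(
            {"classifier": "plsda", "n_lv": "auto", "lv_grid": [1, 2, 3], "chain": ()},
            table, split, cv,
        )
        assert report.selected_n_lv in (1, 2, 3)

    def test_no_leakage_mutating_heldout_rows(self, separable_setup):
        # prediction rows may change arbitrarily without affecting fitted state
        table, split, cv = separable_setup
        X2 = table.X.copy()
        X2[split.prediction_indices] += 100.0
        mutated = build_table(X2, table.labels["endophyte_status"].to_numpy())
        spec = {"classifier": "plsda", "n_lv": 2, "chain": "pt6"}
        r1 = evaluate_model(spec, table, split, cv)
        r2 = evaluate_model(spec, mutated, split, cv)
        for col in ("sensitivity_cal", "class_error_cal", "sensitivity_cv",
                    "class_error_cv"):
            np.testing.assert_allclose(r1.table[col], r2.table[col])

    def test_csv_round_layout(self, separable_setup, tmp_path):
        table, split, cv = separable_setup
        report = evaluate_model(
            {"classifier": "plsda", "n_lv": 2, "chain": ()}, table, split, cv
        )
        out = tmp_path / "report.csv"
        report.to_csv(out)
        text = out.read_text().splitlines()
        assert text[0] == ",".join(report.COLUMNS)
        assert text[-1].startswith("overall_accuracy,")


class TestParameterRecovery:
    def test_cv_accuracy_monotone_in_signal_to_noise(self):
        # average CV accuracy over replicates rises with amplitude/noise ratio
        amplitudes = [0.0, 0.01, 0.03]
        means = []
        for amp in amplitudes:
            accs = []
            for rep in range(20):
                spec = SimSpec(
                    groups=(Group(15, "E+", "T", "b"), Group(15, "E-", "T", "b")),
                    signals={"E+": [(10, amp), (30, amp)]},
                    noise_sd=0.01,
                    n_bands=48,
                    rng_seed=1000 + rep,
                )
                table, _ = make_spectra(spec)
                y = table.labels["endophyte_status"].to_numpy()
                _, t = plsda_cv(table.X, y, (), [2], venetian_blinds(30, 5))
                accs.append(100 - t["cv_class_error"].iloc[0])
            means.append(np.mean(accs))
        assert means[1] >= means[0] - 2.0
        assert means[2] >= means[1] - 2.0
        assert means[2] > means[0] + 10.0
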