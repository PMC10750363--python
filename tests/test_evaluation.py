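import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitpipe.evaluation as ev

ASD, NON = "ASD", "non-ASD"

DOCTOR_1 = ev.RaterRatios(tp_rate=0.4074, fp_rate=0.5926,
                          fn_rate=0.3704, tn_rate=0.6296,
                          n_asd=54, n_non_asd=27)
DOCTOR_2 = ev.RaterRatios(tp_rate=0.4815, fp_rate=0.5185,
                          fn_rate=0.3889, tn_rate=0.6111,
                          n_asd=54, n_non_asd=27)


def _random_labels(rng, n):
    yt = rng.choice([ASD, NON], size=n)
    yp = rng.choice([ASD, NON], size=n)
    # guarantee both truth classes
    yt[0], yt[1] = ASD, NON
    return list(yt), list(yp)


class TestConfusion:
    def test_perfect_predictions_have_empty_off_diagonal(self):
        y = [ASD, NON, ASD, NON]
        cm = ev.confusion(y, y)
        assert cm.n_fp == 0 and cm.n_fn == 0
        assert cm.n_tp == 2 and cm.n_tn == 2

    def test_counts_sum_to_n(self, rng):
        yt, yp = _random_labels(rng, 57)
        assert ev.confusion(yt, yp).n == 57

    def test_matches_brute_force_tally(self, rng):
        for _ in range(100):
            yt, yp = _random_labels(rng, int(rng.integers(5, 60)))
            cm = ev.confusion(yt, yp)
            tp = sum(1 for t, p in zip(yt, yp) if t == ASD and p == ASD)
            fp = sum(1 for t, p in zip(yt, yp) if t == ASD and p == NON)
            fn = sum(1 for t, p in zip(yt, yp) if t == NON and p == ASD)
            tn = sum(1 for t, p in zip(yt, yp) if t == NON and p == NON)
            assert (cm.n_tp, cm.n_fp, cm.n_fn, cm.n_tn) == (tp, fp, fn, tn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion([ASD], [ASD, NON])


class TestAccuracy:
    def test_equals_direct_indicator_mean(self, rng):
        for _ in range(50):
            yt, yp = _random_labels(rng, 40)
            direct = np.mean([t == p for t, p in zip(yt, yp)])
            assert ev.accuracy(ev.confusion(yt, yp)) == pytest.approx(direct)

    def test_all_correct_is_one(self):
        y = [ASD, NON] * 5
        assert ev.accuracy(ev.confusion(y, y)) == 1.0

    def test_rater_accuracy_from_printed_ratios(self):
        # prevalence-weighted mean of the row rates, 54 ASD : 27 non-ASD
        assert ev.accuracy(DOCTOR_1.to_confusion()) == pytest.approx(0.4815, abs=5e-5)
        assert ev.accuracy(DOCTOR_2.to_confusion()) == pytest.approx(0.5247, abs=5e-5)


class TestF1:
    def test_perfect_predictions(self):
        y = [ASD, NON] * 4
        assert ev.f1(ev.confusion(y, y), ASD) == 1.0
        assert ev.f1(ev.confusion(y, y), NON) == 1.0

    def test_rater_f1_with_non_asd_positive(self):
        assert ev.f1(DOCTOR_1.to_confusion(), NON) == pytest.approx(0.4474, abs=5e-5)
        assert ev.f1(DOCTOR_2.to_confusion(), NON) == pytest.approx(0.4615, abs=5e-5)

    def test_invariant_to_uniform_scaling(self, rng):
        cm = ev.ConfusionMatrix(12, 5, 7, 20)
        for s in (0.5, 2, 10):
            scaled = ev.ConfusionMatrix(12 * s, 5 * s, 7 * s, 20 * s)
            assert ev.f1(scaled, ASD) == pytest.approx(ev.f1(cm, ASD))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score
        for _ in range(30):
            yt, yp = _random_labels(rng, 50)
            cm = ev.confusion(yt, yp)
            for pos in (ASD, NON):
                want = f1_score([t == pos for t in yt], [p == pos for p in yp],
                                zero_division=0)
                assert ev.f1(cm, pos) == pytest.approx(want)


class TestAuroc:
    def test_perfect_separation(self):
        y = [ASD] * 3 + [NON] * 3
        assert ev.auroc(y, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]) == 1.0

    def test_identical_scores_give_half(self):
        y = [ASD, ASD, NON, NON]
        assert ev.auroc(y, [0.5] * 4) == 0.5

    def test_matches_all_pairs_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            y = [ASD if v else NON for v in rng.integers(0, 2, n)]
            if ASD not in y or NON not in y:
                continue
            s = rng.choice(np.round(rng.uniform(0, 1, 10), 2), size=n)  # force ties
            got = ev.auroc(y, s)
            wins = total = 0
            for yi, si in zip(y, s):
                if yi != ASD:
                    continue
                for yj, sj in zip(y, s):
                    if yj == ASD:
                        continue
                    total += 1
                    wins += 1.0 if si > sj else (0.5 if si == sj else 0.0)
            assert got == pytest.approx(wins / total)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auroc([ASD, ASD], [0.1, 0.9])


class TestRaterAuroc:
    def test_doctor_rows(self):
        assert ev.rater_auroc(DOCTOR_1.to_confusion()) == pytest.approx(0.5185, abs=5e-5)
        assert ev.rater_auroc(DOCTOR_2.to_confusion()) == pytest.approx(0.5463, abs=5e-5)

    def test_perfect_rater(self):
        cm = ev.ConfusionMatrix(10, 0, 0, 5)
        assert ev.rater_auroc(cm) == 1.0

    def test_equals_rank_auroc_on_hard_scores(self, rng):
        """Closed form (TPR+TNR)/2 == the rank statistic on 0/1 scores."""
        for _ in range(50):
            yt, yp = _random_labels(rng, 40)
            cm = ev.confusion(yt, yp)
            hard = [1.0 if p == ASD else 0.0 for p in yp]
            assert ev.rater_auroc(cm) == pytest.approx(ev.auroc(yt, hard, ASD))


class TestReportFromRatios:
    def test_doctor1_report(self):
        r = ev.report_from_ratios(DOCTOR_1, positive_label=NON)
        assert (round(r.accuracy, 4), round(r.f1, 4), round(r.auroc, 4)) == \
            (0.4815, 0.4474, 0.5185)

    def test_doctor2_report(self):
        r = ev.report_from_ratios(DOCTOR_2, positive_label=NON)
        assert (round(r.accuracy, 4), round(r.f1, 4), round(r.auroc, 4)) == \
            (0.5247, 0.4615, 0.5463)

    def test_identity_rater_is_perfect(self):
        r = ev.report_from_ratios(
            ev.RaterRatios(1.0, 0.0, 0.0, 1.0, n_asd=54, n_non_asd=27), NON)
        assert (r.accuracy, r.f1, r.auroc) == (1.0, 1.0, 1.0)


class TestAggregateCv:
    def test_mean_of_fold_values(self):
        assert ev.aggregate_cv([0.7495, 0.7600, 0.7582]) == pytest.approx(0.7559, abs=5e-5)
        assert ev.aggregate_cv([0.7000, 0.7206, 0.7032]) == pytest.approx(0.7079, abs=5e-5)

    def test_single_value_and_empty(self):
        assert ev.aggregate_cv([0.42]) == 0.42
        with pytest.raises(ValueError):
            ev.aggregate_cv([])


class TestStratifiedGroupKFold:
    def _labels(self, n_asd, n_non):
        labels = {f"A{i}": ASD for i in range(n_asd)}
        labels.update({f"B{i}": NON for i in range(n_non)})
        return labels

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_partition_properties(self, seed):
        labels = self._labels(20, 13)
        fa = ev.stratified_group_kfold(labels, k=5, seed=seed)
        all_pids = [p for f in fa for p in f]
        assert sorted(all_pids) == sorted(labels)          # exhaustive
        assert len(all_pids) == len(set(all_pids))         # disjoint
        for i in range(fa.k):
            train, val = fa.train_val(i)
            assert not set(train) & set(val)

    def test_81_patients_fold_sizes(self):
        fa = ev.stratified_group_kfold(self._labels(54, 27), k=5, seed=0)
        assert sorted(len(f) for f in fa) == [16, 16, 16, 16, 17]

    def test_class_balance_within_one_patient(self):
        labels = self._labels(54, 27)
        global_frac = 54 / 81
        for seed in range(50):
            fa = ev.stratified_group_kfold(labels, k=5, seed=seed)
            for fold in fa:
                n_asd = sum(1 for p in fold if labels[p] == ASD)
                assert abs(n_asd - len(fold) * global_frac) <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            ev.stratified_group_kfold(self._labels(2, 1), k=5)
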