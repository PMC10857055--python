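"""Agreement statistics: printed worked examples and independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from triad import agreement as ag

# Pooled four-way activity confusion matrix reported for the wearable
# (rows = ground truth upright/walk/glide/squat over 10 pooled test folds).
DEVICE_ACTIVITY_CM = np.array([
    [805, 3, 1, 3],
    [45, 88, 8, 9],
    [2, 11, 146, 17],
    [9, 13, 17, 77],
])


class TestIbiAgreement:
    def test_identical_series_all_zero(self):
        r = ag.ibi_agreement(np.array([800.0, 900.0]), np.array([800.0, 900.0]))
        assert (r.mean_error, r.abs_mean_error, r.mape) == (0.0, 0.0, 0.0)
        assert (r.loa_low, r.loa_high) == (0.0, 0.0)

    def test_worked_arithmetic(self):
        r = ag.ibi_agreement(np.array([800.0, 1000.0]), np.array([792.0, 990.0]))
        assert r.abs_mean_error == pytest.approx(9.0)
        assert r.mape == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_direct_formulas(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        ref = rng.uniform(400, 1200, n)
        test = ref + rng.normal(0, 30, n)
        r = ag.ibi_agreement(ref, test)
        diff = ref - test
        assert r.mean_error == pytest.approx(diff.mean())
        assert r.abs_mean_error == pytest.approx(np.abs(diff).mean())
        assert r.mape == pytest.approx((np.abs(diff) / ref).mean() * 100)
        sd = diff.std(ddof=1)
        assert r.loa_low == pytest.approx(diff.mean() - 1.96 * sd)
        assert r.loa_high == pytest.approx(diff.mean() + 1.96 * sd)

    def test_mape_scale_invariant(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(500, 1000, 30)
        test = ref + rng.normal(0, 20, 30)
        assert ag.ibi_agreement(ref, test).mape == pytest.approx(
            ag.ibi_agreement(3.7 * ref, 3.7 * test).mape)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ag.ibi_agreement(np.array([0.0, 800.0]), np.array([1.0, 2.0]))


class TestClassifierMetrics:
    def test_reported_device_matrix(self):
        cm = ag.ConfusionMatrix(["up", "wa", "gl", "sq"], DEVICE_ACTIVITY_CM)
        m = ag.classifier_metrics(cm)
        assert round(m["accuracy"], 2) == 0.89
        assert round(m["weighted_f1"], 2) == 0.88
        assert round(m["kappa"], 2) == 0.79

    def test_identity_matrix_perfect(self):
        cm = ag.ConfusionMatrix(["a", "b", "c"], np.eye(3) * 10)
        m = ag.classifier_metrics(cm)
        assert m["accuracy"] == 1.0
        assert m["kappa"] == 1.0

    def test_uniform_matrix_chance(self):
        cm = ag.ConfusionMatrix(list("abcd"), np.full((4, 4), 5))
        m = ag.classifier_metrics(cm)
        assert m["accuracy"] == 0.25
        assert m["kappa"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_sklearn_oracle(self, seed):
        from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        counts = rng.integers(0, 20, (k, k))
        counts[np.arange(k), np.arange(k)] += 1  # every class observed
        y_true, y_pred = [], []
        for i in range(k):
            for j in range(k):
                y_true += [i] * int(counts[i, j])
                y_pred += [j] * int(counts[i, j])
        m = ag.classifier_metrics(ag.ConfusionMatrix([str(i) for i in range(k)], counts))
        assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
        assert m["weighted_f1"] == pytest.approx(
            f1_score(y_true, y_pred, average="weighted"))
        assert m["kappa"] == pytest.approx(cohen_kappa_score(y_true, y_pred))

    def test_kappa_one_iff_diagonal(self):
        rng = np.random.default_rng(7)
        diag = np.diag(rng.integers(1, 30, 4))
        assert ag.classifier_metrics(
            ag.ConfusionMatrix(list("abcd"), diag))["kappa"] == 1.0
        offdiag = diag.copy()
        offdiag[0, 1] = 3
        assert ag.classifier_metrics(
            ag.ConfusionMatrix(list("abcd"), offdiag))["kappa"] < 1.0


class TestMcNemar:
    def test_activity_device_comparison(self):
        stat, p = ag.mcnemar(ag.PairedOutcome(a=1065, b=95, c=61, d=33))
        assert stat == pytest.approx(7.41, abs=0.005)
        assert p == pytest.approx(0.006, abs=0.001)

    def test_ser_device_comparison(self):
        _, p = ag.mcnemar(ag.PairedOutcome(a=75, b=16, c=23, d=27))
        assert round(p, 2) == 0.26

    def test_symmetric_discordance(self):
        stat, p = ag.mcnemar(ag.PairedOutcome(a=5, b=10, c=10, d=5))
        assert (stat, p) == (0.0, pytest.approx(1.0))

    def test_no_discordance(self):
        assert ag.mcnemar(ag.PairedOutcome(a=50, b=0, c=0, d=2)) == (0.0, 1.0)

    def test_invariant_to_concordant_cells(self):
        r1 = ag.mcnemar(ag.PairedOutcome(a=0, b=12, c=5, d=0))
        r2 = ag.mcnemar(ag.PairedOutcome(a=999, b=12, c=5, d=999))
        assert r1 == r2

    @pytest.mark.parametrize("b,c", [(12, 5), (95, 61), (3, 3), (0, 7)])
    def test_matches_statsmodels(self, b, c):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        table = [[10, b], [c, 10]]
        ours_chi2, ours_p = ag.mcnemar(ag.PairedOutcome(10, b, c, 10), "chi2")
        sm = sm_mcnemar(table, exact=False, correction=False)
        assert ours_chi2 == pytest.approx(float(sm.statistic))
        assert ours_p == pytest.approx(float(sm.pvalue))
        ours_exact = ag.mcnemar(ag.PairedOutcome(10, b, c, 10), "exact")[1]
        sm_exact = sm_mcnemar(table, exact=True)
        assert ours_exact == pytest.approx(float(sm_exact.pvalue))

    def test_continuity_correction(self):
        stat, _ = ag.mcnemar(ag.PairedOutcome(0, 95, 61, 0), "chi2_corrected")
        assert stat == pytest.approx((abs(95 - 61) - 1) ** 2 / 156)


def _lev_oracle(ref: tuple, hyp: tuple, _memo={}) -> int:
    """Plain recursive Levenshtein distance, memoised (independent oracle)."""
    key = (ref, hyp)
    if key in _memo:
        return _memo[key]
    if not ref:
        r = len(hyp)
    elif not hyp:
        r = len(ref)
    elif ref[0] == hyp[0]:
        r = _lev_oracle(ref[1:], hyp[1:])
    else:
        r = 1 + min(_lev_oracle(ref[1:], hyp[1:]),
                    _lev_oracle(ref[1:], hyp),
                    _lev_oracle(ref, hyp[1:]))
    _memo[key] = r
    return r


class TestWer:
    def test_identical_transcripts(self):
        r = ag.wer("kids are talking by the door", "kids are talking by the door")
        assert r["wer"] == 0.0

    def test_worked_example(self):
        r = ag.wer("kids are talking by the door", "kids are walking by door")
        assert (r["S"], r["D"], r["I"], r["N"]) == (1, 1, 0, 6)
        assert r["wer"] == pytest.approx(2 / 6)

    def test_empty_hypothesis_all_deletions(self):
        r = ag.wer("dogs are sitting by the door", "")
        assert r["wer"] == 1.0
        assert r["D"] == 6 and r["S"] == 0 and r["I"] == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ag.wer("", "something")

    def test_tokenization_case_and_punctuation(self):
        assert ag.wer("Kids are talking, by the door!",
                      "kids are talking by the door")["wer"] == 0.0

    def test_exhaustive_small_vocabulary(self):
        # all pairs up to length 4 over a 3-word vocabulary vs the
        # independent recursive oracle, cross-checked with edlib
        import edlib
        vocab = ("a", "b", "c")
        seqs = [s for L in range(5) for s in itertools.product(vocab, repeat=L)]
        for ref in seqs:
            if not ref:
                continue
            for hyp in seqs:
                got = ag.wer(list(ref), list(hyp))
                expected = _lev_oracle(ref, hyp)
                assert got["errors"] == expected
                assert got["S"] + got["D"] + got["I"] == expected
                ed = edlib.align("".join(ref), "".join(hyp))["editDistance"]
                assert expected == ed


class TestRelativeImprovement:
    @pytest.mark.parametrize("base,better,expected", [
        (5.75, 4.16, 27.7), (3.58, 2.73, 23.7)])
    def test_reported_decoding_gains(self, base, better, expected):
        assert ag.relative_improvement(base, better) == pytest.approx(expected, abs=0.05)

    def test_no_change_is_zero(self):
        assert ag.relative_improvement(4.0, 4.0) == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ag.relative_improvement(0.0, 1.0)


class TestPairedT:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ag.paired_t(np.array([2.0, 2.0, 2.0]))

    def test_symmetric_diffs(self):
        t, df, p = ag.paired_t(np.array([1.0, -1.0]), tail="one")
        assert (t, df, p) == (0.0, 1, pytest.approx(0.5))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.4, 1.0, int(rng.integers(3, 30)))
        t, df, p = ag.paired_t(d, tail="two")
        ref = sps.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
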