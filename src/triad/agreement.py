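"""Device- and method-agreement statistics.

Everything needed to compare a wearable's derived measures against a
gold-standard device: interval-level error metrics with Bland–Altman limits
of agreement, confusion-matrix classification metrics (accuracy, weighted
F1, Cohen's kappa), McNemar's matched-pairs test on paired classifier
outcomes, word error rate by Levenshtein alignment, relative improvement
arithmetic, and paired t tests.  All statistics are computed from first
principles on plain arrays/tables so they can be driven by CSV inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AgreementReport:
    """Paired-interval agreement summary (reference minus test, ms)."""

    n: int
    mean_error: float
    abs_mean_error: float
    mape: float  # percent
    bias: float
    loa_low: float
    loa_high: float


@dataclass
class ConfusionMatrix:
    """Labelled K x K count table; rows are ground truth."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], counts=df.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts.astype(int), index=self.labels,
                     columns=self.labels).to_csv(path)


@dataclass
class PairedOutcome:
    """2 x 2 paired correct/incorrect counts for two classifiers A and B.

    a = both correct, b = only A correct, c = only B correct, d = both wrong.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


def ibi_agreement(ref: np.ndarray, test: np.ndarray) -> AgreementReport:
    """Error statistics and Bland–Altman limits for 1:1 paired intervals.

    ``mean_error`` is mean(ref − test); MAPE normalizes each absolute error
    by the reference value; limits of agreement are bias ± 1.96 SD of the
    differences.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape or ref.ndim != 1 or ref.size == 0:
        raise ValueError("ref and test must be equal-length non-empty 1-D arrays")
    if np.any(ref == 0):
        raise ValueError("reference intervals must be non-zero for MAPE")
    diff = ref - test
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if ref.size > 1 else 0.0
    return AgreementReport(
        n=int(ref.size),
        mean_error=bias,
        abs_mean_error=float(np.mean(np.abs(diff))),
        mape=float(np.mean(np.abs(diff) / np.abs(ref)) * 100.0),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def classifier_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, class-frequency-weighted F1, and Cohen's kappa from counts.

    Accuracy = trace/total.  Per-class F1 comes from row (truth) and column
    (prediction) sums; the weighted F1 averages class F1s by true-class
    frequency.  Kappa = (p_o − p_e)/(1 − p_e) with chance agreement p_e from
    the marginal products.
    """
    counts = cm.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    accuracy = tp.sum() / total

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    weighted_f1 = float(np.sum(f1 * row) / total)

    p_o = accuracy
    p_e = float(np.sum(row * col)) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return {"accuracy": float(accuracy), "weighted_f1": weighted_f1, "kappa": float(kappa)}


def mcnemar(outcome: PairedOutcome, method: str = "chi2") -> tuple[float, float]:
    """McNemar's test on the discordant cells of a paired 2 x 2 table.

    ``chi2``            (b−c)^2/(b+c), p from chi-square with 1 df (default);
    ``chi2_corrected``  (|b−c|−1)^2/(b+c) continuity-corrected;
    ``exact``           two-sided binomial(b; b+c, 1/2).

    Returns (statistic, p).  With b = c = 0 the classifiers never disagree:
    statistic 0, p 1.
    """
    b, c = outcome.b, outcome.c
    if b + c == 0:
        return 0.0, 1.0
    if method == "exact":
        p = float(stats.binomtest(b, b + c, 0.5).pvalue)
        return float(min(b, c)), p
    if method == "chi2":
        chi2 = (b - c) ** 2 / (b + c)
    elif method == "chi2_corrected":
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def tokenize(text: str) -> list[str]:
    """Case-fold, strip punctuation, split on whitespace."""
    cleaned = "".join(ch if (ch.isalnum() or ch in "' ") else " " for ch in text.lower())
    return cleaned.split()


def wer(
    reference: str | list[str],
    hypothesis: str | list[str],
) -> dict[str, float]:
    """Word error rate with substitution/deletion/insertion counts.

    Unit-cost Levenshtein alignment at the word level; WER = (S+D+I)/N with
    N the reference length.  String inputs are tokenized (lower-case,
    punctuation stripped).  Tie-break among equal-cost alignments prefers
    substitution over deletion over insertion.
    """
    ref = tokenize(reference) if isinstance(reference, str) else list(reference)
    hyp = tokenize(hypothesis) if isinstance(hypothesis, str) else list(hypothesis)
    n, m = len(ref), len(hyp)
    if n == 0:
        raise ValueError("reference must be non-empty")

    # dp[j] = (cost, S, D, I) for ref[:i] vs hyp[:j]
    prev = [(j, 0, 0, j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(i, 0, i, 0)] + [None] * m
        ri = ref[i - 1]
        for j in range(1, m + 1):
            if ri == hyp[j - 1]:
                cur[j] = prev[j - 1]
                continue
            sub = prev[j - 1]
            dele = prev[j]
            ins = cur[j - 1]
            best = min(
                (sub[0] + 1, sub[1] + 1, sub[2], sub[3]),
                (dele[0] + 1, dele[1], dele[2] + 1, dele[3]),
                (ins[0] + 1, ins[1], ins[2], ins[3] + 1),
                key=lambda t: t[0],
            )
            cur[j] = best
        prev = cur
    cost, s, d, ins = prev[m]
    return {"wer": cost / n, "S": s, "D": d, "I": ins, "N": n, "errors": cost}


def relative_improvement(baseline: float, improved: float) -> float:
    """Relative change (baseline − improved)/baseline x 100, in percent."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return (baseline - improved) / baseline * 100.0


def paired_t(diffs: np.ndarray, tail: str = "one") -> tuple[float, int, float]:
    """Paired t test on per-subject differences.

    Returns (t, df, p).  ``tail='one'`` tests the alternative mean(diff) > 0.
    Raises on zero-variance differences (t undefined).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("paired_t requires n >= 2")
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences; t undefined")
    n = d.size
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    if tail == "one":
        p = float(stats.t.sf(t, df))
    elif tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return t, df, p
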