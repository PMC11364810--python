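"""Evaluation metrics and statistics for decoder comparisons.

Covers the full reporting chain used in motor-imagery benchmarking:
confusion-matrix accuracy, Cohen's kappa under the balanced-chance
convention (P_e = 1/N; a marginal-chance variant is available), per-subject
aggregation as mean +/- sample standard deviation, Hedges' g effect sizes
(Cohen's d with the small-sample correction 1 - 3/(4(n1+n2) - 9)), and an
*exact* paired Wilcoxon signed-rank test: zeros dropped, midranks for tied
absolute differences, and the null distribution enumerated exhaustively over
all 2^n sign assignments — no normal approximation, so the p-values printed
in benchmark tables (e.g. 1/512 = 0.0020 when all nine differences are
positive) are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# confusion matrices, accuracy, kappa
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """N x N count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays differ in length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Fraction of correctly classified trials: trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def kappa(p_o: float, n_classes: int) -> float:
    """Cohen's kappa with balanced chance level P_e = 1/N."""
    if n_classes < 2:
        raise ValueError("kappa needs at least 2 classes")
    if not 0 <= p_o <= 1:
        raise ValueError(f"p_o must lie in [0, 1], got {p_o}")
    p_e = 1.0 / n_classes
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_confusion(cm: np.ndarray, chance: str = "balanced") -> float:
    """Kappa from a confusion matrix.

    ``chance='balanced'`` uses P_e = 1/N (class-balanced test sessions);
    ``chance='marginal'`` uses the product-of-marginals chance agreement.
    """
    cm = np.asarray(cm, dtype=np.float64)
    p_o = accuracy(cm)
    if chance == "balanced":
        return kappa(p_o, cm.shape[0])
    if chance == "marginal":
        total = cm.sum()
        p_e = float((cm.sum(axis=0) * cm.sum(axis=1)).sum() / total ** 2)
        return (p_o - p_e) / (1.0 - p_e)
    raise ValueError(f"unknown chance convention {chance!r}")


@dataclass
class SubjectResult:
    subject_id: str
    confusion: np.ndarray
    accuracy: float
    kappa: float


def subject_result(subject_id: str, cm: np.ndarray,
                   chance: str = "balanced") -> SubjectResult:
    return SubjectResult(subject_id=subject_id, confusion=np.asarray(cm),
                         accuracy=accuracy(cm),
                         kappa=kappa_from_confusion(cm, chance))


@dataclass
class AggregateResult:
    accuracies_pct: list[float]      # per subject, percent
    mean_pct: float
    std_pct: float                   # sample std (n-1 denominator)
    mean_kappa: float


def aggregate(results: list[SubjectResult]) -> AggregateResult:
    """Cross-subject summary: mean +/- sample std of accuracy percentages."""
    if len(results) < 2:
        raise ValueError("aggregation needs >= 2 subjects (sample std)")
    acc = np.array([r.accuracy * 100.0 for r in results])
    kap = np.array([r.kappa for r in results])
    return AggregateResult(accuracies_pct=acc.tolist(),
                           mean_pct=float(acc.mean()),
                           std_pct=float(acc.std(ddof=1)),
                           mean_kappa=float(kap.mean()))


def aggregate_accuracies(acc_pct) -> AggregateResult:
    """Summary straight from accuracy percentages (e.g. a published table row);
    mean kappa via the balanced-chance conversion is *not* derivable without
    N, so use :func:`kappa` separately."""
    acc = np.asarray(acc_pct, dtype=np.float64)
    if acc.size < 2:
        raise ValueError("aggregation needs >= 2 subjects (sample std)")
    return AggregateResult(accuracies_pct=acc.tolist(),
                           mean_pct=float(acc.mean()),
                           std_pct=float(acc.std(ddof=1)),
                           mean_kappa=float("nan"))


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

@dataclass
class EffectSizeResult:
    g: float
    d: float
    mean1: float
    mean2: float
    std1: float
    std2: float
    n1: int
    n2: int


def hedges_g(x, y) -> EffectSizeResult:
    """Hedges' g: pooled-SD Cohen's d times 1 - 3/(4(n1+n2) - 9)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    s1, s2 = x.std(ddof=1), y.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    d = (x.mean() - y.mean()) / pooled
    g = d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))
    return EffectSizeResult(g=float(g), d=float(d), mean1=float(x.mean()),
                            mean2=float(y.mean()), std1=float(s1),
                            std2=float(s2), n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# exact paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _midranks(a: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing the average rank."""
    from scipy.stats import rankdata
    return rankdata(a, method="average")


def wilcoxon_exact_p(x, y, alternative: str = "greater") -> float:
    """Exact paired Wilcoxon signed-rank p-value by sign-pattern enumeration.

    Differences ``x - y``; zero differences are dropped; absolute values are
    ranked with midranks for ties; the null distribution of the
    positive-rank sum W+ is built by exhaustive enumeration of all 2^n sign
    assignments (via integer convolution over doubled ranks, exact for ties).

    ``alternative='greater'`` tests a positive median difference (x above y),
    ``'less'`` the reverse, ``'two_sided'`` doubles the smaller tail (capped
    at 1).
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    ranks = _midranks(np.abs(d))
    # doubled midranks are integers -> exact distribution by convolution
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w_plus = float(2 * ranks[d > 0].sum())
    sums = np.arange(total + 1)
    n_patterns = counts.sum()          # 2^n
    p_greater = counts[sums >= np.rint(w_plus) - 1e-9].sum() / n_patterns
    p_less = counts[sums <= np.rint(w_plus) + 1e-9].sum() / n_patterns
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    return float(min(1.0, 2.0 * min(p_greater, p_less)))
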