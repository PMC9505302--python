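"""Normality-gated two-group test dispatch and Fisher's exact test.

Group comparisons follow the usual clinical-statistics convention: the
Shapiro–Wilk test (gate alpha = 0.05) decides between parametric and
rank-based tests.  Normally distributed data go to two-tailed Student
t-tests (paired or unpaired); otherwise unpaired data go to the exact
Mann–Whitney test (exact for <= 25 per group without ties, normal
approximation with tie correction beyond) and paired data to the
two-tailed Wilcoxon matched-pairs signed-rank test.  Categorical 2x2
contingency tables use Fisher's exact test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError
from .survival import TestResult

GATE_ALPHA = 0.05
EXACT_MW_MAX_N = 25


def dispatch_two_group_test(x, y, paired: bool = False,
                            gate_alpha: float = GATE_ALPHA) -> TestResult:
    """Compare two numeric samples, choosing the test by a normality gate.

    Shapiro–Wilk is run on each group (on the paired differences when
    `paired`); if no gate rejects at `gate_alpha`, a two-tailed t-test is
    used, otherwise the rank-based alternative.  The gate outcome is
    recorded on the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("each group needs >= 3 observations")
    if paired and len(x) != len(y):
        raise ValidationError("paired comparison requires equal-length vectors")

    gate: dict = {"alpha": gate_alpha}
    if paired:
        diff = y - x
        if np.allclose(diff, diff[0]):
            # constant differences: Shapiro is undefined; treat as non-normal
            gate["differences_p"] = None
            normal = False
        else:
            p = float(stats.shapiro(diff).pvalue)
            gate["differences_p"] = p
            normal = p > gate_alpha
    else:
        px = float(stats.shapiro(x).pvalue) if not np.allclose(x, x[0]) else 0.0
        py = float(stats.shapiro(y).pvalue) if not np.allclose(y, y[0]) else 0.0
        gate["x_p"], gate["y_p"] = px, py
        normal = px > gate_alpha and py > gate_alpha
    gate["normal"] = normal

    if paired:
        diff = y - x
        if np.all(diff == 0):
            return TestResult("wilcoxon_signed_rank", 0.0, 1.0,
                              normality_gate=gate, notes="all differences zero")
        if normal:
            res = stats.ttest_rel(x, y)
            return TestResult("t", float(res.statistic), float(res.pvalue),
                              normality_gate=gate)
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return TestResult("wilcoxon_signed_rank", float(res.statistic),
                          float(res.pvalue), normality_gate=gate)

    if normal:
        res = stats.ttest_ind(x, y)
        return TestResult("t", float(res.statistic), float(res.pvalue),
                          normality_gate=gate)
    return mann_whitney(x, y, gate=gate)


def mann_whitney(x, y, gate: dict | None = None) -> TestResult:
    """Two-tailed Mann–Whitney U; exact for small untied samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(x) <= EXACT_MW_MAX_N and len(y) <= EXACT_MW_MAX_N
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      normality_gate=gate or {}, notes=f"method={method}")


def fisher_exact_2x2(table) -> TestResult:
    """Two-tailed Fisher's exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities no larger than the
    observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(np.asarray(t, float) != np.floor(np.asarray(t, float))):
            raise ValidationError("table cells must be integers")
        if np.any(t < 0):
            raise ValidationError("table cells must be non-negative")
        t = t.astype(np.int64)
    if t.sum() == 0:
        raise UndefinedStatisticError("degenerate 2x2 table: all cells zero")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p))
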