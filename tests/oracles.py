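"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own vectorized code paths: explicit
loops, closed-form least squares, and a from-scratch Cohen's kappa, so that
agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math


def brute_force_gene_scores(matrix, alpha=0.5):
    """Per-gene dropout rate, F, F1_hat, F2_hat, dF1, dF2 and G via loops.

    ``matrix`` is a list of rows (cells); columns are genes. The OLS line of
    F on D uses the closed form a = cov(D, F)/var(D), b = mean(F) − a·mean(D).
    """
    n = len(matrix)
    p = len(matrix[0])
    dropout = []
    f = []
    f2 = []
    for j in range(p):
        zeros = 0
        total = 0.0
        log_total = 0.0
        for i in range(n):
            v = matrix[i][j]
            if v == 0:
                zeros += 1
            total += v
            log_total += math.log(v + 1.0)
        dropout.append(zeros / n)
        f.append(math.log(total / n + 1.0))
        f2.append(log_total / n)
    mean_d = sum(dropout) / p
    mean_f = sum(f) / p
    cov = sum((dropout[j] - mean_d) * (f[j] - mean_f) for j in range(p))
    var = sum((dropout[j] - mean_d) ** 2 for j in range(p))
    a = cov / var
    b = mean_f - a * mean_d
    out = []
    for j in range(p):
        f1_hat = a * dropout[j] + b
        df1 = f[j] - f1_hat
        df2 = f[j] - f2[j]
        out.append(
            {
                "dropout_rate": dropout[j],
                "F": f[j],
                "F1_hat": f1_hat,
                "F2_hat": f2[j],
                "dF1": df1,
                "dF2": df2,
                "G": alpha * df1 + (1 - alpha) * df2,
            }
        )
    return out, a, b


def textbook_kappa(true_labels, predicted_labels):
    """Cohen's kappa from first principles over fully-assigned label pairs."""
    n = len(true_labels)
    classes = sorted(set(true_labels) | set(predicted_labels))
    p_o = sum(1 for t, p in zip(true_labels, predicted_labels) if t == p) / n
    p_e = 0.0
    for c in classes:
        a_c = sum(1 for t in true_labels if t == c)
        b_c = sum(1 for p in predicted_labels if p == c)
        p_e += (a_c / n) * (b_c / n)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)
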