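"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available —
explicit dynamic programming, double loops, per-sample tallies — sharing no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

GAP = -0.5


def dp_identity(a: str, b: str) -> float:
    """Global-alignment identity by explicit Needleman-Wunsch DP.

    Scoring: match 1, mismatch 0, linear gap penalty -0.5 per gap symbol.
    Identity = max(0, optimal score) / len(shorter).
    """
    n, m = len(a), len(b)
    dp = np.empty((n + 1, m + 1))
    dp[:, 0] = GAP * np.arange(n + 1)
    dp[0, :] = GAP * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = dp[i - 1, j - 1] + (1.0 if a[i - 1] == b[j - 1] else 0.0)
            dp[i, j] = max(diag, dp[i - 1, j] + GAP, dp[i, j - 1] + GAP)
    return max(0.0, float(dp[n, m])) / min(n, m)


def tally_metrics(truth, decisions, classes):
    """Per-sample tally of TP/FP/FN and macro/weighted metrics.

    Accounting: abstention on an in-scope sample is an FN for its true
    class; an outgroup sample contributes only an FP when a class is
    emitted. Zero-denominator terms contribute 0. Weighted metrics use
    n_c / N with N counting in-scope samples.
    """
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    n_c = {c: 0 for c in classes}
    for t, d in zip(truth, decisions):
        if t in n_c:
            n_c[t] += 1
        if d == "ABSTAIN":
            if t in fn:
                fn[t] += 1
        elif d == t:
            tp[t] += 1
        else:
            fp[d] += 1
            if t in fn:
                fn[t] += 1

    def safe(num, den):
        return num / den if den else 0.0

    prec = {c: safe(tp[c], tp[c] + fp[c]) for c in classes}
    rec = {c: safe(tp[c], tp[c] + fn[c]) for c in classes}
    f1 = {c: safe(2 * prec[c] * rec[c], prec[c] + rec[c]) for c in classes}
    C = len(classes)
    N = sum(n_c.values())
    macro = (
        sum(prec.values()) / C,
        sum(rec.values()) / C,
        sum(f1.values()) / C,
    )
    weighted = (
        sum(n_c[c] * prec[c] for c in classes) / N,
        sum(n_c[c] * rec[c] for c in classes) / N,
        sum(n_c[c] * f1[c] for c in classes) / N,
    )
    return {
        "tp": tp, "fp": fp, "fn": fn, "n_c": n_c, "N": N,
        "macro": macro, "weighted": weighted,
    }


def brute_force_u(a, b) -> float:
    """U_A by the defining pair count: #{a > b} + 0.5 * #{a = b}."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_force_tomek(X, y):
    """Tomek links by an O(n^2) double loop with explicit tie-breaks."""
    X = np.asarray(X, dtype=float)
    n = len(y)
    nearest = []
    for i in range(n):
        best, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            d = float(((X[i] - X[j]) ** 2).sum())
            if d < best_d:  # strict: ties keep the lower index seen first
                best, best_d = j, d
        nearest.append(best)
    links = []
    for i in range(n):
        j = nearest[i]
        if j is not None and j > i and nearest[j] == i and y[i] != y[j]:
            links.append((i, j))
    return links


def segment_residual(point, a, b) -> float:
    """Distance from ``point`` to the segment [a, b] (least-squares projection)."""
    d = b - a
    denom = float(d @ d)
    if denom == 0.0:
        return float(np.linalg.norm(point - a))
    t = float(np.clip((point - a) @ d / denom, 0.0, 1.0))
    return float(np.linalg.norm(point - (a + t * d)))


def random_prediction_set(rng, n_min=5, n_max=200):
    """A random scored test set: classes, truths (with outgroup), decisions."""
    n_classes = int(rng.integers(2, 8))
    classes = [f"c{i}" for i in range(n_classes)]
    n = int(rng.integers(n_min, n_max + 1))
    truth_pool = classes + ["OUTGROUP"]
    truth = [truth_pool[i] for i in rng.integers(0, len(truth_pool), n)]
    dec_pool = classes + ["ABSTAIN"]
    decisions = [dec_pool[i] for i in rng.integers(0, len(dec_pool), n)]
    # guarantee at least one in-scope sample so N > 0
    truth[0] = classes[0]
    return classes, truth, decisions
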