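"""Confidence-thresholded evaluation of the abstaining classifier.

The classifier emits a genus only when the margin between its top two class
probabilities is at least a confidence threshold k (p1 - p2 >= k); otherwise
it abstains.  Metrics are parameterized by k and by the train-versus-test
identity threshold s of the split being scored.

Accounting rules (stated here because they fix the semantics of every
reported number):

* truth c in C, decision c            -> TP_c
* truth c in C, decision c' != c      -> FP_c' and FN_c
* truth c in C, abstain               -> FN_c (and FP for no class)
* truth OUTGROUP, decision c'         -> FP_c'
* truth OUTGROUP, abstain             -> no positive count
* TN_c = non-abstained samples touching neither c as truth nor as decision
  (recorded for completeness; no reported metric uses TN)

Abstention counting as FN-only is the accounting under which low k
prioritizes recall and high k prioritizes precision.  Macro metrics are
unweighted means of per-class precision/recall/F1; weighted metrics weight
by n_c / N.  By default N and n_c count in-scope samples only, with
outgroup records contributing solely through false positives; set
``count_outgroup_in_n=True`` for the alternative reading.  Per-class terms
with a zero denominator contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ABSTAIN",
    "OUTGROUP",
    "ClassCounts",
    "confusion_counts",
    "confusion_matrix",
    "decide",
    "evaluate_at_k",
    "macro_metrics",
    "pr_curve",
    "weighted_metrics",
]

ABSTAIN = "ABSTAIN"
OUTGROUP = "OUTGROUP"

DEFAULT_K_GRID = tuple(np.round(np.arange(0.0, 1.0, 0.1), 10))  # 0.0 .. 0.9


def decide(p: np.ndarray, k: float, classes) -> str:
    """Argmax class iff the top-two margin p1 - p2 >= k, else ABSTAIN.

    Argmax ties take the earlier class in ``classes`` order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) != len(classes):
        raise ValueError(f"probability vector length {p.shape} != {len(classes)} classes")
    if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("not a probability vector")
    top2 = np.sort(p)[-2:]
    p1, p2 = top2[1], top2[0]
    # 1e-12 slack so an exact margin (e.g. 0.6 - 0.4 vs k = 0.2) is not
    # lost to floating-point representation
    if p1 - p2 >= k - 1e-12:
        return str(classes[int(np.argmax(p))])
    return ABSTAIN


@dataclass
class ClassCounts:
    """Per-class TP/FP/FN/TN tallies plus class sizes for weighting."""

    classes: list[str]
    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]
    tn: dict[str, int]
    n_per_class: dict[str, int]
    N: int


def confusion_counts(
    truth, decisions, classes, count_outgroup_in_n: bool = False
) -> ClassCounts:
    """Tally per-class counts under the module's accounting rules."""
    truth = list(truth)
    decisions = list(decisions)
    if len(truth) != len(decisions):
        raise ValueError("truth and decisions differ in length")
    classes = [str(c) for c in classes]
    valid = set(classes)
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    tn = {c: 0 for c in classes}
    n_per_class = {c: 0 for c in classes}
    for t, d in zip(truth, decisions):
        t, d = str(t), str(d)
        if t not in valid and t != OUTGROUP:
            raise ValueError(f"truth label {t!r} outside classes + OUTGROUP")
        if d not in valid and d != ABSTAIN:
            raise ValueError(f"decision {d!r} outside classes + ABSTAIN")
        if t != OUTGROUP:
            n_per_class[t] += 1
        if d == ABSTAIN:
            if t != OUTGROUP:
                fn[t] += 1
            continue
        if t == d:
            tp[t] += 1
        else:
            fp[d] += 1
            if t != OUTGROUP:
                fn[t] += 1
        for c in classes:
            if c != t and c != d:
                tn[c] += 1
    N = len(truth) if count_outgroup_in_n else sum(n_per_class.values())
    return ClassCounts(
        classes=classes, tp=tp, fp=fp, fn=fn, tn=tn,
        n_per_class=n_per_class, N=N,
    )


def _per_class(counts: ClassCounts) -> dict[str, tuple[float, float, float]]:
    out = {}
    for c in counts.classes:
        tp, fp, fn = counts.tp[c], counts.fp[c], counts.fn[c]
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1)
    return out


def macro_metrics(counts: ClassCounts) -> tuple[float, float, float]:
    """Unweighted class means of precision, recall and F1."""
    per = _per_class(counts)
    arr = np.array(list(per.values()))
    return tuple(arr.mean(axis=0))


def weighted_metrics(counts: ClassCounts) -> tuple[float, float, float]:
    """Class-size-weighted metrics: (1/N) * sum_c n_c * metric_c."""
    if counts.N == 0:
        raise ValueError("N = 0: no in-scope test samples")
    per = _per_class(counts)
    weights = np.array([counts.n_per_class[c] for c in counts.classes], dtype=float)
    arr = np.array([per[c] for c in counts.classes])
    return tuple((weights[:, None] * arr).sum(axis=0) / counts.N)


def evaluate_at_k(
    probs: np.ndarray,
    truth,
    k: float,
    classes,
    s: float | None = None,
    count_outgroup_in_n: bool = False,
) -> dict:
    """One metric-report row at confidence threshold k."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    decisions = [decide(p, k, classes) for p in probs]
    counts = confusion_counts(truth, decisions, classes, count_outgroup_in_n)
    mp, mr, mf = macro_metrics(counts)
    wp, wr, wf = weighted_metrics(counts)
    coverage = sum(d != ABSTAIN for d in decisions) / len(decisions)
    row = {
        "k": k,
        "s": s,
        "coverage": coverage,
        "macro_precision": mp,
        "macro_recall": mr,
        "macro_f1": mf,
        "weighted_precision": wp,
        "weighted_recall": wr,
        "weighted_f1": wf,
    }
    per = _per_class(counts)
    for c in counts.classes:
        row[f"f1_{c}"] = per[c][2]
    return row


def pr_curve(
    probs: np.ndarray,
    truth,
    k_grid=DEFAULT_K_GRID,
    classes=None,
    s: float | None = None,
    count_outgroup_in_n: bool = False,
) -> pd.DataFrame:
    """Metrics across the confidence-threshold grid (default 0.0-0.9, step 0.1)."""
    k_grid = list(k_grid)
    if any(b < a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be sorted ascending")
    if classes is None:
        raise ValueError("classes must be given")
    rows = [
        evaluate_at_k(probs, truth, k, classes, s=s,
                      count_outgroup_in_n=count_outgroup_in_n)
        for k in k_grid
    ]
    return pd.DataFrame(rows)


def confusion_matrix(
    truth, decisions, classes, normalize: str | None = None
) -> pd.DataFrame:
    """(|C|+1) x (|C|+1) table: truth rows (+OUTGROUP), decision columns (+ABSTAIN).

    ``normalize`` is None (raw counts), "true" (rows sum to 1; the in-scope
    diagonal is then per-class recall) or "pred" (columns sum to 1; the
    diagonal is per-class precision). Zero rows/columns stay zero.
    """
    classes = [str(c) for c in classes]
    rows_idx = classes + [OUTGROUP]
    cols_idx = classes + [ABSTAIN]
    table = pd.DataFrame(0.0, index=rows_idx, columns=cols_idx)
    for t, d in zip(truth, decisions):
        table.loc[str(t), str(d)] += 1
    if normalize is None:
        return table
    if normalize == "true":
        sums = table.sum(axis=1)
        nonzero = sums > 0
        table.loc[nonzero] = table.loc[nonzero].div(sums[nonzero], axis=0)
        return table
    if normalize == "pred":
        sums = table.sum(axis=0)
        nonzero = sums[sums > 0].index
        table[nonzero] = table[nonzero].div(table[nonzero].sum(axis=0), axis=1)
        return table
    raise ValueError(f"normalize must be None, 'true' or 'pred', got {normalize!r}")
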