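"""Training-set class balancing: SMOTE oversampling + Tomek-link cleaning.

Host-genus datasets are heavily imbalanced (a few genera dominate), so after
splitting, the training set is rebalanced: SMOTE equalizes every class to the
majority count by interpolating synthetic points between a minority sample
and one of its k nearest same-class neighbors, then a single pass of
Tomek-link detection removes boundary pairs (mutual nearest neighbors with
different labels).  Balancing applies to the training set only; the test set
is never resampled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = ["BalancedSet", "SmoteTomek", "TomekPolicy", "smote", "smote_tomek", "tomek_links"]


class TomekPolicy(enum.Enum):
    REMOVE_BOTH = "both"
    REMOVE_MAJORITY_ONLY = "majority"


@dataclass
class BalancedSet:
    """Resampled training data with provenance flags."""

    X: np.ndarray
    y: np.ndarray
    synthetic_flags: np.ndarray
    removed_indices: list[int] = field(default_factory=list)


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    target: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    Each synthetic point is ``x + u * (x_nn - x)`` with u uniform on [0, 1),
    x a seeded-random member of the class being augmented and x_nn one of its
    k nearest same-class neighbors (Euclidean; k capped at class size - 1).
    ``target`` maps class label -> desired count; classes absent from the
    target, or already at/above it, are left alone. Default target equalizes
    all classes to the majority count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    count_of = dict(zip(classes.tolist(), counts.tolist()))
    if target is None:
        majority = int(counts.max())
        target = {c: majority for c in classes.tolist()}
    rng = np.random.default_rng(np.uint32(seed))

    new_rows, new_labels = [], []
    for label in classes.tolist():
        need = target.get(label, count_of[label]) - count_of[label]
        if need <= 0:
            continue
        if count_of[label] < 2:
            raise ValueError(
                f"class {label!r} has a single member; cannot interpolate"
            )
        members = X[y == label]
        k = min(k_neighbors, len(members) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
        # drop column 0: each point is its own nearest neighbor
        neighbor_idx = nn.kneighbors(members, return_distance=False)[:, 1:]
        base = rng.integers(0, len(members), size=need)
        pick = rng.integers(0, k, size=need)
        u = rng.random(size=need)
        for b, p, uu in zip(base, pick, u):
            x = members[b]
            x_nn = members[neighbor_idx[b, p]]
            new_rows.append(x + uu * (x_nn - x))
            new_labels.append(label)

    if not new_rows:
        return X.copy(), y.copy(), np.zeros(len(y), dtype=bool)
    X_aug = np.vstack([X, np.asarray(new_rows)])
    y_aug = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
    flags = np.concatenate(
        [np.zeros(len(y), dtype=bool), np.ones(len(new_rows), dtype=bool)]
    )
    return X_aug, y_aug, flags


def tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """Exhaustive Tomek-link detection.

    (i, j) is a link iff the labels differ and each point is the other's
    single nearest neighbor (Euclidean; distance ties broken by lower index).
    Returned pairs are ordered (i < j) and sorted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two points")
    # full distance matrix; training sets here are desk-scale
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = d2.argmin(axis=1)  # argmin takes the lowest index on ties
    links = []
    for i in range(n):
        j = int(nearest[i])
        if j > i and int(nearest[j]) == i and y[i] != y[j]:
            links.append((i, j))
    return sorted(links)


def smote_tomek(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
    policy: TomekPolicy = TomekPolicy.REMOVE_BOTH,
) -> BalancedSet:
    """SMOTE to the majority count, then one Tomek cleaning pass."""
    return SmoteTomek(k_neighbors=k_neighbors, policy=policy, seed=seed).fit_resample(
        X, y
    )


class SmoteTomek(BaseEstimator):
    """Combined SMOTE + Tomek resampler (imbalanced-learn-style interface).

    Parameters
    ----------
    k_neighbors : SMOTE neighbor count (capped at class size - 1).
    policy : REMOVE_BOTH deletes both members of each link (the classic
        combined resampler); REMOVE_MAJORITY_ONLY keeps the minority member.
    seed : drives all randomness; a fixed seed gives an identical result.
    """

    def __init__(
        self,
        k_neighbors: int = 5,
        policy: TomekPolicy = TomekPolicy.REMOVE_BOTH,
        seed: int = 0,
        target: dict | None = None,
    ):
        self.k_neighbors = k_neighbors
        self.policy = policy
        self.seed = seed
        self.target = target

    def fit_resample(self, X, y) -> BalancedSet:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        X_aug, y_aug, flags = smote(
            X, y, k_neighbors=self.k_neighbors, target=self.target, seed=self.seed
        )
        links = tomek_links(X_aug, y_aug)
        drop: set[int] = set()
        if self.policy is TomekPolicy.REMOVE_BOTH:
            for i, j in links:
                drop.update((i, j))
        else:
            classes, counts = np.unique(y_aug, return_counts=True)
            count_of = dict(zip(classes.tolist(), counts.tolist()))
            for i, j in links:
                # remove the member of the larger class; ties remove both
                ci, cj = count_of[y_aug[i]], count_of[y_aug[j]]
                if ci > cj:
                    drop.add(i)
                elif cj > ci:
                    drop.add(j)
                else:
                    drop.update((i, j))
        keep = np.array([i for i in range(len(y_aug)) if i not in drop], dtype=int)
        result = BalancedSet(
            X=X_aug[keep],
            y=y_aug[keep],
            synthetic_flags=flags[keep],
            removed_indices=sorted(drop),
        )
        self.links_ = links
        self.sampling_target_ = int(np.unique(y, return_counts=True)[1].max())
        return result
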