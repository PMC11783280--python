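"""Paired-distance two-group analysis of embeddings.

Do proteins targeting the same host genus sit closer together in embedding
space than proteins targeting different genera, even when their sequences
have diverged?  For each genus, two groups of protein pairs are sampled under
an identity cap (default: pairwise sequence identity below 40%): within-genus
pairs (both proteins target the genus) and cross-genus pairs (exactly one
does).  The distance between the members of each pair — cosine distance
between embeddings, or an externally supplied structural distance such as an
RMSD — is compared between the two groups with a Mann-Whitney U test
(midranks, tie-corrected variance, two-sided normal approximation with
continuity correction; group sizes here are large enough that the normal
approximation is accurate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .simsplit import IdentityCache

__all__ = [
    "PairGroup",
    "UTestResult",
    "cosine_distance",
    "mann_whitney_u",
    "sample_pair_groups",
    "two_group_report",
]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v), in [0, 2]. Zero vectors are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


@dataclass
class UTestResult:
    """Mann-Whitney U statistics and two-sided normal-approximation p-value."""

    U_A: float
    U_B: float
    z: float
    p_two_sided: float
    n_A: int
    n_B: int


def mann_whitney_u(group_a, group_b) -> UTestResult:
    """Two-sided Mann-Whitney U test via midranks.

    U_A counts pairs (a, b) with a > b plus half the tied pairs (the
    conventional definition, so U_A = 0 when every value in B exceeds every
    value in A), and U_A + U_B = n_A * n_B always. The variance carries the
    standard tie correction; the z-score applies a 0.5 continuity correction
    toward the null mean. With every pooled value tied the test is
    degenerate and p = 1 is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    rank_sum_a = ranks[:n_a].sum()
    # U_A = #{a>b} + 0.5*#{a=b}: A's rank sum minus its internal comparisons
    U_A = float(rank_sum_a - n_a * (n_a + 1) / 2.0)
    U_B = float(n_a * n_b - U_A)

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    mu = n_a * n_b / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:
        return UTestResult(U_A, U_B, 0.0, 1.0, n_a, n_b)
    diff = U_A - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return UTestResult(U_A, U_B, float(z), float(p), n_a, n_b)


@dataclass
class PairGroup:
    """Sampled within- and cross-genus pairs with their distances."""

    genus: str
    within_pairs: list[tuple[str, str]]
    cross_pairs: list[tuple[str, str]]
    within_distances: np.ndarray
    cross_distances: np.ndarray
    identity_cap: float
    seed: int


def _eligible_pairs(ids_a, ids_b, identity, cap, rng, n_needed, forbid_reuse):
    """Walk a shuffled candidate list, keeping identity-eligible pairs.

    Uniform without replacement over the eligible-pair set (a uniform random
    permutation filtered by a fixed predicate is a uniform sample of the
    predicate's support).
    """
    if ids_b is None:  # unordered pairs within one set
        candidates = [
            (ids_a[i], ids_a[j])
            for i in range(len(ids_a))
            for j in range(i + 1, len(ids_a))
        ]
    else:
        candidates = [(x, y) for x in ids_a for y in ids_b]
    order = rng.permutation(len(candidates))
    picked, used = [], set()
    for idx in order:
        x, y = candidates[idx]
        if forbid_reuse and (x in used or y in used):
            continue
        if identity(x, y) < cap:
            picked.append((x, y))
            used.update((x, y))
            if len(picked) == n_needed:
                break
    return picked, len(candidates)


def sample_pair_groups(
    sequences: dict[str, str],
    labels: dict[str, str],
    genus: str,
    identity_cap: float = 0.40,
    n_per_group: int = 500,
    seed: int = 0,
    forbid_reuse: bool = False,
    identity_cache: IdentityCache | None = None,
    distances: dict | None = None,
    embeddings: dict[str, np.ndarray] | None = None,
) -> PairGroup:
    """Sample within- and cross-genus pairs below the identity cap.

    Distances come from ``distances`` (a mapping of unordered id pairs to an
    externally computed value, e.g. a structural RMSD) when given, else from
    cosine distance between ``embeddings``.
    """
    if distances is None and embeddings is None:
        raise ValueError("provide embeddings or an external distance table")
    members = sorted(i for i, g in labels.items() if g == genus)
    others = sorted(i for i, g in labels.items() if g != genus)
    if len(members) < 2 or not others:
        raise ValueError(
            f"genus {genus!r}: {len(members)} members, {len(others)} others — "
            "not enough records to form both groups"
        )
    identity = identity_cache or IdentityCache(sequences)
    rng = np.random.default_rng(np.uint32(seed))
    within, n_within_cand = _eligible_pairs(
        members, None, identity, identity_cap, rng, n_per_group, forbid_reuse
    )
    cross, n_cross_cand = _eligible_pairs(
        members, others, identity, identity_cap, rng, n_per_group, forbid_reuse
    )
    if len(within) < n_per_group or len(cross) < n_per_group:
        raise ValueError(
            f"genus {genus!r}: insufficient eligible pairs below identity "
            f"{identity_cap} (within {len(within)}/{n_per_group} from "
            f"{n_within_cand} candidates, cross {len(cross)}/{n_per_group} "
            f"from {n_cross_cand})"
        )

    def dist(pair):
        if distances is not None:
            key = frozenset(pair)
            if key not in distances:
                raise KeyError(f"no external distance for pair {tuple(pair)}")
            return float(distances[key])
        return cosine_distance(embeddings[pair[0]], embeddings[pair[1]])

    return PairGroup(
        genus=genus,
        within_pairs=within,
        cross_pairs=cross,
        within_distances=np.array([dist(p) for p in within]),
        cross_distances=np.array([dist(p) for p in cross]),
        identity_cap=identity_cap,
        seed=seed,
    )


def two_group_report(pair_groups: list[PairGroup], alpha: float = 0.05) -> pd.DataFrame:
    """One row per genus: U statistic, p-value and significance at alpha."""
    rows = []
    for group in pair_groups:
        result = mann_whitney_u(group.within_distances, group.cross_distances)
        rows.append(
            {
                "genus": group.genus,
                "n_within": len(group.within_pairs),
                "n_cross": len(group.cross_pairs),
                "median_within": float(np.median(group.within_distances)),
                "median_cross": float(np.median(group.cross_distances)),
                "U": result.U_A,
                "z": result.z,
                "p_value": result.p_two_sided,
                "significant": bool(result.p_two_sided < alpha),
            }
        )
    return pd.DataFrame(rows)
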