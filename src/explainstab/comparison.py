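"""Comparison of the two explanation methods.

Per-subject agreement (correlation of the two methods' averaged attribution
vectors), per-feature correlation of averaged scores with age (Bonferroni
over features), tail-percentile feature sets from each method's correlation
distribution, their Jaccard overlap across a symmetric threshold sweep, and
a label-permutation significance test of each overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import UNDEFINED_CORRELATION, pearson_correlation
from .reliability import AveragedScores

__all__ = [
    "AgreementResult",
    "AgeCorrelationResult",
    "OverlapResult",
    "method_agreement",
    "score_age_correlation",
    "tail_feature_sets",
    "jaccard",
    "overlap_sweep",
    "overlap_permutation_test",
    "compare_r_distributions",
    "default_threshold_grid",
]


@dataclass
class AgreementResult:
    subject_ids: np.ndarray
    per_subject_r: np.ndarray  # NaN sentinel where undefined
    mean: float
    sd: float


@dataclass
class AgeCorrelationResult:
    feature_names: np.ndarray
    r: np.ndarray  # NaN sentinel for zero-variance score columns
    p: np.ndarray
    p_bonferroni: np.ndarray
    significant: np.ndarray  # adjusted p < alpha (False where sentinel)
    alpha: float
    method: str


@dataclass
class OverlapResult:
    thresholds: list  # (upper_pct, lower_pct) pairs
    sets_a: list  # frozenset of feature indices per threshold (first method)
    sets_b: list
    jaccard: np.ndarray
    both_empty: np.ndarray  # flag: J defined as 0 because both sets empty
    p_values: np.ndarray | None = None


def method_agreement(avg_a: AveragedScores, avg_b: AveragedScores) -> AgreementResult:
    """Per-subject correlation between the two methods' averaged vectors."""
    if list(avg_a.subject_ids) != list(avg_b.subject_ids):
        raise ValueError("subject mismatch between the two averaged-score sets")
    if avg_a.matrix.shape != avg_b.matrix.shape:
        raise ValueError("feature dimension mismatch")
    vals = np.array(
        [pearson_correlation(a, b) for a, b in zip(avg_a.matrix, avg_b.matrix)]
    )
    defined = vals[np.isfinite(vals)]
    return AgreementResult(
        subject_ids=avg_a.subject_ids,
        per_subject_r=vals,
        mean=float(np.mean(defined)) if defined.size else UNDEFINED_CORRELATION,
        sd=float(np.std(defined, ddof=1)) if defined.size > 1 else 0.0,
    )


def score_age_correlation(
    avg: AveragedScores, ages, feature_names=None, alpha: float = 0.05
) -> AgeCorrelationResult:
    """Per-feature Pearson r between the averaged score column and age, with
    two-sided p-values Bonferroni-multiplied by the number of features."""
    ages = np.asarray(ages, dtype=float)
    T, P = avg.matrix.shape
    if T < 3:
        raise ValueError("need at least 3 subjects")
    if len(ages) != T:
        raise ValueError("ages length does not match subjects")
    names = (
        np.asarray(feature_names)
        if feature_names is not None
        else np.asarray([f"feature_{j}" for j in range(P)])
    )
    r = np.empty(P)
    p = np.empty(P)
    for j in range(P):
        col = avg.matrix[:, j]
        if np.std(col) == 0 or np.std(ages) == 0:
            r[j], p[j] = UNDEFINED_CORRELATION, np.nan
        else:
            r[j], p[j] = stats.pearsonr(col, ages)
    p_adj = np.minimum(1.0, p * P)
    sig = np.where(np.isfinite(p_adj), p_adj < alpha, False)
    return AgeCorrelationResult(
        feature_names=names, r=r, p=p, p_bonferroni=p_adj,
        significant=sig, alpha=alpha, method=avg.method,
    )


def tail_feature_sets(
    result: AgeCorrelationResult, upper_pct: float, lower_pct: float
) -> frozenset:
    """Features in the tails of the r distribution: r >= the upper_pct
    percentile or r <= the lower_pct percentile (linear-interpolation
    percentiles over defined r values; ties at the cut enter the set)."""
    if not (75 <= upper_pct <= 99) or not (1 <= lower_pct <= 25):
        raise ValueError("upper_pct must lie in [75, 99], lower_pct in [1, 25]")
    defined = np.isfinite(result.r)
    vals = result.r[defined]
    if vals.size == 0:
        raise ValueError("no defined correlation values")
    hi = np.percentile(vals, upper_pct)
    lo = np.percentile(vals, lower_pct)
    idx = np.flatnonzero(defined & ((result.r >= hi) | (result.r <= lo)))
    return frozenset(int(i) for i in idx)


def jaccard(set_a, set_b) -> tuple[float, bool]:
    """|A n B| / |A u B|; (0, flagged) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0, True
    return len(a & b) / len(union), False


def default_threshold_grid() -> list[tuple[int, int]]:
    """Symmetric sweep (75, 25), (77, 23), ..., (99, 1) — step 2."""
    return [(u, 100 - u) for u in range(75, 100, 2)]


def overlap_sweep(
    res_a: AgeCorrelationResult,
    res_b: AgeCorrelationResult,
    grid: list[tuple[int, int]] | None = None,
) -> OverlapResult:
    """Jaccard overlap of the two methods' tail feature sets per threshold."""
    if list(res_a.feature_names) != list(res_b.feature_names):
        raise ValueError("feature universe mismatch between methods")
    grid = grid or default_threshold_grid()
    sets_a, sets_b, J, flags = [], [], [], []
    for u, l in grid:
        A = tail_feature_sets(res_a, u, l)
        B = tail_feature_sets(res_b, u, l)
        j, flag = jaccard(A, B)
        sets_a.append(A)
        sets_b.append(B)
        J.append(j)
        flags.append(flag)
    return OverlapResult(
        thresholds=list(grid), sets_a=sets_a, sets_b=sets_b,
        jaccard=np.asarray(J), both_empty=np.asarray(flags),
    )


def overlap_permutation_test(
    res_a: AgeCorrelationResult,
    res_b: AgeCorrelationResult,
    threshold_pair: tuple[float, float],
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Null: each method's per-feature r vector is permuted independently
    over feature labels, tail sets recomputed, Jaccard re-measured.
    p = (# null J >= observed J) / n_permutations."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    u, l = threshold_pair
    obs, _ = jaccard(tail_feature_sets(res_a, u, l), tail_feature_sets(res_b, u, l))
    rng = np.random.default_rng(seed)

    def permuted(res: AgeCorrelationResult) -> AgeCorrelationResult:
        perm = rng.permutation(len(res.r))
        return AgeCorrelationResult(
            feature_names=res.feature_names, r=res.r[perm], p=res.p[perm],
            p_bonferroni=res.p_bonferroni[perm], significant=res.significant[perm],
            alpha=res.alpha, method=res.method,
        )

    hits = 0
    for _ in range(n_permutations):
        j_null, _ = jaccard(
            tail_feature_sets(permuted(res_a), u, l),
            tail_feature_sets(permuted(res_b), u, l),
        )
        if j_null >= obs:
            hits += 1
    return hits / n_permutations


def attach_permutation_pvalues(
    result: OverlapResult,
    res_a: AgeCorrelationResult,
    res_b: AgeCorrelationResult,
    n_permutations: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    result.p_values = np.asarray(
        [
            overlap_permutation_test(res_a, res_b, pair, n_permutations, seed + i)
            for i, pair in enumerate(result.thresholds)
        ]
    )
    return result


def compare_r_distributions(r_a, r_b) -> dict:
    """Two-sided rank-sum test plus Cohen's d between two correlation-value
    distributions (defined values only)."""
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    stat, p = stats.ranksums(a, b)
    na, nb = len(a), len(b)
    pooled_var = (
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        if na + nb > 2
        else 0.0
    )
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var) if pooled_var > 0 else 0.0
    return {"ranksum_stat": float(stat), "p": float(p), "cohens_d": float(d)}
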