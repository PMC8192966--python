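"""Reliability of explanation stacks.

Two levels of analysis:

* within subject — the *intra-consistency* (IC): the Pearson correlation
  between every pair of a subject's attribution vectors produced by models
  trained on resampled training sets.  A reliable explainer yields vectors
  that barely move when the training set is perturbed (IC near 1).
* between subjects — the *inter-similarity* (IS): the correlation between
  two subjects' resampling-averaged attribution vectors.  The T x T IS
  matrix is partitioned with the k-medoid (PAM) algorithm and the resulting
  clusters are screened for age / FIQ / SNR structure with Kruskal-Wallis
  omnibus tests (Bonferroni over covariates) and Tukey-Kramer post-hocs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .explain import ExplanationStack
from .model import UNDEFINED_CORRELATION, pearson_correlation

__all__ = [
    "AveragedScores",
    "ConsistencyEntry",
    "SimilarityMatrix",
    "ClusterPartition",
    "average_scores",
    "stacks_to_averaged",
    "intra_consistency",
    "consistency_table",
    "ic_covariate_correlation",
    "inter_similarity",
    "k_medoid_partition",
    "cluster_covariate_tests",
]

log = logging.getLogger(__name__)


@dataclass
class AveragedScores:
    """T x P matrix of per-subject resampling-mean attribution vectors."""

    subject_ids: np.ndarray
    matrix: np.ndarray
    method: str


@dataclass
class ConsistencyEntry:
    subject_id: str
    pair_values: np.ndarray  # N(N-1)/2 pairwise correlations (NaN = undefined)
    mean_ic: float
    n_undefined: int


@dataclass
class SimilarityMatrix:
    subject_ids: np.ndarray
    matrix: np.ndarray  # T x T, symmetric, unit diagonal, NaN sentinel rows allowed
    method: str


@dataclass
class ClusterPartition:
    k: int
    labels: np.ndarray  # in [1, k], aligned with subject_ids
    medoid_ids: np.ndarray
    selection_scores: dict  # k -> mean silhouette
    subject_ids: np.ndarray
    excluded_ids: np.ndarray  # zero-variance subjects left out of clustering


def average_scores(stack: ExplanationStack) -> np.ndarray:
    """Column-wise mean of the stack: one representative vector per subject."""
    if stack.scores.size == 0 or stack.n_rounds < 1:
        raise ValueError("empty explanation stack")
    return stack.scores.mean(axis=0)


def stacks_to_averaged(stacks: dict[str, ExplanationStack], method: str) -> AveragedScores:
    ids = np.asarray(list(stacks.keys()))
    matrix = np.vstack([average_scores(stacks[s]) for s in ids])
    return AveragedScores(subject_ids=ids, matrix=matrix, method=method)


def intra_consistency(stack: ExplanationStack) -> ConsistencyEntry:
    """All N(N-1)/2 pairwise correlations between stack rows and their mean.

    Zero-variance rows make individual pairs undefined; those pairs are
    excluded from the mean and counted.  If every pair is undefined the
    subject-level mean is the sentinel.
    """
    N, P = stack.scores.shape
    if N < 2:
        raise ValueError("intra-consistency needs at least 2 rounds")
    if P < 2:
        raise ValueError("intra-consistency needs at least 2 features")
    vals = np.array(
        [pearson_correlation(stack.scores[k], stack.scores[z]) for k, z in combinations(range(N), 2)]
    )
    undefined = ~np.isfinite(vals)
    n_undef = int(undefined.sum())
    mean_ic = float(np.mean(vals[~undefined])) if n_undef < len(vals) else UNDEFINED_CORRELATION
    if n_undef:
        log.info("subject %s: %d undefined IC pairs excluded", stack.subject_id, n_undef)
    return ConsistencyEntry(
        subject_id=stack.subject_id, pair_values=vals, mean_ic=mean_ic, n_undefined=n_undef
    )


def consistency_table(stacks: dict[str, ExplanationStack], cohort: Cohort) -> pd.DataFrame:
    """Per-subject IC summary joined with site labels (subject, site,
    mean IC, number of undefined pairs)."""
    site_of = dict(zip(cohort.subject_ids.astype(str), cohort.site))
    rows = []
    for sid, stack in stacks.items():
        e = intra_consistency(stack)
        rows.append(
            {
                "subject_id": sid,
                "site": site_of.get(sid, ""),
                "mean_ic": e.mean_ic,
                "n_undefined_pairs": e.n_undefined,
            }
        )
    return pd.DataFrame(rows)


def ic_covariate_correlation(mean_ic_per_subject, covariate_values) -> tuple[float, float]:
    """Pearson r (and two-sided p) between subjects' mean IC and a covariate,
    over pairwise-complete subjects."""
    ic = np.asarray(mean_ic_per_subject, dtype=float)
    cov = np.asarray(covariate_values, dtype=float)
    if ic.shape != cov.shape:
        raise ValueError("length mismatch")
    ok = np.isfinite(ic) & np.isfinite(cov)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete pairs, have {int(ok.sum())}")
    r, p = stats.pearsonr(ic[ok], cov[ok])
    return float(r), float(p)


def inter_similarity(averaged: AveragedScores) -> SimilarityMatrix:
    """T x T matrix of correlations between averaged attribution vectors."""
    M = averaged.matrix
    T = M.shape[0]
    if T < 2:
        raise ValueError("need at least 2 subjects")
    sd = M.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(M)
    C = np.asarray(C, dtype=float)
    C[sd == 0, :] = UNDEFINED_CORRELATION
    C[:, sd == 0] = UNDEFINED_CORRELATION
    C = (C + C.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(C, 1.0)
    finite = np.isfinite(C)
    C[finite] = np.clip(C[finite], -1.0, 1.0)
    return SimilarityMatrix(subject_ids=averaged.subject_ids, matrix=C, method=averaged.method)


def _pam(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """One PAM run: random medoid init, alternate assignment and medoid
    update until stable.  Returns (labels 0..k-1, medoid indices, cost)."""
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                # re-seed an empty cluster at the worst-served point
                worst = int(np.argmax(D[np.arange(n), medoids[labels]]))
                new_medoids[c] = worst
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    cost = float(D[np.arange(n), medoids[labels]].sum())
    return labels, medoids, cost


def k_medoid_partition(
    similarity: SimilarityMatrix,
    k_range=range(2, 16),
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterPartition:
    """Partition subjects by explanation profile.

    Dissimilarity d = 1 - IS (negative similarities allowed, range [0, 2]).
    For each k in ``k_range``, PAM with seeded multi-restart keeps the
    lowest-cost run; the final k maximises the mean silhouette.  Subjects
    with sentinel (zero-variance) similarity rows are excluded and reported.
    """
    from sklearn.metrics import silhouette_score

    S = similarity.matrix
    ids = similarity.subject_ids
    valid = np.array([np.isfinite(S[i]).all() for i in range(len(ids))])
    excluded = ids[~valid]
    if excluded.size:
        log.info("excluding %d zero-variance subjects from clustering: %s",
                 excluded.size, list(excluded))
    S = S[np.ix_(valid, valid)]
    ids_v = ids[valid]
    n = len(ids_v)
    if n < 3:
        raise ValueError("too few clusterable subjects")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    off = D[~np.eye(n, dtype=bool)]
    if off.size and (off.max() - off.min()) < 1e-12:
        raise ValueError("non-clusterable input: all pairwise dissimilarities equal")

    rng = np.random.default_rng(seed)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range has no feasible values in [2, T-1]")
    best = None
    scores: dict[int, float] = {}
    for k in k_range:
        best_cost, best_run = np.inf, None
        for _ in range(n_restarts):
            labels, medoids, cost = _pam(D, k, rng)
            if cost < best_cost:
                best_cost, best_run = cost, (labels, medoids)
        labels, medoids = best_run
        if len(np.unique(labels)) < 2:
            scores[k] = -np.inf
            continue
        scores[k] = float(silhouette_score(D, labels, metric="precomputed"))
        if best is None or scores[k] > scores[best[0]]:
            best = (k, labels, medoids)
    if best is None:
        raise ValueError("no k produced a valid partition")
    k, labels, medoids = best
    return ClusterPartition(
        k=k,
        labels=labels + 1,
        medoid_ids=ids_v[medoids],
        selection_scores=scores,
        subject_ids=ids_v,
        excluded_ids=excluded,
    )


def _dunn_posthoc(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Rank-based Dunn all-pairs comparisons with Bonferroni adjustment."""
    ranks = stats.rankdata(values)
    n = len(values)
    groups = np.unique(labels)
    # tie correction for the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 1.0
    rows = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for a, b in combinations(groups, 2):
        ra = ranks[labels == a]
        rb = ranks[labels == b]
        se = np.sqrt((n * (n + 1) / 12.0) * tie * (1 / len(ra) + 1 / len(rb)))
        z = (ra.mean() - rb.mean()) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z,
                     "p_adj": min(1.0, p * n_pairs), "reject": min(1.0, p * n_pairs) < 0.05})
    return pd.DataFrame(rows)


def cluster_covariate_tests(
    partition: ClusterPartition,
    cohort: Cohort,
    covariates: tuple[str, ...] = ("age", "fiq", "snr"),
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> dict:
    """Kruskal-Wallis omnibus per covariate across clusters, Bonferroni over
    covariates; all-pairs post-hoc (Tukey-Kramer on raw values, or rank-based
    Dunn with ``posthoc='dunn'``) when the adjusted omnibus is significant.
    Entirely-missing covariates are skipped with a notice.
    """
    if partition.k < 2:
        raise ValueError("need at least 2 clusters")
    idx_of = {str(s): i for i, s in enumerate(cohort.subject_ids.astype(str))}
    rows = np.asarray([idx_of[str(s)] for s in partition.subject_ids])
    labels = partition.labels
    results: dict = {}
    tested = [c for c in covariates if np.isfinite(getattr(cohort, c)[rows]).any()]
    for cov in covariates:
        values = np.asarray(getattr(cohort, cov), dtype=float)[rows]
        ok = np.isfinite(values)
        if not ok.any():
            log.info("covariate %s entirely missing: skipped", cov)
            results[cov] = {"skipped": True, "reason": "entirely missing"}
            continue
        v, lab = values[ok], labels[ok]
        groups = [v[lab == g] for g in np.unique(lab) if (lab == g).sum() > 0]
        if len(groups) < 2 or all(len(g) < 1 for g in groups):
            results[cov] = {"skipped": True, "reason": "fewer than 2 nonempty clusters"}
            continue
        stat, p = stats.kruskal(*groups)
        p_adj = min(1.0, p * len(tested))
        entry = {
            "skipped": False,
            "kruskal_h": float(stat),
            "p": float(p),
            "p_bonferroni": float(p_adj),
            "significant": bool(p_adj < alpha),
            "posthoc": None,
        }
        if entry["significant"]:
            if posthoc == "tukey":
                from statsmodels.stats.multicomp import pairwise_tukeyhsd

                res = pairwise_tukeyhsd(v, lab, alpha=alpha)
                entry["posthoc"] = pd.DataFrame(
                    res.summary().data[1:], columns=res.summary().data[0]
                )
            elif posthoc == "dunn":
                entry["posthoc"] = _dunn_posthoc(v, lab)
            else:
                raise ValueError(f"unknown posthoc {posthoc!r}")
        results[cov] = entry
    return results
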