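"""Local surrogate explainers: Shapley-kernel regression and a LIME-style
proximity-weighted sparse linear surrogate, plus an exact-enumeration
Shapley oracle.

Both explainers fit an interpretable linear model g around one instance x of
a black-box predictor f by minimising a proximity-weighted squared loss over
a neighbourhood of simplified inputs, plus a complexity penalty:

    xi = argmin_g  sum_{z in Z} [f(h_x(z)) - g(z)]^2 * pi_x(z)  +  Omega(g)

The two methods differ only in the neighbourhood, the proximity kernel pi
and the penalty Omega:

* Shapley kernel: z are binary coalition vectors; h_x keeps "present"
  features at the instance's values and replaces absent ones by background
  rows; pi is the Shapley kernel (P-1) / (C(P,s) * s * (P-s)); Omega = 0 but
  the surrogate is constrained to local accuracy (base + sum(phi) = f(x)).
  With every coalition enumerated the solution equals the exact Shapley
  values of the induced cooperative game.
* LIME: z are Gaussian perturbations of the instance scaled by per-feature
  training standard deviations; pi = exp(-d^2 / width^2) with d the
  Euclidean distance in standardised space; Omega is an L2 penalty plus an
  optional top-k sparsity screen.

Attributions are in units of the predicted outcome (years of age here).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial
from typing import Callable

import numpy as np

from .cohort import Cohort

__all__ = [
    "ExplainerConfig",
    "SurrogateExplanation",
    "ExplanationStack",
    "shapley_kernel_weight",
    "exact_shapley",
    "kernel_shap_explain",
    "lime_explain",
    "explain_cohort",
]

_MAX_EXACT_P = 14


@dataclass
class ExplainerConfig:
    """Settings shared by both surrogate methods.

    ``n_samples`` is the number of coalitions (Shapley kernel) or
    perturbations (LIME) evaluated; ``background_size`` rows of the training
    subsample stand in for "absent" features and provide perturbation
    statistics.  ``kernel_width`` defaults to 0.75 * sqrt(P) in standardised
    space when left as None.
    """

    method: str = "shap_kernel"  # or "lime"
    background_size: int = 100
    n_samples: int | None = None  # None -> method default
    kernel_width: float | None = None
    regularization: float = 1.0
    top_k_features: int | None = None  # None -> dense (all P)
    seed: int = 0

    def validate(self, n_features: int | None = None) -> "ExplainerConfig":
        if self.method not in ("shap_kernel", "lime"):
            raise ValueError("method must be 'shap_kernel' or 'lime'")
        if self.background_size < 1:
            raise ValueError("background_size must be >= 1")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.kernel_width is not None and self.kernel_width <= 0:
            raise ValueError("kernel_width must be > 0")
        if n_features is not None and self.n_samples is not None:
            if self.n_samples < n_features + 2:
                raise ValueError(
                    f"n_samples = {self.n_samples} too small for a solvable "
                    f"surrogate over P = {n_features} features (need >= P + 2)"
                )
        return self

    def resolved_n_samples(self, P: int) -> int:
        if self.n_samples is not None:
            return self.n_samples
        return 2 * P + 2048 if self.method == "shap_kernel" else 5000


@dataclass
class SurrogateExplanation:
    phi: np.ndarray  # length P, units of the prediction
    base_value: float  # expected prediction over the background
    fidelity: float  # weighted surrogate loss at the solution
    method: str
    n_samples: int
    degenerate: bool = False  # True when the solver fell back to phi = 0


@dataclass
class ExplanationStack:
    """Per-subject attributions across resampling rounds: row n is the
    attribution vector produced by the round-n model."""

    subject_id: str
    method: str
    scores: np.ndarray  # (N, P)

    @property
    def n_rounds(self) -> int:
        return self.scores.shape[0]

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]


def shapley_kernel_weight(P: int, subset_size: int) -> float:
    """Shapley kernel pi(s) = (P - 1) / (C(P, s) * s * (P - s)).

    Defined for 0 < s < P; the empty and full coalitions carry infinite
    weight and are handled as equality constraints by the solver.
    """
    P = int(P)
    s = int(subset_size)
    if not (0 < s < P):
        raise ValueError(
            f"subset_size {s} out of (0, {P}): empty/full coalitions "
            "are equality constraints, not weighted samples"
        )
    # exact big-int denominator; plain ints avoid int64 overflow at large P
    return float((P - 1) / (comb(P, s) * s * (P - s)))


def _masked_values(
    predict_fn: Callable, instance: np.ndarray, background: np.ndarray, Z: np.ndarray,
    chunk: int = 128,
) -> np.ndarray:
    """v(z) = mean over background rows of f(x with absent features replaced),
    for each coalition row z of Z.  Evaluates in batched chunks."""
    B, P = background.shape
    out = np.empty(len(Z))
    for start in range(0, len(Z), chunk):
        zc = Z[start : start + chunk]
        # (n_chunk, B, P): background copies with present features overwritten
        data = np.broadcast_to(background, (len(zc), B, P)).copy()
        mask = zc.astype(bool)
        for i, z in enumerate(mask):
            data[i, :, z] = instance[z][:, None]
        preds = np.asarray(predict_fn(data.reshape(-1, P)), dtype=float)
        out[start : start + chunk] = preds.reshape(len(zc), B).mean(axis=1)
    return out


def exact_shapley(predict_fn, instance, background) -> np.ndarray:
    """Shapley values by full enumeration of all 2^P coalitions.

    The cooperative game is v(S) = E_b[f(x_S, b_{-S})] with the expectation
    over the background rows.  Exact but exponential; refuses P > 14.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    P = len(instance)
    if P > _MAX_EXACT_P:
        raise ValueError(f"exact enumeration infeasible for P = {P} > {_MAX_EXACT_P}")
    if len(background) == 0:
        raise ValueError("background must be nonempty")

    masks = np.arange(2**P, dtype=np.int64)
    Z = ((masks[:, None] >> np.arange(P)) & 1).astype(float)
    v = _masked_values(predict_fn, instance, background, Z)

    sizes = Z.sum(axis=1).astype(int)
    # |S|! (P - |S| - 1)! / P! indexed by |S| of the coalition without j
    w_by_size = np.array(
        [factorial(s) * factorial(P - s - 1) / factorial(P) for s in range(P)]
    )
    phi = np.zeros(P)
    for j in range(P):
        without_j = (masks >> j) & 1 == 0
        s = sizes[without_j]
        gain = v[masks[without_j] | (1 << j)] - v[without_j]
        phi[j] = np.sum(w_by_size[s] * gain)
    return phi


def _enumerate_coalitions(P: int, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic coalition scheme: complete size levels from the extremes
    (1, P-1, 2, P-2, ...) inward while they fit the budget, then paired
    random draws (coalition + complement) from the remaining sizes."""
    sizes_order = []
    lo, hi = 1, P - 1
    while lo <= hi:
        sizes_order.append(lo)
        if hi != lo:
            sizes_order.append(hi)
        lo += 1
        hi -= 1
    rows: list[np.ndarray] = []
    used = 0
    remaining_sizes = []
    for s in sizes_order:
        count = comb(P, s)
        if used + count <= budget:
            # enumerate all subsets of size s via combinations
            from itertools import combinations

            block = np.zeros((count, P))
            for i, idx in enumerate(combinations(range(P), s)):
                block[i, list(idx)] = 1.0
            rows.append(block)
            used += count
        else:
            remaining_sizes.append(s)
    if remaining_sizes and used < budget:
        probs = np.array([shapley_kernel_weight(P, s) * comb(P, s) for s in remaining_sizes])
        probs = probs / probs.sum()
        extra = []
        while used + len(extra) + 1 < budget:
            s = remaining_sizes[rng.choice(len(remaining_sizes), p=probs)]
            z = np.zeros(P)
            z[rng.choice(P, size=s, replace=False)] = 1.0
            extra.append(z)
            extra.append(1.0 - z)  # paired complement for variance reduction
        if extra:
            rows.append(np.asarray(extra))
    return np.concatenate(rows, axis=0) if rows else np.zeros((0, P))


def kernel_shap_explain(
    predict_fn, instance, background, config: ExplainerConfig
) -> SurrogateExplanation:
    """Shapley-kernel weighted least squares over binary coalitions.

    Solves the surrogate objective with the local-accuracy constraint
    base + sum(phi) = f(x) eliminated analytically.  With n_samples covering
    all 2^P - 2 proper coalitions the estimate is exact (equals
    :func:`exact_shapley` up to solver tolerance).
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    P = len(instance)
    config.validate()
    n_samples = config.resolved_n_samples(P)
    if n_samples < P + 2:
        raise ValueError(f"n_samples = {n_samples} < P + 2 = {P + 2}")
    rng = np.random.default_rng(config.seed)

    base = float(np.mean(np.asarray(predict_fn(background), dtype=float)))
    fx = float(np.asarray(predict_fn(instance[None, :]), dtype=float)[0])
    delta = fx - base

    full = 2**P - 2 if P <= 62 else None
    if full is not None and n_samples >= full:
        from itertools import combinations

        rows = []
        for s in range(1, P):
            block = np.zeros((comb(P, s), P))
            for i, idx in enumerate(combinations(range(P), s)):
                block[i, list(idx)] = 1.0
            rows.append(block)
        Z = np.concatenate(rows, axis=0)
    else:
        Z = _enumerate_coalitions(P, n_samples, rng)
    sizes = Z.sum(axis=1).astype(int)
    w = np.array([shapley_kernel_weight(P, s) for s in sizes])

    v = _masked_values(predict_fn, instance, background, Z)
    y = v - base

    # eliminate the constraint: phi_P = delta - sum(phi_1..P-1)
    A = Z[:, :-1] - Z[:, -1:]
    b = y - Z[:, -1] * delta
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
    degenerate = not np.all(np.isfinite(sol))
    if degenerate:
        phi = np.zeros(P)
    else:
        phi = np.concatenate([sol, [delta - sol.sum()]])
    fidelity = float(np.sum(w * (y - Z @ phi) ** 2))
    return SurrogateExplanation(
        phi=phi,
        base_value=base,
        fidelity=fidelity,
        method="shap_kernel",
        n_samples=len(Z),
        degenerate=degenerate,
    )


def lime_explain(
    predict_fn, instance, training_stats, config: ExplainerConfig
) -> SurrogateExplanation:
    """Proximity-weighted L2-regularised linear surrogate around one instance.

    ``training_stats`` is a ``(means, sds)`` pair over the training subjects;
    perturbations are drawn as instance + eps * sd with eps ~ N(0, 1),
    weighted by exp(-d^2 / width^2) with d = ||eps||.  Coefficients are
    returned in raw feature units (standardised-space fit divided by sd), so
    for a linear predictor they recover its weight vector.  Zero-variance
    features are held fixed and get coefficient 0.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    means, sds = (np.asarray(a, dtype=float).ravel() for a in training_stats)
    P = len(instance)
    config.validate()
    n = config.resolved_n_samples(P)
    rng = np.random.default_rng(config.seed)

    free = sds > 0
    width = config.kernel_width if config.kernel_width is not None else 0.75 * np.sqrt(P)

    eps = np.zeros((n, P))
    eps[:, free] = rng.standard_normal((n, int(free.sum())))
    Zraw = instance + eps * sds
    d2 = np.sum(eps * eps, axis=1)
    w = np.exp(-d2 / width**2)
    y = np.asarray(predict_fn(Zraw), dtype=float)

    phi = np.zeros(P)
    active = np.flatnonzero(free)
    if config.top_k_features is not None and config.top_k_features < len(active):
        # pre-screen by |weighted covariance| between each perturbed feature
        # and the predictor output
        wsum = w.sum()
        yc = y - np.sum(w * y) / wsum
        cov = np.abs((w[:, None] * eps[:, active] * yc[:, None]).sum(axis=0)) / wsum
        keep = active[np.argsort(-cov)[: config.top_k_features]]
        active = np.sort(keep)

    if len(active) and w.sum() > 0:
        U = eps[:, active]
        wsum = w.sum()
        u_mean = (w[:, None] * U).sum(axis=0) / wsum
        y_mean = np.sum(w * y) / wsum
        Uc = U - u_mean
        yc = y - y_mean
        G = (w[:, None] * Uc).T @ Uc + config.regularization * np.eye(len(active))
        rhs = (w[:, None] * Uc).T @ yc
        beta = np.linalg.solve(G, rhs)
        phi[active] = beta / sds[active]
        fidelity = float(np.sum(w * (yc - Uc @ beta) ** 2))
        base = float(y_mean)
    else:
        fidelity = 0.0
        base = float(np.mean(y)) if n else 0.0
    return SurrogateExplanation(
        phi=phi,
        base_value=base,
        fidelity=fidelity,
        method="lime",
        n_samples=n,
        degenerate=False,
    )


def explain_cohort(
    registry: dict,
    cohort: Cohort,
    configs: dict[str, ExplainerConfig],
    *,
    n_rounds: int | None = None,
) -> dict[str, dict[str, ExplanationStack]]:
    """Attribution stacks for every subject from the resampled LOSO models.

    ``registry`` is the model registry from :func:`run_resampled_loso`; each
    subject is explained only by the models of the fold holding out that
    subject's site, with background rows / training statistics drawn from
    each round's actual training subsample (never the subject's own site).
    Returns ``{method: {subject_id: ExplanationStack}}``.
    """
    folds = registry["folds"]
    if n_rounds is None:
        n_rounds = max(n for (f, n) in (k for k in registry if isinstance(k, tuple))) + 1
    out: dict[str, dict[str, ExplanationStack]] = {m: {} for m in configs}

    for f, (train_idx, test_idx, site) in enumerate(folds):
        # per-round masking backgrounds and perturbation statistics
        round_ctx = []
        for n in range(n_rounds):
            if (f, n) not in registry:
                raise KeyError(f"missing model for fold {f} round {n}")
            entry = registry[(f, n)]
            sub = np.asarray(entry["train_indices"])
            Xsub = cohort.features[sub]
            # salt folds the subsample identity into the explainer seed
            salt = int((sub.astype(np.int64) * np.arange(1, len(sub) + 1)).sum() % (2**31))
            ctx = {"model": entry["model"], "X": Xsub, "train_idx_sum": salt}
            round_ctx.append(ctx)

        for t in test_idx:
            x = cohort.features[t]
            for method, cfg in configs.items():
                scores = np.empty((n_rounds, cohort.n_features))
                for n, ctx in enumerate(round_ctx):
                    # seeded by (fold, subject, subsample content): identical
                    # models trained on identical subsamples yield identical
                    # stack rows, while distinct rounds decorrelate
                    ss = np.random.SeedSequence(
                        [cfg.seed, f, int(t), ctx.get("train_idx_sum", 0)]
                    )
                    seed_n = int(ss.generate_state(1)[0] % 2**31)
                    cfg_n = ExplainerConfig(
                        method=cfg.method,
                        background_size=cfg.background_size,
                        n_samples=cfg.n_samples,
                        kernel_width=cfg.kernel_width,
                        regularization=cfg.regularization,
                        top_k_features=cfg.top_k_features,
                        seed=seed_n,
                    )
                    rng = np.random.default_rng(seed_n + 1)
                    X = ctx["X"]
                    predict = ctx["model"].predict
                    if cfg.method == "shap_kernel":
                        bsize = min(cfg.background_size, len(X))
                        bg = X[rng.choice(len(X), size=bsize, replace=False)]
                        scores[n] = kernel_shap_explain(predict, x, bg, cfg_n).phi
                    else:
                        stats = (X.mean(axis=0), X.std(axis=0))
                        scores[n] = lime_explain(predict, x, stats, cfg_n).phi
                out[method][str(cohort.subject_ids[t])] = ExplanationStack(
                    subject_id=str(cohort.subject_ids[t]), method=method, scores=scores
                )
    return out
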