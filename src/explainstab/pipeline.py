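"""End-to-end orchestration: simulate/load -> train -> explain -> reliability
-> comparison, with per-stage artifacts, resumability and a structured JSON
report.

Stage artifacts under the output directory are the interchange contract:

    cohort/        features.tsv, phenotype.tsv, ground_truth.json
    models/        fold{f}_round{n}.npz + predictions.tsv + performance.json
    explanations/  {method}_stacks.zip (TSV per subject + manifest)
    reliability/   {method}_consistency.tsv, {method}_similarity.tsv,
                   {method}_partition.json, {method}_cluster_tests.json
    comparison/    agreement.tsv, {method}_age_correlation.tsv, overlap.tsv
    report.json, manifest.json

Any stage can therefore be driven by externally produced inputs (e.g. real
FreeSurfer tables written in the cohort TSV layout).
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
import time
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from . import reliability as rel
from .cohort import GeneratorConfig, generate_cohort, load_cohort, write_cohort
from .explain import ExplainerConfig, ExplanationStack, explain_cohort
from .model import (
    FittedModel,
    ModelConfig,
    ResamplingPlan,
    loso_splits,
    permutation_test_performance,
    run_resampled_loso,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "load_run_config",
    "validate_report",
    "desk_run_config",
]

log = logging.getLogger(__name__)

STAGES = ("cohort", "models", "explanations", "reliability", "comparison")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.  Exactly one of ``features_path``/
    ``phenotype_path`` or ``generator`` must be provided."""

    output_dir: str
    generator: GeneratorConfig | None = None
    features_path: str | None = None
    phenotype_path: str | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    plan: ResamplingPlan = field(default_factory=ResamplingPlan)
    explainers: dict = field(
        default_factory=lambda: {
            "shap_kernel": ExplainerConfig(method="shap_kernel"),
            "lime": ExplainerConfig(method="lime"),
        }
    )
    k_range: tuple[int, int] = (2, 15)
    n_permutations: int = 1000
    performance_permutations: int = 0  # 0 disables the (expensive) test
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        from_files = self.features_path is not None or self.phenotype_path is not None
        if from_files and self.generator is not None:
            raise ValueError("provide either input paths or a generator config, not both")
        if not from_files and self.generator is None:
            raise ValueError("provide input paths or a generator config")
        if from_files and (self.features_path is None or self.phenotype_path is None):
            raise ValueError("both features_path and phenotype_path are required")
        self.model.validate()
        self.plan.validate()
        for cfg in self.explainers.values():
            cfg.validate()
        return self


def desk_run_config(
    output_dir,
    seed: int = 0,
    n_rounds: int = 20,
    n_permutations: int = 200,
) -> RunConfig:
    """Desk-scale study preset: the default 6-site / 300-subject / 60-feature
    simulated cohort, N resampling rounds at 80%, a 2x32 Adam-trained net, and
    moderate explainer budgets (256 coalitions over a 25-row background for
    the Shapley kernel, 1,000 perturbations for LIME).  Runs end to end in
    minutes on one CPU while exercising every stage of the framework."""
    from .model import small_model_config

    return RunConfig(
        output_dir=str(output_dir),
        generator=GeneratorConfig(seed=seed),
        model=small_model_config(seed=seed, max_epochs=120, early_stop_patience=12),
        plan=ResamplingPlan(n_rounds=n_rounds, subsample_fraction=0.8, base_seed=seed),
        explainers={
            "shap_kernel": ExplainerConfig(
                method="shap_kernel", n_samples=256, background_size=25, seed=seed
            ),
            "lime": ExplainerConfig(method="lime", n_samples=1000, seed=seed),
        },
        k_range=(2, 10),
        n_permutations=n_permutations,
        seed=seed,
    ).validate()


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    gen = raw.pop("generator", None)
    model = raw.pop("model", {})
    plan = raw.pop("plan", {})
    explainers = raw.pop("explainers", None)
    cfg = RunConfig(
        generator=GeneratorConfig(**{
            **gen, **{k: tuple(map(tuple, v)) if k == "site_age_ranges" else tuple(v)
                      for k, v in gen.items() if isinstance(v, list)},
        }) if gen is not None else None,
        model=ModelConfig(**model),
        plan=ResamplingPlan(**plan),
        **raw,
    )
    if explainers is not None:
        cfg.explainers = {
            name: ExplainerConfig(method=spec.get("method", name), **{
                k: v for k, v in spec.items() if k != "method"
            })
            for name, spec in explainers.items()
        }
    return cfg.validate()


# --- stack (de)serialisation ------------------------------------------------

def save_stacks(stacks: dict[str, ExplanationStack], method: str, path) -> None:
    """One zip archive of per-subject TSV matrices plus a JSON manifest."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        manifest = {"method": method, "subjects": list(stacks)}
        zf.writestr("manifest.json", json.dumps(manifest))
        for sid, stack in stacks.items():
            buf = io.StringIO()
            pd.DataFrame(stack.scores).to_csv(buf, sep="\t", index=False, header=False)
            zf.writestr(f"{sid}.tsv", buf.getvalue())


def load_stacks(path) -> tuple[str, dict[str, ExplanationStack]]:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        method = manifest["method"]
        stacks = {}
        for sid in manifest["subjects"]:
            df = pd.read_csv(io.BytesIO(zf.read(f"{sid}.tsv")), sep="\t", header=None)
            stacks[sid] = ExplanationStack(
                subject_id=sid, method=method, scores=df.to_numpy(dtype=float)
            )
    return method, stacks


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _done(path: Path, stage: str) -> Path:
    return path / f".{stage}.done"


def run_pipeline(config: RunConfig, resume: bool = False, stop_after: str | None = None) -> dict:
    """Execute the full framework; returns the report dictionary.

    With ``resume=True`` stages whose completion marker and artifacts exist
    are reloaded from disk instead of recomputed.  ``stop_after`` ends the
    run after the named stage (artifacts preserved).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {"stages": {}, "alpha": config.alpha}
    manifest: dict = {"seed": config.seed, "stages": {}}
    t_start = time.time()

    def finish(stage):
        _done(out, stage).write_text("ok")
        manifest["stages"][stage] = {"seconds": round(time.time() - t_start, 2)}
        log.info("stage %s complete (%.1fs elapsed)", stage, time.time() - t_start)

    # ---- cohort ----
    stage = "cohort"
    cohort_dir = out / "cohort"
    cohort_dir.mkdir(exist_ok=True)
    try:
        if resume and _done(out, stage).exists():
            cohort = load_cohort(cohort_dir / "features.tsv", cohort_dir / "phenotype.tsv")
            truth = None
            gt_path = cohort_dir / "ground_truth.json"
            if gt_path.exists():
                truth = json.loads(gt_path.read_text())
        elif config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.generator.seed or config.seed)
            cohort, truth_obj = generate_cohort(gen)
            write_cohort(cohort, cohort_dir / "features.tsv", cohort_dir / "phenotype.tsv")
            truth = {
                "planted_feature_indices": truth_obj.planted_feature_indices.tolist(),
                "age_slopes": truth_obj.age_slopes.tolist(),
                "quad_coeffs": truth_obj.quad_coeffs.tolist(),
            }
            (cohort_dir / "ground_truth.json").write_text(json.dumps(truth))
            finish(stage)
        else:
            cohort = load_cohort(config.features_path, config.phenotype_path)
            write_cohort(cohort, cohort_dir / "features.tsv", cohort_dir / "phenotype.tsv")
            truth = None
            finish(stage)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc
    report["stages"]["cohort"] = {
        "n_subjects": cohort.n_subjects,
        "n_features": cohort.n_features,
        "n_sites": len(cohort.sites),
    }
    if stop_after == "cohort":
        _write_report(out, report, manifest)
        return report

    # ---- models ----
    stage = "models"
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    try:
        n_folds = len(loso_splits(cohort))
        if resume and _done(out, stage).exists():
            registry = {"folds": loso_splits(cohort)}
            for f in range(n_folds):
                for n in range(config.plan.n_rounds):
                    m = FittedModel.load(models_dir / f"fold{f}_round{n}.npz")
                    registry[(f, n)] = {
                        "model": m,
                        "train_indices": np.asarray(m.metadata["train_indices"]),
                    }
            perf_json = json.loads((models_dir / "performance.json").read_text())
            predictions = pd.read_csv(models_dir / "predictions.tsv", sep="\t")
            perf = None
        else:
            perf, registry = run_resampled_loso(cohort, config.model, config.plan)
            for (key, entry) in registry.items():
                if not isinstance(key, tuple):
                    continue
                f, n = key
                entry["model"].metadata["train_indices"] = [int(i) for i in entry["train_indices"]]
                entry["model"].save(models_dir / f"fold{f}_round{n}.npz")
            if config.performance_permutations > 0:
                p_mae, p_r = permutation_test_performance(
                    cohort, config.model, config.plan,
                    config.performance_permutations, seed=config.seed + 1,
                    observed=perf,
                )
                perf.p_mae, perf.p_r = p_mae, p_r
            perf_json = perf.to_json_dict()
            (models_dir / "performance.json").write_text(json.dumps(perf_json))
            perf.to_subject_frame().to_csv(models_dir / "predictions.tsv", sep="\t", index=False)
            finish(stage)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    report["stages"]["models"] = perf_json
    if stop_after == "models":
        _write_report(out, report, manifest)
        return report

    # ---- explanations ----
    stage = "explanations"
    exp_dir = out / "explanations"
    exp_dir.mkdir(exist_ok=True)
    try:
        if resume and _done(out, stage).exists():
            all_stacks = {}
            for name in config.explainers:
                _, stacks = load_stacks(exp_dir / f"{name}_stacks.zip")
                all_stacks[name] = stacks
        else:
            all_stacks = explain_cohort(
                registry, cohort, config.explainers, n_rounds=config.plan.n_rounds
            )
            for name, stacks in all_stacks.items():
                save_stacks(stacks, name, exp_dir / f"{name}_stacks.zip")
            finish(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    report["stages"]["explanations"] = {
        name: {"n_subjects": len(stacks)} for name, stacks in all_stacks.items()
    }
    if stop_after == "explanations":
        _write_report(out, report, manifest)
        return report

    # ---- reliability ----
    stage = "reliability"
    rel_dir = out / "reliability"
    rel_dir.mkdir(exist_ok=True)
    averaged: dict[str, rel.AveragedScores] = {}
    try:
        rel_report = {}
        order = [str(s) for s in cohort.subject_ids]
        for name, stacks in all_stacks.items():
            stacks_ordered = {s: stacks[s] for s in order}
            ic_table = rel.consistency_table(stacks_ordered, cohort)
            ic_table.to_csv(rel_dir / f"{name}_consistency.tsv", sep="\t", index=False)
            avg = rel.stacks_to_averaged(stacks_ordered, name)
            averaged[name] = avg
            sim = rel.inter_similarity(avg)
            pd.DataFrame(sim.matrix, index=avg.subject_ids, columns=avg.subject_ids).to_csv(
                rel_dir / f"{name}_similarity.tsv", sep="\t"
            )
            part = rel.k_medoid_partition(
                sim, k_range=range(config.k_range[0], config.k_range[1] + 1),
                seed=config.seed + 7,
            )
            tests = rel.cluster_covariate_tests(part, cohort, alpha=config.alpha)
            (rel_dir / f"{name}_partition.json").write_text(json.dumps({
                "k": part.k,
                "labels": {str(s): int(l) for s, l in zip(part.subject_ids, part.labels)},
                "medoids": [str(m) for m in part.medoid_ids],
                "silhouette_by_k": {str(k): v for k, v in part.selection_scores.items()},
            }))
            (rel_dir / f"{name}_cluster_tests.json").write_text(json.dumps({
                cov: {k: v for k, v in res.items() if k != "posthoc"}
                for cov, res in tests.items()
            }))
            ic_vals = ic_table["mean_ic"].to_numpy()
            cov_corr = {}
            for covname in ("age", "fiq", "snr"):
                try:
                    r, p = rel.ic_covariate_correlation(ic_vals, getattr(cohort, covname))
                    cov_corr[covname] = {"r": r, "p": p}
                except ValueError:
                    cov_corr[covname] = None
            rel_report[name] = {
                "mean_ic": float(np.nanmean(ic_vals)),
                "chosen_k": part.k,
                "ic_covariate_correlations": cov_corr,
                "cluster_tests": {
                    cov: ({"p_bonferroni": res.get("p_bonferroni"),
                           "significant": res.get("significant")}
                          if not res.get("skipped") else {"skipped": True})
                    for cov, res in tests.items()
                },
            }
        if not (resume and _done(out, stage).exists()):
            finish(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    report["stages"]["reliability"] = rel_report
    if stop_after == "reliability":
        _write_report(out, report, manifest)
        return report

    # ---- comparison ----
    stage = "comparison"
    cmp_dir = out / "comparison"
    cmp_dir.mkdir(exist_ok=True)
    try:
        names = list(config.explainers)
        if len(names) >= 2:
            a, b = names[0], names[1]
            agree = cmp.method_agreement(averaged[a], averaged[b])
            pd.DataFrame({
                "subject_id": agree.subject_ids, "r": agree.per_subject_r,
            }).to_csv(cmp_dir / "agreement.tsv", sep="\t", index=False)
        else:
            agree = None
        age_corr = {}
        for name in names:
            res = cmp.score_age_correlation(
                averaged[name], cohort.age,
                feature_names=cohort.feature_names, alpha=config.alpha,
            )
            age_corr[name] = res
            pd.DataFrame({
                "feature": res.feature_names, "r": res.r, "p": res.p,
                "p_bonferroni": res.p_bonferroni, "significant": res.significant,
            }).to_csv(cmp_dir / f"{name}_age_correlation.tsv", sep="\t", index=False)
        cmp_report = {}
        if agree is not None:
            overlap = cmp.overlap_sweep(age_corr[a], age_corr[b])
            overlap = cmp.attach_permutation_pvalues(
                overlap, age_corr[a], age_corr[b],
                n_permutations=config.n_permutations, seed=config.seed + 13,
            )
            pd.DataFrame({
                "upper_pct": [u for u, _ in overlap.thresholds],
                "lower_pct": [l for _, l in overlap.thresholds],
                "jaccard": overlap.jaccard,
                "p": overlap.p_values,
            }).to_csv(cmp_dir / "overlap.tsv", sep="\t", index=False)
            dist = cmp.compare_r_distributions(age_corr[a].r, age_corr[b].r)
            cmp_report = {
                "agreement_mean": agree.mean,
                "agreement_sd": agree.sd,
                "r_distribution_contrast": dist,
                "overlap": {
                    f"{u}/{l}": {"jaccard": float(j), "p": float(p)}
                    for (u, l), j, p in zip(
                        overlap.thresholds, overlap.jaccard, overlap.p_values
                    )
                },
            }
        if not (resume and _done(out, stage).exists()):
            finish(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    report["stages"]["comparison"] = cmp_report

    _write_report(out, report, manifest)
    validate_report(report)
    return report


def _write_report(out: Path, report: dict, manifest: dict) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _schema() -> dict:
    import importlib.resources as res

    with res.files("explainstab").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Structural validation of a report dict against the shipped schema
    (required keys and primitive types; a deliberately small checker)."""
    schema = _schema()

    def check(obj, spec, path="report"):
        typ = spec.get("type")
        if typ == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{path}: expected object")
            for key, sub in spec.get("required_properties", {}).items():
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
                check(obj[key], sub, f"{path}.{key}")
        elif typ == "number":
            if obj is not None and not isinstance(obj, (int, float)):
                raise ValueError(f"{path}: expected number, got {type(obj).__name__}")

    check(report, schema)
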