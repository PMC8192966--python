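"""Multi-site morphometric cohorts: simulation, validation and TSV I/O.

A cohort is a subjects-by-features matrix of morphological descriptors
(thicknesses, surface areas, curvature indices, volumes — units vary per
column) together with per-subject phenotype: acquisition site, chronological
age in years, full-scale IQ (FIQ, possibly missing) and the anatomical
signal-to-noise ratio (SNR) of the scan.

The generator emulates the structure of a multi-site neuroimaging study:
sites of heterogeneous size and age range, a right-skewed overall age
distribution, per-site additive/multiplicative batch effects on every
feature, a planted subset of features with genuine (linear or mildly
quadratic) age dependence, pure-noise features, and per-subject FIQ/SNR
covariates with optional coupling of feature noise to scan quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "GeneratorConfig",
    "GroundTruth",
    "CohortError",
    "ConfigError",
    "LoadError",
    "generate_cohort",
    "load_cohort",
    "write_cohort",
    "abide_like_config",
]


class CohortError(ValueError):
    """A cohort violates one of its structural invariants."""


class ConfigError(ValueError):
    """A generator configuration is internally inconsistent."""


class LoadError(ValueError):
    """A cohort file pair cannot be parsed into a valid cohort."""


@dataclass
class Cohort:
    """Validated subjects-by-features table plus phenotype.

    Attributes
    ----------
    subject_ids : array of str, unique, length T
    features : float array, shape (T, P)
    feature_names : array of str, length P
    age : float array, years, strictly positive
    site : array of str, site label per subject
    fiq : float array, NaN where missing
    snr : float array, strictly positive
    """

    subject_ids: np.ndarray
    features: np.ndarray
    feature_names: np.ndarray
    age: np.ndarray
    site: np.ndarray
    fiq: np.ndarray
    snr: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def sites(self) -> np.ndarray:
        """Unique site labels in first-appearance order."""
        _, idx = np.unique(self.site, return_index=True)
        return self.site[np.sort(idx)]

    def validate(self) -> "Cohort":
        t = self.n_subjects
        if t == 0:
            raise CohortError("cohort is empty (T = 0)")
        ids = [str(s) for s in self.subject_ids]
        if len(set(ids)) != t:
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise CohortError(f"duplicate subject ids: {dupes}")
        if self.features.shape[0] != t:
            raise CohortError(
                f"feature matrix has {self.features.shape[0]} rows for {t} subjects"
            )
        if len(self.feature_names) != self.features.shape[1]:
            raise CohortError("feature_names length does not match feature columns")
        if not np.all(np.isfinite(self.features)):
            i, j = np.argwhere(~np.isfinite(self.features))[0]
            raise CohortError(
                f"non-finite feature value at subject {ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        for name in ("age", "site", "fiq", "snr"):
            if len(getattr(self, name)) != t:
                raise CohortError(f"{name} has length {len(getattr(self, name))}, expected {t}")
        if not np.all(self.age > 0):
            raise CohortError("ages must be strictly positive")
        if not np.all(np.isfinite(self.age)):
            raise CohortError("ages must be finite")
        snr = np.asarray(self.snr, dtype=float)
        if not np.all(np.isfinite(snr)) or not np.all(snr > 0):
            raise CohortError("snr must be finite and > 0")
        return self

    def site_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.site == label)


@dataclass
class GeneratorConfig:
    """Parameters of the multi-site cohort simulator.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 6 sites, T = 300 subjects, P = 60 descriptors of which 10 carry a
    genuine age signal.  ``abide_like_config`` gives the 17-site, 378-subject,
    1,213-feature preset mirroring the public multi-site study this package
    models.
    """

    n_sites: int = 6
    site_sizes: tuple[int, ...] = (50, 50, 50, 50, 50, 50)
    site_age_ranges: tuple[tuple[float, float], ...] = (
        (6.0, 18.0),
        (8.0, 20.0),
        (10.0, 30.0),
        (6.0, 25.0),
        (18.0, 40.0),
        (12.0, 48.0),
    )
    n_features: int = 60
    n_age_features: int = 10
    # slopes in feature-units per year of age, planted on the first
    # n_age_features columns
    age_effect_sizes: tuple[float, ...] = (
        1.0, -1.0, 0.8, -0.8, 1.2, -1.2, 0.6, -0.6, 1.5, -1.5,
    )
    nonlinear_fraction: float = 0.2
    site_offset_sd: float = 0.5
    site_scale_sd: float = 0.05
    noise_sd: float = 1.0
    fiq_mean: float = 112.1
    fiq_sd: float = 11.7
    fiq_missing_sites: tuple[str, ...] = ()
    snr_site_means: tuple[float, ...] = (25.0, 12.0, 18.0, 9.0, 22.0, 15.0)
    snr_sd: float = 2.5
    snr_noise_coupling: float = 0.5
    site_names: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_sites < 2:
            raise ConfigError("n_sites must be >= 2")
        for name in ("site_sizes", "site_age_ranges", "snr_site_means"):
            if len(getattr(self, name)) != self.n_sites:
                raise ConfigError(f"{name} must have one entry per site ({self.n_sites})")
        if any(s < 1 for s in self.site_sizes):
            raise ConfigError("site_sizes entries must be >= 1")
        for lo, hi in self.site_age_ranges:
            if not (0 < lo < hi):
                raise ConfigError(f"site_age_ranges entry ({lo}, {hi}) must satisfy 0 < low < high")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if not (0 <= self.n_age_features <= self.n_features):
            raise ConfigError("n_age_features must lie in [0, n_features]")
        if len(self.age_effect_sizes) != self.n_age_features:
            raise ConfigError("age_effect_sizes must have n_age_features entries")
        if not (0 <= self.nonlinear_fraction <= 1):
            raise ConfigError("nonlinear_fraction must lie in [0, 1]")
        for name in ("site_offset_sd", "site_scale_sd", "noise_sd", "fiq_sd", "snr_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.snr_noise_coupling < 0:
            raise ConfigError("snr_noise_coupling must be >= 0")
        if any(m <= 0 for m in self.snr_site_means):
            raise ConfigError("snr_site_means must be > 0")
        if self.site_names is not None and len(self.site_names) != self.n_sites:
            raise ConfigError("site_names must have one entry per site")
        return self

    @property
    def n_subjects(self) -> int:
        return int(sum(self.site_sizes))


@dataclass
class GroundTruth:
    """What the simulator planted, for downstream recovery checks."""

    planted_feature_indices: np.ndarray
    age_slopes: np.ndarray  # per planted feature, feature-units / year
    quad_coeffs: np.ndarray  # per planted feature; 0 for purely linear ones
    site_offsets: np.ndarray  # (n_sites, P) additive batch offsets
    site_names: np.ndarray


def _site_ages(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Right-skewed ages within [lo, hi]: log-normal offset above the site
    minimum, clipped at the maximum (mass piles near the young end, long
    right tail — the regime of developmental multi-site cohorts)."""
    span = hi - lo
    offset = rng.lognormal(mean=np.log(span / 4.0), sigma=0.6, size=n)
    return np.clip(lo + offset, lo, hi)


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate a multi-site cohort with planted age-related features.

    Planted feature p of subject i is
    ``slope_p * age_i + q_p * (age_i - mid)^2 + offset[site, p] + eps`` with
    ``eps ~ Normal(0, noise_sd * (snr_ref / snr_i) ** snr_noise_coupling)``;
    non-planted features are batch offset plus noise only.  Identical config
    (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites
    site_names = (
        np.asarray(config.site_names)
        if config.site_names is not None
        else np.asarray([f"site{i + 1:02d}" for i in range(n_sites)])
    )
    T, P = config.n_subjects, config.n_features

    site = np.repeat(site_names, config.site_sizes)
    age = np.concatenate(
        [
            _site_ages(rng, n, lo, hi)
            for n, (lo, hi) in zip(config.site_sizes, config.site_age_ranges)
        ]
    )

    snr_mean_per_subject = np.repeat(np.asarray(config.snr_site_means, float), config.site_sizes)
    snr = snr_mean_per_subject + rng.normal(0.0, config.snr_sd, size=T)
    snr = np.maximum(snr, 1.0)  # SNR is a positive quality index

    fiq = config.fiq_mean + rng.normal(0.0, config.fiq_sd, size=T)
    for s in config.fiq_missing_sites:
        fiq[site == s] = np.nan

    k = config.n_age_features
    slopes = np.asarray(config.age_effect_sizes, dtype=float)
    n_quad = int(np.ceil(config.nonlinear_fraction * k)) if k else 0
    quad = np.zeros(k)
    if n_quad:
        # mild curvature: at the edge of the overall age span the quadratic
        # term is ~25% of the linear term's span
        lo_all = min(r[0] for r in config.site_age_ranges)
        hi_all = max(r[1] for r in config.site_age_ranges)
        half_span = (hi_all - lo_all) / 2.0
        quad[:n_quad] = 0.25 * slopes[:n_quad] / half_span
    age_mid = float(np.mean(age))

    signal = np.zeros((T, P))
    if k:
        signal[:, :k] = age[:, None] * slopes[None, :] + quad[None, :] * (
            (age[:, None] - age_mid) ** 2
        )

    site_offsets = rng.normal(0.0, config.site_offset_sd, size=(n_sites, P))
    site_scales = np.exp(rng.normal(0.0, config.site_scale_sd, size=(n_sites, P)))
    site_idx = np.repeat(np.arange(n_sites), config.site_sizes)

    snr_ref = float(np.mean(config.snr_site_means))
    noise_scale = config.noise_sd * (snr_ref / snr) ** config.snr_noise_coupling
    noise = rng.normal(0.0, 1.0, size=(T, P)) * noise_scale[:, None]

    features = site_scales[site_idx] * (signal + noise) + site_offsets[site_idx]

    subject_ids = np.asarray([f"sub-{i + 1:04d}" for i in range(T)])
    feature_names = np.asarray(
        [f"age_feat_{j + 1:03d}" if j < k else f"noise_feat_{j + 1:03d}" for j in range(P)]
    )
    cohort = Cohort(
        subject_ids=subject_ids,
        features=features,
        feature_names=feature_names,
        age=age,
        site=site,
        fiq=fiq,
        snr=snr,
    ).validate()
    truth = GroundTruth(
        planted_feature_indices=np.arange(k),
        age_slopes=slopes.copy(),
        quad_coeffs=quad,
        site_offsets=site_offsets,
        site_names=site_names,
    )
    return cohort, truth


# Table-of-sites preset: 17 acquisition sites, 378 male subjects aged 6-48,
# 1,213 FreeSurfer descriptors; FIQ unavailable at two sites; per-site SNR
# means from the published quality metrics.
_ABIDE_SITES = [
    # (name, n, age_lo, age_hi, snr_mean)
    ("CMU", 2, 21, 25, 42.5),
    ("KKI", 23, 8, 13, 23.9),
    ("Leuven1", 13, 18, 29, 16.0),
    ("Leuven2", 14, 12, 17, 13.5),
    ("MaxMun", 24, 7, 48, 20.2),
    ("NYU", 77, 6, 32, 12.6),
    ("Olin", 13, 10, 23, 18.3),
    ("Pitt", 22, 12, 33, 9.4),
    ("SBL", 14, 20, 42, 6.3),
    ("SDSU", 14, 12, 17, 20.5),
    ("Trinity", 25, 12, 25, 11.3),
    ("UCLA1", 28, 9, 18, 13.8),
    ("UCLA2", 11, 10, 14, 13.8),
    ("UM1", 32, 8, 19, 22.7),
    ("UM2", 17, 13, 29, 24.3),
    ("USM", 43, 8, 40, 20.5),
    ("Yale", 6, 8, 17, 21.5),
]


def abide_like_config(
    n_features: int = 1213, n_age_features: int = 100, seed: int = 0
) -> GeneratorConfig:
    """Full-scale preset: 17 sites, 378 subjects, ages spanning 6-48 years."""
    rng = np.random.default_rng(seed + 1)
    slopes = rng.uniform(0.5, 1.5, size=n_age_features) * rng.choice([-1, 1], n_age_features)
    return GeneratorConfig(
        n_sites=len(_ABIDE_SITES),
        site_names=tuple(s[0] for s in _ABIDE_SITES),
        site_sizes=tuple(s[1] for s in _ABIDE_SITES),
        site_age_ranges=tuple((float(s[2]), float(s[3])) for s in _ABIDE_SITES),
        snr_site_means=tuple(s[4] for s in _ABIDE_SITES),
        n_features=n_features,
        n_age_features=n_age_features,
        age_effect_sizes=tuple(slopes),
        fiq_missing_sites=("Leuven2", "SBL"),
        seed=seed,
    ).validate()


def write_cohort(cohort: Cohort, features_path, phenotype_path) -> None:
    """Write a cohort as a features TSV + phenotype TSV pair.

    Missing FIQ is written as ``NA``.  Floats use shortest round-trip repr so
    ``load_cohort`` reproduces the arrays exactly.
    """
    cohort.validate()
    feat = pd.DataFrame(cohort.features, columns=list(cohort.feature_names))
    feat.insert(0, "subject_id", cohort.subject_ids)
    feat.to_csv(features_path, sep="\t", index=False)
    pheno = pd.DataFrame(
        {
            "subject_id": cohort.subject_ids,
            "site": cohort.site,
            "age": cohort.age,
            "fiq": cohort.fiq,
            "snr": cohort.snr,
        }
    )
    pheno.to_csv(phenotype_path, sep="\t", index=False, na_rep="NA")


def load_cohort(features_path, phenotype_path) -> Cohort:
    """Read and validate a features/phenotype TSV pair written by
    :func:`write_cohort` (or produced externally with the same layout)."""
    feat = pd.read_csv(features_path, sep="\t", dtype={"subject_id": str})
    pheno = pd.read_csv(pheno_path := phenotype_path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in feat.columns:
        raise LoadError(f"features file {features_path} lacks a 'subject_id' column")
    for col in ("subject_id", "site", "age"):
        if col not in pheno.columns:
            raise LoadError(f"phenotype file {pheno_path} lacks mandatory column {col!r}")

    ids = feat["subject_id"].to_numpy(dtype=str)
    if len(set(ids)) != len(ids):
        raise LoadError("duplicate subject ids in features file")
    missing = set(ids) - set(pheno["subject_id"])
    extra = set(pheno["subject_id"]) - set(ids)
    if missing or extra:
        raise LoadError(
            "subject id mismatch between files: "
            f"missing from phenotype {sorted(missing)}, missing from features {sorted(extra)}"
        )
    pheno = pheno.set_index("subject_id").loc[ids].reset_index()

    feature_cols = [c for c in feat.columns if c != "subject_id"]
    matrix = np.empty((len(ids), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        values = pd.to_numeric(feat[col], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            i = int(np.flatnonzero(~np.isfinite(values))[0])
            raise LoadError(
                f"non-numeric or missing feature cell at subject {ids[i]!r}, column {col!r}"
            )
        matrix[:, j] = values

    age = pd.to_numeric(pheno["age"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(age)):
        i = int(np.flatnonzero(~np.isfinite(age))[0])
        raise LoadError(f"missing or non-numeric age for subject {ids[i]!r}")
    fiq = (
        pd.to_numeric(pheno["fiq"], errors="coerce").to_numpy(dtype=float)
        if "fiq" in pheno.columns
        else np.full(len(ids), np.nan)
    )
    snr = (
        pd.to_numeric(pheno["snr"], errors="coerce").to_numpy(dtype=float)
        if "snr" in pheno.columns
        else np.full(len(ids), np.nan)
    )
    if "snr" in pheno.columns and np.any(~np.isfinite(snr)):
        i = int(np.flatnonzero(~np.isfinite(snr))[0])
        raise LoadError(f"missing or non-numeric snr for subject {ids[i]!r}")
    if "snr" not in pheno.columns:
        snr = np.ones(len(ids))  # neutral quality when not recorded

    try:
        return Cohort(
            subject_ids=ids,
            features=matrix,
            feature_names=np.asarray(feature_cols),
            age=age,
            site=pheno["site"].to_numpy(dtype=str),
            fiq=fiq,
            snr=snr,
        ).validate()
    except CohortError as exc:
        raise LoadError(str(exc)) from exc
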