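"""End-to-end orchestration: preprocess -> decompose -> cluster -> label -> model.

The pipeline mirrors the study workflow: every trial is detrended and
low-pass filtered, decomposed into 16 dyadic levels plus approximation, and
reduced to its 17-component relative-energy spectrum.  Only the stable-
eyes-open (SEO) spectra are clustered; clusters are labeled with the
balance-strategy archetype rules, and a multinomial logistic model relates
group membership to the sensorimotor/fall-related-concern covariates with
group 3 as reference.  All conditions flow into the descriptive reports.

Every run is deterministic given the configuration and seed; intermediates
are written to disk alongside a manifest recording the configuration,
per-stage counts and convergence diagnostics.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import fit_clusters, label_archetypes, silhouette_report
from .errors import ParameterError, ValidationError
from .io_preprocess import (
    CONDITIONS,
    COVARIATE_COLUMNS,
    COVARIATE_NAMES,
    load_covariates,
    load_trial,
    preprocess,
    validate_covariates,
)
from .multinomial_model import coefficient_table, fit_multinomial
from .wavelet_features import component_names, modwt, relative_energy

logger = logging.getLogger("swaywave")


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run."""

    fs: float = 3000.0
    cutoff: float = 10.0
    filter_order: int = 4
    detrend_mode: str = "linear"
    levels: int = 16
    wavelet: str = "sym4"
    boundary: str = "periodic"
    k: int = 3
    seed: int = 7
    n_restarts: int = 50
    cluster_method: str = "kmeans"
    clustering_condition: str = "SEO"
    reference_class: str = "group3"
    penalty: float = 0.0
    standardize: bool = False
    predictors: list | None = None
    input_dir: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.boundary != "periodic":
            raise ParameterError("only the periodic (circular) boundary is supported")
        if self.clustering_condition not in CONDITIONS:
            raise ParameterError(
                f"clustering_condition must be one of {CONDITIONS}"
            )
        if not 0 < self.cutoff < self.fs / 2:
            raise ParameterError("cutoff must lie in (0, Nyquist)")
        if self.levels < 1 or self.k < 1 or self.filter_order < 1:
            raise ParameterError("levels, k and filter_order must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    spectra: pd.DataFrame          # subject_id, condition, E_D1..E_approx
    cluster_model: object
    group_labels: object           # GroupLabel
    subject_groups: pd.DataFrame   # subject_id, cluster, group_label
    model_fit: object | None
    coef_tables: dict              # contrast -> DataFrame
    descriptives: pd.DataFrame
    condition_profiles: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def load_trials(input_dir, fs: float) -> list:
    """Read every ``{subject}_{condition}.csv`` trial file under a directory."""
    input_dir = Path(input_dir)
    files = sorted(p for p in input_dir.glob("*.csv")
                   if p.stem.rsplit("_", 1)[-1] in CONDITIONS)
    if not files:
        raise ValidationError(f"no trial files (*_SEO.csv etc.) in {input_dir}")
    trials = []
    for path in files:
        subject, condition = path.stem.rsplit("_", 1)
        trials.append(load_trial(path, fs=fs, condition=condition,
                                 subject_id=subject))
    return trials


def compute_spectra(trials, config: PipelineConfig) -> pd.DataFrame:
    """Preprocess and decompose every trial; one spectrum row per trial."""
    rows = []
    names = component_names(config.levels)
    for trial in trials:
        clean = preprocess(trial, cutoff=config.cutoff, order=config.filter_order,
                           detrend_mode=config.detrend_mode)
        decomp = modwt(clean, levels=config.levels, wavelet=config.wavelet)
        spec = relative_energy(decomp, subject_id=trial.subject_id,
                               condition=trial.condition)
        rows.append({"subject_id": trial.subject_id, "condition": trial.condition,
                     **{f"E_{n}": v for n, v in zip(names, spec.e)}})
    return pd.DataFrame(rows)


def descriptive_report(covariates: pd.DataFrame, group_col: str = "group_label"
                       ) -> pd.DataFrame:
    """Per-group mean/sd of every covariate plus the pooled column.

    One row per variable x1..x24; group sizes are stored in ``attrs['n']``.
    x24 is a 0/1 indicator, so its mean is the falls-history proportion.
    """
    if group_col not in covariates.columns:
        raise ValidationError(f"covariates must contain {group_col!r}")
    groups = sorted(covariates[group_col].astype(str).unique())
    rows = []
    sizes = {g: int((covariates[group_col] == g).sum()) for g in groups}
    sizes["all"] = len(covariates)
    for col in COVARIATE_COLUMNS:
        row = {"variable": col, "name": COVARIATE_NAMES[col]}
        for g in groups:
            vals = covariates.loc[covariates[group_col] == g, col]
            row[f"{g}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{g}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        row["all_mean"] = covariates[col].mean()
        row["all_sd"] = covariates[col].std(ddof=1)
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["n"] = sizes
    return report


def condition_response(spectra: pd.DataFrame, labels: dict,
                       levels: int = 16) -> pd.DataFrame:
    """Mean energy profile per (group, condition) plus the dominant level.

    ``labels`` maps subject_id to group.  A (group, condition) cell with no
    spectra is simply absent from the output.
    """
    names = [f"E_{n}" for n in component_names(levels)]
    df = spectra.copy()
    df["group"] = df["subject_id"].map(labels)
    df = df.dropna(subset=["group"])
    rows = []
    for (group, condition), sub in df.groupby(["group", "condition"], sort=True):
        mean = sub[names].mean()
        rows.append({"group": group, "condition": condition,
                     "n_subjects": sub["subject_id"].nunique(),
                     "dominant_level": mean.idxmax()[2:],
                     **mean.to_dict()})
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.spectra.to_csv(out / "spectra.csv", index=False)
    result.subject_groups.to_csv(out / "assignments.csv", index=False)
    for contrast, table in result.coef_tables.items():
        name = f"coef_{contrast}_vs_{result.manifest['config']['reference_class']}.csv"
        table.to_csv(out / name, index=False)
    result.descriptives.to_csv(out / "descriptives.csv", index=False)
    result.condition_profiles.to_csv(out / "condition_profiles.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig, trials=None,
                 covariates: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full analysis on in-memory data or on ``config.input_dir``.

    Subjects without a trial in the clustering condition are excluded from
    clustering and modeling with a logged warning; subjects in clusters no
    archetype rule covers are excluded from the model only.
    """
    if trials is None:
        if config.input_dir is None:
            raise ValidationError("either trials or config.input_dir is required")
        trials = load_trials(config.input_dir, fs=config.fs)
        cov_path = Path(config.input_dir) / "covariates.csv"
        if covariates is None and cov_path.exists():
            covariates = load_covariates(cov_path)
    if not trials:
        raise ValidationError("no trials to analyze")
    if covariates is not None:
        covariates = validate_covariates(covariates)

    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stages": {}}
    logger.info("stage preprocess+decompose: %d trials", len(trials))
    spectra = compute_spectra(trials, config)
    manifest["stages"]["spectra"] = {"n_trials": len(spectra)}

    seo = spectra[spectra["condition"] == config.clustering_condition]
    all_subjects = spectra["subject_id"].unique()
    missing = sorted(set(all_subjects) - set(seo["subject_id"]))
    if missing:
        logger.warning("excluding %d subjects without a %s trial: %s",
                       len(missing), config.clustering_condition, missing)
    if seo.empty:
        raise ValidationError(
            f"no {config.clustering_condition} trials available for clustering"
        )
    energy_cols = [c for c in spectra.columns if c.startswith("E_")]
    model = fit_clusters(
        seo[energy_cols].to_numpy(),
        k=config.k,
        seed=config.seed,
        n_restarts=config.n_restarts,
        method=config.cluster_method,
        subject_ids=list(seo["subject_id"]),
    )
    labels = label_archetypes(model)
    subject_groups = pd.DataFrame(
        {
            "subject_id": model.subject_ids,
            "cluster": model.labels_,
            "group_label": [labels.mapping[int(c)] for c in model.labels_],
        }
    )
    manifest["stages"]["clustering"] = {
        "n_subjects": len(subject_groups),
        "excluded_no_seo": missing,
        "wcss": model.wcss,
        "method": model.method,
        "label_evidence": labels.rule_evidence,
    }
    if 2 <= model.k <= len(subject_groups) - 1:
        sil = silhouette_report(model, seo[energy_cols].to_numpy())
        manifest["stages"]["clustering"]["silhouette"] = sil["per_cluster"]

    model_fit = None
    coef_tables: dict = {}
    descriptives = pd.DataFrame()
    if covariates is not None:
        merged = covariates.merge(subject_groups, on="subject_id", how="inner")
        labeled = merged[merged["group_label"] != "unclassified"]
        dropped = len(merged) - len(labeled)
        if dropped:
            logger.warning("excluding %d subjects in unclassified clusters "
                           "from the model", dropped)
        model_fit = fit_multinomial(
            labeled,
            reference=config.reference_class,
            standardize=config.standardize,
            penalty=config.penalty,
            group_col="group_label",
            predictors=config.predictors,
        )
        if not model_fit.converged:
            logger.warning("multinomial fit did not converge: %s", model_fit.message)
        for contrast in model_fit.classes:
            coef_tables[contrast] = coefficient_table(model_fit, contrast)
        descriptives = descriptive_report(merged, group_col="group_label")
        manifest["stages"]["model"] = {
            "n_obs": model_fit.n_obs,
            "converged": model_fit.converged,
            "message": model_fit.message,
            "penalty": model_fit.penalty,
            "loglik": model_fit.loglik,
        }
        manifest["stages"]["descriptives"] = {"group_sizes": descriptives.attrs["n"]}

    profiles = condition_response(
        spectra, dict(zip(subject_groups["subject_id"],
                          subject_groups["group_label"])),
        levels=config.levels,
    )

    result = PipelineResult(
        spectra=spectra,
        cluster_model=model,
        group_labels=labels,
        subject_groups=subject_groups,
        model_fit=model_fit,
        coef_tables=coef_tables,
        descriptives=descriptives,
        condition_profiles=profiles,
        manifest=manifest,
    )
    if config.out_dir:
        _write_outputs(result, config.out_dir)
    return result
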