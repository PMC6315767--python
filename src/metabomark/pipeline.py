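"""End-to-end workflow: filter → transform → scale → model → validate → select.

:func:`run_pipeline` reproduces the full biomarker-discovery workflow on a
feature table: QC-RSD and missingness filtering, log2 transform, half-minimum
imputation and Pareto scaling, a pairwise OPLS-DA model per configured group
pair with permutation and CV-ANOVA validation, and — only for pairs whose
model is both valid and significant — the marker filtration cascade.

All randomness flows from a single seed; each stochastic stage derives its
own stream by hashing the stage name, so adding a pair never perturbs the
others.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .markers import CascadeConfig, MarkerReport, select_markers
from .opls import evaluate_fit, fit_oplsda
from .preprocess import (
    filter_by_missingness,
    filter_by_rsd,
    impute_half_minimum,
    log2_transform,
    pareto_scale,
)
from .tables import FeatureTable
from .validation import ModelVerdict, assess_model, cv_anova, permutation_test

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "derive_seed", "fit_pair"]

log = logging.getLogger("metabomark")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2³¹, derived by hashing."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of the full workflow (YAML-loadable)."""

    group_pairs: list[tuple[str, str]] | None = None  # None = all pairs
    rsd_threshold: float = 30.0
    max_missing: float = 0.20
    n_ortho: int = 1
    n_folds: int = 7
    n_perm: int = 999
    seed: int = 0
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cascade = CascadeConfig(**raw.pop("cascade", {}))
        pairs = raw.pop("group_pairs", None)
        if pairs is not None:
            pairs = [tuple(p) for p in pairs]
        return cls(group_pairs=pairs, cascade=cascade, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["group_pairs"] is not None:
            d["group_pairs"] = [list(p) for p in d["group_pairs"]]
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class ReportBundle:
    """Everything a run produces, ready to serialise as CSV/JSON."""

    rsd_report: pd.DataFrame
    missingness_report: pd.DataFrame
    verdicts: pd.DataFrame
    markers: dict[str, MarkerReport]
    metadata: dict
    partial: bool = False
    errors: list[str] = field(default_factory=list)

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rsd_report.to_csv(out / "rsd_filter_report.csv")
        self.missingness_report.to_csv(out / "missingness_filter_report.csv")
        self.verdicts.to_csv(out / "model_verdicts.csv", index=False)
        for pair, report in self.markers.items():
            report.frame().to_csv(out / f"markers_{pair.replace(' ', '_')}.csv")
        pd.Series(self.metadata).to_json(out / "run_metadata.json", indent=1)


def verdict_row(v: ModelVerdict) -> dict:
    return {
        "model": v.model_name,
        "r2x_cum": v.r2x_cum,
        "r2": v.r2,
        "q2": v.q2,
        "permutation_pass": v.permutation_pass,
        "r2_minus_q2": v.r2_minus_q2,
        "valid": v.valid,
        "p_cv_anova": v.p_cv_anova,
        "significant": v.significant,
    }


def fit_pair(
    log2_table: FeatureTable,
    group_a: str,
    group_b: str,
    n_ortho: int = 1,
    n_folds: int = 7,
):
    """Pareto-scale the two-group submatrix of a log2 table (after
    half-minimum imputation) and fit + cross-validate its OPLS-DA model.

    Returns ``(model, fit, X_scaled, pair_table)``.
    """
    pair = log2_table.pair(group_a, group_b)
    complete = impute_half_minimum(pair.values, log_scale=True)
    scaled = pareto_scale(complete)
    y = pair.groups.to_numpy()
    model = fit_oplsda(scaled.values, y, n_ortho=n_ortho)
    fit = evaluate_fit(scaled.values, y, n_ortho=n_ortho, n_folds=n_folds)
    return model, fit, scaled.values, pair


def run_pipeline(table: FeatureTable, config: PipelineConfig) -> ReportBundle:
    """Execute the full workflow on a feature table.

    Fails fast on an invalid configuration (e.g. zero permutations); a
    failure inside one pairwise model is logged and leaves the bundle marked
    partial instead of aborting the other pairs.
    """
    if config.n_perm < 1:
        raise ValueError("n_perm must be >= 1; validation cannot be skipped")
    config.cascade.validate()

    n0 = table.n_features
    table, rsd_report = filter_by_rsd(table, config.rsd_threshold)
    log.info("RSD filter: %d -> %d features", n0, table.n_features)
    n1 = table.n_features
    table, miss_report = filter_by_missingness(table, config.max_missing)
    log.info("missingness filter: %d -> %d features", n1, table.n_features)

    log2_table = log2_transform(table.biological(), zeros="missing")

    group_order = list(dict.fromkeys(log2_table.groups))
    pairs = config.group_pairs or list(combinations(group_order, 2))

    rows = []
    marker_reports: dict[str, MarkerReport] = {}
    errors: list[str] = []
    for a, b in pairs:
        name = f"{a} vs {b}"
        try:
            model, fit, X, pair = fit_pair(
                log2_table, a, b, n_ortho=config.n_ortho, n_folds=config.n_folds
            )
            perm = permutation_test(
                X,
                pair.groups.to_numpy(),
                n_ortho=config.n_ortho,
                n_perm=config.n_perm,
                seed=derive_seed(config.seed, f"perm:{name}"),
                n_folds=config.n_folds,
            )
            verdict = assess_model(fit, perm, cv_anova(fit), model_name=name)
            rows.append(verdict_row(verdict))
            log.info(
                "%s: R2=%.2f Q2=%.2f valid=%s significant=%s",
                name, verdict.r2, verdict.q2, verdict.valid, verdict.significant,
            )
            if verdict.valid and verdict.significant:
                marker_reports[name] = select_markers(
                    pair, model, fit, config.cascade, group_a=a, group_b=b
                )
                log.info(
                    "%s: %d markers selected", name, len(marker_reports[name].selected)
                )
        except Exception as exc:  # keep going; mark the bundle partial
            log.error("pair %s failed: %s", name, exc)
            errors.append(f"{name}: {exc}")

    bundle = ReportBundle(
        rsd_report=rsd_report,
        missingness_report=miss_report,
        verdicts=pd.DataFrame(rows),
        markers=marker_reports,
        metadata={
            "seed": config.seed,
            "version": __version__,
            "n_perm": config.n_perm,
            "n_ortho": config.n_ortho,
            "n_folds": config.n_folds,
            "config_hash": hashlib.sha256(repr(asdict(config)).encode()).hexdigest()[:16],
        },
        partial=bool(errors),
        errors=errors,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
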