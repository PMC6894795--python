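"""Single-study pipeline and the batch runner.

``run_study`` chains the whole method for one study summary: population
simulation -> VIF screen and model-kind choice -> stratified split -> fit
(nested CV) -> held-out test ROC/AUROC -> heritability by both routes.
``run_batch`` maps it over many studies with per-study failure isolation
and order-independent seeding, and aggregates an AUROC histogram, summary
statistics, and the correlation between AUROC^2 and the summary-statistic
heritability.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .heritability import HeritabilityEstimate, pawitan_h2
from .modeling import (
    FittedRiskModel,
    choose_model_kind,
    compute_vif,
    fit_risk_model,
    predict_risk,
    split_population,
)
from .popsim import SimulatedPopulation, simulate_population
from .rocstats import ROCCurve, roc_curve
from .study_io import StudySummary, check_eligibility

__all__ = [
    "RunConfig",
    "StudyResult",
    "BatchResult",
    "EligibilityError",
    "run_study",
    "run_batch",
    "derive_study_seed",
]

logger = logging.getLogger("sumroc")


class EligibilityError(ValueError):
    """Raised when an ineligible study is run without an override."""

    def __init__(self, study_id: str, reasons):
        self.reasons = tuple(reasons)
        super().__init__(f"study {study_id} ineligible: {', '.join(self.reasons)}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a single-study run (and per-study batch defaults)."""

    seed: int = 0
    coding: str = "dominant"
    train_fraction: float = 0.7
    outer_folds: int = 3
    inner_folds: int = 2
    penalty_grid: Optional[tuple[float, ...]] = None
    scale: int = 1
    min_case: int = 1000
    min_control: int = 1000
    enforce_eligibility: bool = True


@dataclass
class StudyResult:
    """Everything computed for one study, ready for report writing."""

    study: StudySummary
    config: RunConfig
    model: FittedRiskModel
    curve: ROCCurve
    population: SimulatedPopulation
    heritability: HeritabilityEstimate
    warnings: tuple[str, ...] = ()

    @property
    def study_id(self) -> str:
        return self.study.study_id

    @property
    def auroc(self) -> float:
        return self.curve.auroc

    def row(self) -> dict:
        """Flat per-study record for the batch results table."""
        return {
            "study_id": self.study.study_id,
            "phenotype": self.study.phenotype,
            "n_case": self.study.n_case,
            "n_control": self.study.n_control,
            "n_snps": self.study.n_snps,
            "model_kind": self.model.model_kind,
            "ridge_penalty": self.model.ridge_penalty,
            "cv_auroc": self.model.cv_auroc,
            "auroc": self.auroc,
            "var_g": self.heritability.var_g,
            "h2_pawitan": self.heritability.h2_pawitan,
            "h2_auroc": self.heritability.h2_auroc,
            "somers_d": self.heritability.somers_d,
            "seed": self.config.seed,
            "warnings": ";".join((*self.warnings, *self.model.warnings)),
        }


@dataclass
class BatchResult:
    """Batch rows plus the aggregate views of the AUROC distribution."""

    rows: pd.DataFrame
    failures: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin_edges) of the predicted AUROCs at bin width 0.01."""
        edges = np.round(np.arange(0.0, 1.0 + 0.01, 0.01), 10)
        counts, _ = np.histogram(self.rows["auroc"], bins=edges)
        return counts, edges

    @property
    def summary(self) -> dict:
        aurocs = self.rows["auroc"]
        return {
            "n_studies": int(len(self.rows)),
            "mean_auroc": float(aurocs.mean()) if len(aurocs) else float("nan"),
            "median_auroc": float(aurocs.median()) if len(aurocs) else float("nan"),
            "n_auroc_ge_0.7": int((aurocs >= 0.7).sum()),
            "n_auroc_ge_0.8": int((aurocs >= 0.8).sum()),
        }

    @property
    def auroc_sq_h2_correlation(self) -> float:
        """Pearson r between AUROC^2 and the summary-statistic h2 across
        successful rows (NaN for fewer than two rows)."""
        if len(self.rows) < 2:
            return float("nan")
        return float(np.corrcoef(self.rows["auroc"] ** 2, self.rows["h2_pawitan"])[0, 1])


def derive_study_seed(master_seed: int, study_id: str) -> int:
    """Deterministic, order-independent per-study seed below 2^31."""
    mix = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(study_id.encode("utf-8"))]
    )
    return int(mix.generate_state(1)[0] % (2**31))


def run_study(study: StudySummary, config: Optional[RunConfig] = None) -> StudyResult:
    """Run the full summary-to-AUROC pipeline for one study."""
    cfg = RunConfig() if config is None else config
    notes: list[str] = []
    report = check_eligibility(study, cfg.min_case, cfg.min_control)
    if not report.eligible:
        if cfg.enforce_eligibility:
            raise EligibilityError(study.study_id, report.reasons)
        notes.append(f"eligibility_override:{','.join(report.reasons)}")
    rng = np.random.default_rng(cfg.seed)
    pop = simulate_population(study, cfg.coding, rng, cfg.scale)
    pop.seed = cfg.seed

    if study.n_snps >= 2:
        vifs = compute_vif(pop.features)
        kind = choose_model_kind(vifs)
    else:
        vifs = None  # single-SNP panels skip the screen
        kind = "standard"

    train, test = split_population(pop, cfg.train_fraction, rng)
    model = fit_risk_model(
        train,
        kind=kind,
        penalty_grid=cfg.penalty_grid,
        cv=(cfg.outer_folds, cfg.inner_folds),
        rng=rng,
    )
    model.vif_values = vifs
    scores = predict_risk(model, test.features)
    curve = roc_curve(scores, test.labels)
    model.test_auroc = curve.auroc
    herit = pawitan_h2(study.snps, auroc=curve.auroc)
    logger.info(
        "run_study: %s kind=%s auroc=%.4f h2_pawitan=%.4f h2_auroc=%.4f",
        study.study_id, model.model_kind, curve.auroc,
        herit.h2_pawitan, herit.h2_auroc,
    )
    return StudyResult(
        study=study,
        config=cfg,
        model=model,
        curve=curve,
        population=pop,
        heritability=herit,
        warnings=tuple(notes),
    )


def run_batch(
    studies: Sequence[StudySummary], config: Optional[RunConfig] = None
) -> BatchResult:
    """Run many studies with per-study seeds derived from the master seed
    and the study id (so results do not depend on batch order)."""
    cfg = RunConfig() if config is None else config
    rows = []
    failures = []
    warnings = []
    for study in studies:
        study_cfg = replace(cfg, seed=derive_study_seed(cfg.seed, study.study_id))
        try:
            rows.append(run_study(study, study_cfg).row())
        except Exception as exc:
            failures.append({"study_id": study.study_id, "error": repr(exc)})
            logger.warning("run_batch: %s failed: %r", study.study_id, exc)
    if not rows:
        warnings.append("no eligible studies produced results")
    columns = [
        "study_id", "phenotype", "n_case", "n_control", "n_snps", "model_kind",
        "ridge_penalty", "cv_auroc", "auroc", "var_g", "h2_pawitan", "h2_auroc",
        "somers_d", "seed", "warnings",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return BatchResult(rows=df, failures=failures, warnings=warnings)
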