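"""Synthetic individual-level studies with known truth, and the validation
experiment comparing true vs. summary-predicted AUROC.

The generator emulates a raw case-control genotype study: per SNP, a
control risk-allele frequency f and an allelic odds ratio OR define the
case-group frequency

    f_case = OR * f / (1 - f + OR * f),

and genotypes are drawn as two independent allele draws per individual at
the group's frequency (Hardy-Weinberg within each group), with SNPs
independent.  Summarizing such a study back to OR/RAF yields exactly the
input the summary-level pipeline consumes, so "true" AUROC (logistic
regression on the raw genotypes) can be compared with the "predicted"
AUROC (the full simulation + modelling pipeline run on the summary alone),
with no access to external genotype resources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .batch import RunConfig, run_study
from .modeling import fit_risk_model, predict_risk, split_population
from .popsim import CODINGS, SimulatedPopulation, snp_coding
from .rocstats import ROCCurve, delong_test, roc_curve
from .study_io import SNPSummary, StudySummary

__all__ = [
    "IndividualStudy",
    "ValidationDesign",
    "ValidationReport",
    "gen_individual_study",
    "summarize_individual_study",
    "binarize_genotypes",
    "true_auroc",
    "run_validation",
]

logger = logging.getLogger("sumroc")


@dataclass
class IndividualStudy:
    """A raw case-control genotype study with known generating truth.

    ``genotypes`` holds risk-allele counts 0/1/2 (individuals x SNPs),
    ``labels`` 1 for cases, 0 for controls; ``truth`` is the per-SNP
    (control allele frequency, allelic OR) used to generate it.
    """

    genotypes: np.ndarray
    labels: np.ndarray
    truth: tuple[tuple[float, float], ...]
    seed: Optional[int] = None

    @property
    def n_case(self) -> int:
        return int(self.labels.sum())

    @property
    def n_control(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class ValidationDesign:
    """Design space for the validation experiment.

    Defaults are the standing study conditions: 2000 cases / 3000 controls
    per study, panels of 1-10 SNPs, allelic ORs uniform on [1.1, 3.0],
    control RAFs uniform on [0.05, 0.95], cycling through the four
    inheritance schemes.
    """

    n_case: int = 2000
    n_control: int = 3000
    snp_range: tuple[int, int] = (1, 10)
    or_range: tuple[float, float] = (1.1, 3.0)
    raf_range: tuple[float, float] = (0.05, 0.95)
    codings: tuple[str, ...] = CODINGS
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_case < 1000 or self.n_control < 1000:
            raise ValueError("validation arms must have >= 1000 individuals")
        for c in self.codings:
            if c not in CODINGS:
                raise ValueError(f"unknown coding {c!r}")


@dataclass
class ValidationReport:
    """Per-study rows plus aggregates of the true-vs-predicted comparison."""

    rows: pd.DataFrame
    failures: list = field(default_factory=list)

    @property
    def mean_abs_difference(self) -> float:
        return float(self.rows["abs_difference"].mean())

    @property
    def max_abs_difference(self) -> float:
        return float(self.rows["abs_difference"].max())

    @property
    def mean_delong_p(self) -> float:
        return float(self.rows["delong_p"].mean())

    @property
    def fraction_not_rejected(self) -> float:
        """Fraction of studies whose true and predicted ROC curves do not
        differ significantly at the 0.05 level."""
        return float((self.rows["delong_p"] > 0.05).mean())

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6g")


def gen_individual_study(
    n_case: int,
    n_control: int,
    snp_params: Sequence[tuple[float, float]],
    rng: Optional[np.random.Generator] = None,
) -> IndividualStudy:
    """Draw a raw genotype study; controls (label 0) first, then cases."""
    if n_case < 2 or n_control < 2:
        raise ValueError("n_case and n_control must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    p = len(snp_params)
    genotypes = np.empty((n_control + n_case, p), dtype=np.uint8)
    for j, (f, oratio) in enumerate(snp_params):
        if not (0.0 < f < 1.0):
            raise ValueError(f"SNP {j}: control allele frequency must be in (0, 1)")
        if oratio <= 0:
            raise ValueError(f"SNP {j}: odds ratio must be > 0")
        f_case = oratio * f / (1.0 - f + oratio * f)
        genotypes[:n_control, j] = rng.binomial(2, f, size=n_control)
        genotypes[n_control:, j] = rng.binomial(2, f_case, size=n_case)
    labels = np.concatenate(
        [np.zeros(n_control, dtype=np.int8), np.ones(n_case, dtype=np.int8)]
    )
    return IndividualStudy(
        genotypes=genotypes,
        labels=labels,
        truth=tuple((float(f), float(o)) for f, o in snp_params),
    )


def summarize_individual_study(
    study: IndividualStudy, study_id: str = "synthetic", phenotype: str = "synthetic"
) -> StudySummary:
    """Reduce raw genotypes to the summary statistics a GWA study reports.

    Per SNP: RAF = control risk-allele count / (2 * n_control); OR from the
    2x2 allele table with a Haldane-Anscombe 0.5 correction when any cell
    is zero; p-value from the chi-square test on the allele table.
    """
    ctrl = study.genotypes[study.labels == 0]
    case = study.genotypes[study.labels == 1]
    n_control, n_case = len(ctrl), len(case)
    snps = []
    for j in range(study.n_snps):
        hs = int(ctrl[:, j].sum())
        hn = 2 * n_control - hs
        ds = int(case[:, j].sum())
        dn = 2 * n_case - ds
        if min(hs, hn, ds, dn) == 0:
            oratio = ((ds + 0.5) * (hn + 0.5)) / ((dn + 0.5) * (hs + 0.5))
        else:
            oratio = (ds * hn) / (dn * hs)
        table = np.array([[ds, dn], [hs, hn]], dtype=float)
        if table.sum(axis=0).min() == 0:
            pval = 1.0  # a zero column: no information in the table
        else:
            pval = float(stats.chi2_contingency(table, correction=False)[1])
        snps.append(
            SNPSummary(
                snp_id=f"snp{j + 1}",
                odds_ratio=float(oratio),
                raf=hs / (2 * n_control),
                p_value=pval,
            )
        )
    return StudySummary(
        study_id=study_id,
        phenotype=phenotype,
        n_case=n_case,
        n_control=n_control,
        snps=tuple(snps),
    )


def binarize_genotypes(study: IndividualStudy, coding: str) -> SimulatedPopulation:
    """Binarize 0/1/2 genotypes under an inheritance coding to the carrier
    matrix the risk models consume."""
    features = np.empty_like(study.genotypes)
    for j in range(study.n_snps):
        if snp_coding(coding, j) == "dominant":
            features[:, j] = (study.genotypes[:, j] >= 1).astype(np.uint8)
        else:
            features[:, j] = (study.genotypes[:, j] == 2).astype(np.uint8)
    return SimulatedPopulation(
        features=features, labels=study.labels, coding=coding, seed=study.seed
    )


def true_auroc(
    study: IndividualStudy,
    coding: str = "dominant",
    split_fraction: float = 0.7,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, ROCCurve]:
    """Ground-truth discrimination of the raw study: binarize genotypes
    under ``coding``, fit standard logistic regression on a stratified
    train split, return the held-out test ROC/AUROC."""
    rng = np.random.default_rng() if rng is None else rng
    pop = binarize_genotypes(study, coding)
    train, test = split_population(pop, split_fraction, rng)
    model = fit_risk_model(train, kind="standard", rng=rng)
    curve = roc_curve(predict_risk(model, test.features), test.labels)
    return curve.auroc, curve


def run_validation(
    n_studies: int = 20,
    design: Optional[ValidationDesign] = None,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> ValidationReport:
    """Run the full true-vs-predicted AUROC validation experiment.

    For each generated study: the true AUROC is computed from the raw
    genotypes; the study is summarized to OR/RAF; the summary-level
    pipeline produces the predicted AUROC; the two ROC curves are compared
    with the unpaired DeLong test.  A failed study is recorded in
    ``failures`` rather than aborting the batch.
    """
    design = ValidationDesign() if design is None else design
    children = np.random.SeedSequence(seed).spawn(n_studies)
    rows = []
    failures = []
    for i in range(n_studies):
        rng = np.random.default_rng(children[i])
        coding = design.codings[i % len(design.codings)]
        try:
            k = int(rng.integers(design.snp_range[0], design.snp_range[1] + 1))
            ors = rng.uniform(*design.or_range, size=k)
            rafs = rng.uniform(*design.raf_range, size=k)
            istudy = gen_individual_study(
                design.n_case, design.n_control, list(zip(rafs, ors)), rng
            )
            t_auc, t_curve = true_auroc(istudy, coding, design.train_fraction, rng)
            summary = summarize_individual_study(istudy, study_id=f"synth{i:03d}")
            cfg = config if config is not None else RunConfig()
            cfg = RunConfig(
                seed=int(rng.integers(2**31)),
                coding=coding,
                train_fraction=design.train_fraction,
                outer_folds=cfg.outer_folds,
                inner_folds=cfg.inner_folds,
                penalty_grid=cfg.penalty_grid,
            )
            result = run_study(summary, cfg)
            _, p = delong_test(t_curve, result.curve)
            rows.append(
                {
                    "study_id": summary.study_id,
                    "coding": coding,
                    "n_snps": k,
                    "true_auroc": t_auc,
                    "predicted_auroc": result.auroc,
                    "abs_difference": abs(t_auc - result.auroc),
                    "delong_p": p,
                }
            )
            logger.info(
                "validation: %s coding=%s true=%.4f predicted=%.4f p=%.3f",
                summary.study_id, coding, t_auc, result.auroc, p,
            )
        except Exception as exc:  # per-study isolation
            failures.append({"study_index": i, "error": repr(exc)})
            logger.warning("validation: study %d failed: %r", i, exc)
    return ValidationReport(rows=pd.DataFrame(rows), failures=failures)
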