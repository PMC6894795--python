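"""Reading, validating and writing study summary files.

A study summary is the sole input to the prediction pipeline: the number of
cases and controls in the source GWA study plus, for each SNP in the risk
panel, an allelic odds ratio (risk vs. non-risk allele) and the risk allele
frequency among control chromosomes.  The on-disk format is a flat CSV with
one row per SNP; study-level fields are repeated on every row.

Required columns: ``study_id``, ``n_case``, ``n_control``, ``snp_id``,
``odds_ratio``, ``raf``.  Optional: ``phenotype``, ``risk_allele``,
``p_value``.  Missing values may be written as an empty field or ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "SNPSummary",
    "StudySummary",
    "EligibilityReport",
    "StudyFormatError",
    "StudyParseError",
    "StudyValidationError",
    "read_study_csv",
    "write_study_csv",
    "check_eligibility",
    "write_outputs",
]

REQUIRED_COLUMNS = ("study_id", "n_case", "n_control", "snp_id", "odds_ratio", "raf")
OPTIONAL_COLUMNS = ("phenotype", "risk_allele", "p_value")

#: failure codes emitted by :func:`check_eligibility`
TOO_FEW_CASES = "too_few_cases"
TOO_FEW_CONTROLS = "too_few_controls"
MISSING_OR = "missing_or"
MISSING_RAF = "missing_raf"
NO_SNPS = "no_snps"


class StudyFormatError(ValueError):
    """The file does not conform to the expected schema (e.g. missing column)."""


class StudyParseError(ValueError):
    """A cell could not be parsed (e.g. non-numeric odds ratio)."""


class StudyValidationError(ValueError):
    """The parsed content violates a study invariant (e.g. duplicate SNP ids)."""


@dataclass(frozen=True)
class SNPSummary:
    """Summary-level record for one SNP in a risk panel.

    ``odds_ratio`` and ``raf`` may be ``None`` when the source row lacked
    them; such studies are flagged by :func:`check_eligibility` and cannot
    be simulated.
    """

    snp_id: str
    odds_ratio: Optional[float]
    raf: Optional[float]
    risk_allele: str = ""
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.odds_ratio is not None and not self.odds_ratio > 0:
            raise StudyValidationError(
                f"SNP {self.snp_id}: odds_ratio must be > 0, got {self.odds_ratio}"
            )
        if self.raf is not None and not (0.0 <= self.raf <= 1.0):
            raise StudyValidationError(
                f"SNP {self.snp_id}: raf must be in [0, 1], got {self.raf}"
            )


@dataclass(frozen=True)
class StudySummary:
    """A GWA study reduced to its summary statistics."""

    study_id: str
    n_case: int
    n_control: int
    snps: tuple[SNPSummary, ...]
    phenotype: str = ""

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise StudyValidationError(
                f"study {self.study_id}: n_case and n_control must be >= 1"
            )
        if not self.snps:
            raise StudyValidationError(f"study {self.study_id}: no SNPs")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StudyValidationError(
                f"study {self.study_id}: duplicate snp_id values {dupes}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass(frozen=True)
class EligibilityReport:
    """Outcome of the study inclusion filters (report-style, never raises)."""

    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        assert self.eligible == (len(self.reasons) == 0)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_study_csv(path) -> StudySummary:
    """Parse a flat one-row-per-SNP study CSV into a :class:`StudySummary`.

    Row order is preserved.  Raises :class:`StudyFormatError` for a missing
    required column, :class:`StudyParseError` for non-numeric OR/RAF cells
    (naming the offending row) and :class:`StudyValidationError` for
    duplicate SNP ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=["", "NA"])
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            code = {"odds_ratio": MISSING_OR, "raf": MISSING_RAF}.get(col)
            raise StudyFormatError(
                f"{path.name}: missing required column '{col}'"
                + (f" ({code})" if code else "")
            )
    if len(df) == 0:
        raise StudyValidationError(f"{path.name}: no SNP rows")

    def parse_cell(row_idx: int, col: str, required_int: bool = False):
        raw = df.at[row_idx, col]
        if pd.isna(raw):
            return None
        try:
            return int(raw) if required_int else float(raw)
        except (TypeError, ValueError):
            raise StudyParseError(
                f"{path.name} row {row_idx + 2}: non-numeric value "
                f"{raw!r} in column '{col}'"
            ) from None

    n_case = parse_cell(0, "n_case", required_int=True)
    n_control = parse_cell(0, "n_control", required_int=True)
    if n_case is None or n_control is None:
        raise StudyParseError(f"{path.name}: n_case/n_control missing on first row")

    snps = []
    for i in range(len(df)):
        snps.append(
            SNPSummary(
                snp_id=str(df.at[i, "snp_id"]),
                odds_ratio=parse_cell(i, "odds_ratio"),
                raf=parse_cell(i, "raf"),
                risk_allele=(
                    "" if "risk_allele" not in df.columns or pd.isna(df.at[i, "risk_allele"])
                    else str(df.at[i, "risk_allele"])
                ),
                p_value=(
                    None if "p_value" not in df.columns else parse_cell(i, "p_value")
                ),
            )
        )
    phenotype = ""
    if "phenotype" in df.columns and not pd.isna(df.at[0, "phenotype"]):
        phenotype = str(df.at[0, "phenotype"])
    return StudySummary(
        study_id=str(df.at[0, "study_id"]),
        n_case=n_case,
        n_control=n_control,
        snps=tuple(snps),
        phenotype=phenotype,
    )


def write_study_csv(study: StudySummary, path) -> Path:
    """Write a :class:`StudySummary` in the flat CSV schema read back by
    :func:`read_study_csv`.  Floats are rendered at 12 significant digits so
    a read → write → read round trip is the identity."""
    path = Path(path)
    rows = []
    for s in study.snps:
        rows.append(
            {
                "study_id": study.study_id,
                "phenotype": study.phenotype,
                "n_case": study.n_case,
                "n_control": study.n_control,
                "snp_id": s.snp_id,
                "risk_allele": s.risk_allele,
                "odds_ratio": s.odds_ratio,
                "raf": s.raf,
                "p_value": s.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g", na_rep="NA")
    return path


def check_eligibility(
    study: StudySummary, min_case: int = 1000, min_control: int = 1000
) -> EligibilityReport:
    """Apply the study inclusion filters: a minimum of ``min_case`` cases and
    ``min_control`` controls, and an odds ratio and risk allele frequency
    present for every SNP in the panel."""
    reasons: list[str] = []
    if study.n_case < min_case:
        reasons.append(TOO_FEW_CASES)
    if study.n_control < min_control:
        reasons.append(TOO_FEW_CONTROLS)
    if any(s.odds_ratio is None for s in study.snps):
        reasons.append(MISSING_OR)
    if any(s.raf is None for s in study.snps):
        reasons.append(MISSING_RAF)
    return EligibilityReport(eligible=not reasons, reasons=tuple(reasons))


def write_outputs(result, outdir) -> list[Path]:
    """Write the four per-study artifacts and return their paths.

    ``result`` is a completed ``StudyResult`` (see :mod:`sumroc.batch`).
    The artifacts are: a coefficients CSV (intercept + one row per SNP), a
    metrics CSV (threshold / sensitivity / specificity sweep with a final
    AUROC record), the simulated population CSV (one row per individual,
    0/1 per SNP, case/control label) and a ROC curve PNG.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = result.study_id
    snp_ids = [s.snp_id for s in result.study.snps]
    model = result.model
    curve = result.curve

    coef_path = outdir / f"{sid}_coefficients.csv"
    coef_rows = [
        {
            "term": "(intercept)",
            "estimate": model.intercept,
            "model_kind": model.model_kind,
            "penalty": model.ridge_penalty,
        }
    ]
    for snp_id, beta in zip(snp_ids, model.coefficients):
        coef_rows.append(
            {
                "term": snp_id,
                "estimate": beta,
                "model_kind": model.model_kind,
                "penalty": model.ridge_penalty,
            }
        )
    pd.DataFrame(coef_rows).to_csv(coef_path, index=False, float_format="%.12g")

    metrics_path = outdir / f"{sid}_metrics.csv"
    mdf = pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.points[:, 1],
            "specificity": 1.0 - curve.points[:, 0],
        }
    )
    mdf = pd.concat(
        [
            mdf,
            pd.DataFrame(
                [{"threshold": "auroc", "sensitivity": curve.auroc, "specificity": ""}]
            ),
        ],
        ignore_index=True,
    )
    mdf.to_csv(metrics_path, index=False, float_format="%.12g")

    pop_path = outdir / f"{sid}_population.csv"
    pop = result.population
    pdf = pd.DataFrame(pop.features, columns=snp_ids)
    pdf.insert(0, "label", pop.labels)
    pdf.insert(0, "individual_id", [f"{sid}_{i + 1}" for i in range(len(pdf))])
    pdf.to_csv(pop_path, index=False)

    png_path = outdir / f"{sid}_roc.png"
    _plot_roc(curve, sid, png_path)
    return [coef_path, metrics_path, pop_path, png_path]


def _plot_roc(curve, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.points[:, 0], curve.points[:, 1], color="C0", lw=1.5)
    ax.plot([0, 1], [0, 1], color="grey", ls="--", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title}  (AUROC = {curve.auroc:.3f})")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
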