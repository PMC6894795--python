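"""SNP heritability from summary statistics and from the AUROC.

Two routes to the proportion of disease-liability variance explained by a
SNP panel:

* the summary-statistic (Pawitan-style) formula on the logistic liability
  scale,

      var(g) = 2 * sum_k RAF_k * (1 - RAF_k) * (ln OR_k)^2
      h^2    = var(g) / (var(g) + pi^2 / 3)

  where g is the random genetic effect of the panel and pi^2/3 is the
  variance of the standard logistic residual;

* the identity linking heritability to discrimination through Somers'
  rank correlation D = 2 * AUROC - 1:

      h^2 = D^2 = (2 * AUROC - 1)^2,   AUROC = (1 + sqrt(h^2)) / 2.

Logs are natural throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .study_io import SNPSummary

__all__ = [
    "HeritabilityEstimate",
    "genetic_variance",
    "pawitan_h2",
    "auroc_to_h2",
    "h2_to_auroc",
    "round_report",
]

LOGISTIC_RESIDUAL_VARIANCE = math.pi**2 / 3


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Heritability estimates for one study.

    ``h2_auroc`` and ``somers_d`` are NaN until an AUROC is available.
    """

    var_g: float
    h2_pawitan: float
    h2_auroc: float = math.nan
    somers_d: float = math.nan

    def with_auroc(self, auroc: float) -> "HeritabilityEstimate":
        d = 2.0 * auroc - 1.0
        return HeritabilityEstimate(
            var_g=self.var_g,
            h2_pawitan=self.h2_pawitan,
            h2_auroc=d * d,
            somers_d=d,
        )


def genetic_variance(snps: Sequence[SNPSummary]) -> float:
    """Variance of the panel's genetic effect, 2 * sum RAF(1-RAF)(ln OR)^2."""
    total = 0.0
    for s in snps:
        if s.odds_ratio is None or s.raf is None:
            raise ValueError(f"SNP {s.snp_id} lacks OR or RAF")
        if s.odds_ratio <= 0:
            raise ValueError(f"SNP {s.snp_id}: odds_ratio must be > 0")
        total += s.raf * (1.0 - s.raf) * math.log(s.odds_ratio) ** 2
    return 2.0 * total


def pawitan_h2(
    snps: Sequence[SNPSummary], auroc: Optional[float] = None
) -> HeritabilityEstimate:
    """Summary-statistic heritability h^2 = var(g) / (var(g) + pi^2/3);
    strictly increasing in var(g) and always in [0, 1)."""
    var_g = genetic_variance(snps)
    est = HeritabilityEstimate(
        var_g=var_g,
        h2_pawitan=var_g / (var_g + LOGISTIC_RESIDUAL_VARIANCE),
    )
    return est if auroc is None else est.with_auroc(auroc)


def auroc_to_h2(auroc: float) -> float:
    """Heritability from discrimination: (2 * AUROC - 1)^2.

    Symmetric about AUROC = 0.5 (an anti-predictor explains as much
    variance as its reverse)."""
    if not (0.0 <= auroc <= 1.0):
        raise ValueError(f"auroc must be in [0, 1], got {auroc}")
    d = 2.0 * auroc - 1.0
    return d * d


def h2_to_auroc(h2: float) -> float:
    """Inverse of :func:`auroc_to_h2` on the informative branch
    AUROC >= 0.5: (1 + sqrt(h^2)) / 2."""
    if not (0.0 <= h2 <= 1.0):
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    return 0.5 * (1.0 + math.sqrt(h2))


def round_report(value: float, places: int = 3) -> float:
    """Half-up rounding for report tables (Python's round is half-even)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
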