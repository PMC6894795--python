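"""Population simulation from summary statistics.

The core trick of the method: given a study's case/control counts and, per
SNP, the allelic odds ratio OR and control risk allele frequency RAF, the
exact number of risk alleles in each group is determined by

    H_s = ceil(2 * N_control * RAF)            (risk alleles, healthy group)
    H_n = 2 * N_control - H_s
    D_s = ceil(2 * OR * N_case * H_s / (H_n + OR * H_s))
    D_n = 2 * N_case - D_s                     (diseased group)

These allele totals are then distributed over individuals: each group has
2N allele slots, the risk alleles are placed by a uniform random
permutation, and slots are paired into individuals, giving hypergeometric
genotype counts.  A binary feature is derived per individual under an
inheritance coding (dominant: >= 1 risk allele; recessive: both alleles).
SNPs are simulated independently (the panels are assumed LD-free).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .study_io import StudySummary

__all__ = [
    "AlleleCounts",
    "SimulatedPopulation",
    "CODINGS",
    "allele_counts",
    "binarize",
    "carrier_assignment",
    "place_alleles",
    "simulate_population",
    "snp_coding",
]

logger = logging.getLogger("sumroc")

#: supported inheritance codings.  The "odd_*" variants alternate per SNP
#: (1-based SNP index): odd_dominant = odd-indexed SNPs dominant, even
#: recessive; odd_recessive the reverse.
CODINGS = ("dominant", "recessive", "odd_dominant", "odd_recessive")


@dataclass(frozen=True)
class AlleleCounts:
    """Exact per-group risk/non-risk allele counts for one SNP."""

    hs: int  # risk alleles, healthy (control) group
    hn: int  # non-risk alleles, healthy group
    ds: int  # risk alleles, diseased (case) group
    dn: int  # non-risk alleles, diseased group

    def __post_init__(self) -> None:
        assert min(self.hs, self.hn, self.ds, self.dn) >= 0

    @property
    def control_raf(self) -> float:
        return self.hs / (self.hs + self.hn)

    @property
    def case_raf(self) -> float:
        return self.ds / (self.ds + self.dn)

    @property
    def implied_or(self) -> float:
        """Allelic odds ratio implied by the integer counts (differs from the
        input OR only through ceiling rounding)."""
        if self.hs == 0 or self.dn == 0:
            return math.inf
        return (self.ds / self.dn) / (self.hs / self.hn)


@dataclass
class SimulatedPopulation:
    """Binary individuals x SNPs matrix with case/control labels.

    ``features`` holds 0/1 carrier indicators (one column per SNP in study
    order), ``labels`` 1 for cases and 0 for controls.
    """

    features: np.ndarray
    labels: np.ndarray
    coding: str = "dominant"
    seed: Optional[int] = None
    #: the 0/1/2 genotype matrix behind ``features`` where available
    genotypes: Optional[np.ndarray] = None

    @property
    def n_case(self) -> int:
        return int(self.labels.sum())

    @property
    def n_control(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def allele_counts(
    n_control: int, n_case: int, raf: float, odds_ratio: float
) -> AlleleCounts:
    """Evaluate the four allele-count equations with integer ceiling.

    ``ds`` is clamped to ``[0, 2*n_case]``; the clamp can only fire through
    floating-point pathology at extreme OR x RAF and is logged when it does.
    """
    if n_control < 1 or n_case < 1:
        raise ValueError("n_control and n_case must be >= 1")
    if not (0.0 <= raf <= 1.0):
        raise ValueError(f"raf must be in [0, 1], got {raf}")
    if not odds_ratio > 0:
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")

    hs = math.ceil(2 * n_control * raf)
    hn = 2 * n_control - hs
    if hs == 0:
        ds = 0
    else:
        ds = math.ceil(2 * odds_ratio * n_case * hs / (hn + odds_ratio * hs))
    if ds > 2 * n_case:
        logger.warning(
            "allele_counts: ds=%d exceeds 2*n_case=%d (raf=%g, OR=%g); clamping",
            ds, 2 * n_case, raf, odds_ratio,
        )
        ds = 2 * n_case
    dn = 2 * n_case - ds
    return AlleleCounts(hs=hs, hn=hn, ds=ds, dn=dn)


def place_alleles(
    n_individuals: int,
    risk_alleles: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Distribute exactly ``risk_alleles`` risk alleles uniformly at random
    over the ``2*n_individuals`` allele slots of a group and pair slots into
    individuals, returning the 0/1/2 genotype vector (hypergeometric
    risk-allele counts; the allele total is conserved exactly)."""
    if not (0 <= risk_alleles <= 2 * n_individuals):
        raise ValueError(
            f"risk_alleles={risk_alleles} out of range [0, {2 * n_individuals}]"
        )
    rng = np.random.default_rng() if rng is None else rng
    slots = np.zeros(2 * n_individuals, dtype=np.uint8)
    slots[:risk_alleles] = 1
    rng.shuffle(slots)
    return slots.reshape(n_individuals, 2).sum(axis=1, dtype=np.uint8)


def binarize(genotype: np.ndarray, coding: str) -> np.ndarray:
    """0/1 carrier indicator from a 0/1/2 genotype vector under a per-SNP
    coding (dominant: >= 1 risk allele; recessive: both)."""
    if coding == "dominant":
        return (genotype >= 1).astype(np.uint8)
    if coding == "recessive":
        return (genotype == 2).astype(np.uint8)
    raise ValueError(f"unknown per-SNP coding {coding!r}")


def carrier_assignment(
    n_individuals: int,
    risk_alleles: int,
    coding: str = "dominant",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Binary carrier vector from a uniform placement of ``risk_alleles``
    risk alleles over the group's allele slots (see :func:`place_alleles`)."""
    return binarize(place_alleles(n_individuals, risk_alleles, rng), coding)


def snp_coding(coding: str, snp_index: int) -> str:
    """Resolve a panel-level coding to the per-SNP coding for the SNP at
    0-based ``snp_index`` (the alternating schemes count SNPs from 1)."""
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")
    if coding in ("dominant", "recessive"):
        return coding
    odd = (snp_index + 1) % 2 == 1
    if coding == "odd_dominant":
        return "dominant" if odd else "recessive"
    return "recessive" if odd else "dominant"


def simulate_population(
    study: StudySummary,
    coding: str = "dominant",
    rng: Optional[np.random.Generator] = None,
    scale: int = 1,
) -> SimulatedPopulation:
    """Simulate a labelled case/control population from a study summary.

    Controls (label 0) come first, then cases (label 1).  For each SNP the
    exact allele totals from :func:`allele_counts` are placed independently
    within each group, so the realized risk-allele counts reproduce
    ``hs``/``ds`` exactly for every seed.  ``scale`` multiplies both group
    sizes (allele totals are recomputed at the scaled N).
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n_control = study.n_control * scale
    n_case = study.n_case * scale
    features = np.empty((n_control + n_case, study.n_snps), dtype=np.uint8)
    genotypes = np.empty_like(features)
    for j, snp in enumerate(study.snps):
        if snp.odds_ratio is None or snp.raf is None:
            raise ValueError(
                f"SNP {snp.snp_id} lacks OR/RAF; study is not simulatable"
            )
        counts = allele_counts(n_control, n_case, snp.raf, snp.odds_ratio)
        genotypes[:n_control, j] = place_alleles(n_control, counts.hs, rng)
        genotypes[n_control:, j] = place_alleles(n_case, counts.ds, rng)
        features[:, j] = binarize(genotypes[:, j], snp_coding(coding, j))
    labels = np.concatenate(
        [np.zeros(n_control, dtype=np.int8), np.ones(n_case, dtype=np.int8)]
    )
    logger.info(
        "popsim: study=%s n_control=%d n_case=%d snps=%d coding=%s",
        study.study_id, n_control, n_case, study.n_snps, coding,
    )
    return SimulatedPopulation(
        features=features, labels=labels, coding=coding, genotypes=genotypes
    )
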