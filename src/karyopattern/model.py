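"""Closed-form allelic admixture model.

Links an integer allele-copy genotype and a tumor-cell fraction (purity) to
the expected B-allele frequency (BAF) at a germline-heterozygous SNP and to
the expected sequencing-depth ratio against a diploid baseline, plus the
inverse estimators for purity and genome ploidy.

A specimen is modeled as a mixture of one tumor clone (purity ``p``) and
diploid normal cells (``1 - p``).  At a germline het the normal contributes
one A and one B copy; the tumor contributes ``major`` copies of one allele
and ``minor`` of the other:

    BAF  = (p * major + (1 - p)) / (p * (major + minor) + 2 * (1 - p))
    logR = log2( (p * (major + minor) + 2 * (1 - p)) / 2 )

``expected_baf`` returns the B-major orientation (value in [0.5, 1]); the
A-major orientation is its mirror ``1 - BAF``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .arms import CHROMOSOMES

__all__ = [
    "GenotypeState",
    "STATE_UNIVERSE",
    "expected_baf",
    "expected_log2_ratio",
    "estimate_purity",
    "estimate_ploidy",
    "PloidyEstimate",
]


@dataclass(frozen=True)
class GenotypeState:
    """Unordered allele copy pair (major, minor), total copies <= 4.

    Canonical labels follow the field convention: (1,1)=AB, (1,0)=A0/0B,
    (2,0)=AA/BB (copy-neutral LOH or doubled haploid), (2,1)=AAB/ABB
    (single-allele gain), (2,2)=AABB (balanced whole-chromosome gain, the
    heterozygous signature of genome doubling).
    """

    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.major < 0 or self.minor < 0:
            raise ValueError("allele copies must be non-negative")
        if self.major < self.minor:
            raise ValueError("major must be >= minor")
        if self.major + self.minor > 4:
            raise ValueError("total copies above 4 are outside the model")

    @property
    def total(self) -> int:
        return self.major + self.minor

    @property
    def label(self) -> str:
        return _LABELS.get((self.major, self.minor), f"{self.major}+{self.minor}")

    @property
    def is_loh(self) -> bool:
        """True when one parental allele is fully lost (minor == 0, total > 0)."""
        return self.minor == 0 and self.major > 0


_LABELS = {
    (1, 1): "AB",
    (1, 0): "A0/0B",
    (2, 0): "AA/BB",
    (2, 1): "AAB/ABB",
    (2, 2): "AABB",
    (0, 0): "0",
}

#: The five states the caller can assign to a diploid-baseline arm.
STATE_UNIVERSE: tuple[GenotypeState, ...] = (
    GenotypeState(1, 1),
    GenotypeState(1, 0),
    GenotypeState(2, 0),
    GenotypeState(2, 1),
    GenotypeState(2, 2),
)


def _check_purity(purity: float) -> None:
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")


def expected_baf(state: GenotypeState, purity: float) -> float:
    """Expected BAF at a germline het, B-major orientation (in [0.5, 1])."""
    _check_purity(purity)
    num = purity * state.major + (1.0 - purity)
    den = purity * state.total + 2.0 * (1.0 - purity)
    if den == 0.0:
        # total copies 0 at purity 1: no DNA, no BAF
        raise ValueError("zero expected coverage: BAF undefined")
    return num / den


def expected_log2_ratio(state: GenotypeState, purity: float) -> float:
    """Expected log2 depth ratio against the sample's diploid baseline."""
    _check_purity(purity)
    rel = (purity * state.total + 2.0 * (1.0 - purity)) / 2.0
    if rel <= 0.0:
        return float("-inf")
    return math.log2(rel)


def expected_relative_coverage(state: GenotypeState, purity: float,
                               normal_copies: int = 2) -> float:
    """Expected depth relative to the diploid baseline.

    ``normal_copies`` is the germline copy number of the region (1 for the
    male X, 2 elsewhere).
    """
    _check_purity(purity)
    return (purity * state.total + (1.0 - purity) * normal_copies) / 2.0


def estimate_purity(mirrored_baf: float, mechanism: str) -> float:
    """Invert the admixture model on an LOH arm to recover tumor purity.

    For a one-copy loss (state (1,0)) the mirrored BAF is m = 1/(2-p), so
    p = 2 - 1/m.  For copy-neutral LOH (state (2,0)) m = (1+p)/2, so
    p = 2m - 1.  Result clipped to (0, 1].
    """
    if mirrored_baf < 0.5:
        raise ValueError("mirrored BAF below 0.5 is not a valid LOH signal")
    if mirrored_baf > 1.0:
        raise ValueError("mirrored BAF above 1 is impossible")
    if mechanism == "loss":
        p = 2.0 - 1.0 / mirrored_baf
    elif mechanism == "cn_loh":
        p = 2.0 * mirrored_baf - 1.0
    else:
        raise ValueError(f"unknown LOH mechanism {mechanism!r}")
    if p <= 0.0:
        raise ValueError("mirrored BAF implies non-positive purity: uninformative")
    return min(p, 1.0)


@dataclass(frozen=True)
class PloidyEstimate:
    """Mean total copy number per chromosome, equal per-chromosome weights."""

    raw: float

    @property
    def rounded(self) -> float:
        return round(self.raw, 1)


def estimate_ploidy(states: Mapping[str, GenotypeState]) -> PloidyEstimate:
    """Genome ploidy as the equal-weight mean of per-chromosome total copies.

    ``states`` must provide one whole-chromosome state for each of the 23
    chromosomes (1-22 and X).
    """
    missing = [c for c in CHROMOSOMES if c not in states]
    if missing:
        raise ValueError(f"missing chromosomes: {', '.join(missing)}")
    mean = sum(states[c].total for c in CHROMOSOMES) / len(CHROMOSOMES)
    return PloidyEstimate(raw=mean)
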