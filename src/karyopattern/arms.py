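"""Chromosome-arm identifiers for arm-resolution karyotype analysis.

The scoreable genome is autosomes 1-22 plus X, at arm resolution, with the
acrocentric short arms (13p, 14p, 15p, 21p, 22p) excluded because they carry
no scoreable unique sequence.  That leaves exactly 41 arms, the maximum number
of altered arms a single tumor can show.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:-1]

#: Acrocentric short arms with no scoreable loci.
EXCLUDED_P_ARMS: frozenset[str] = frozenset({"13", "14", "15", "21", "22"})

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


@dataclass(frozen=True, order=False)
class ArmId:
    """One scoreable chromosome arm, e.g. ``ArmId('1', 'p')``."""

    chromosome: str
    arm: str

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROM_ORDER:
            raise ValueError(f"invalid chromosome {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"invalid arm {self.arm!r} (must be 'p' or 'q')")
        if self.arm == "p" and self.chromosome in EXCLUDED_P_ARMS:
            raise ValueError(
                f"arm {self.chromosome}p is acrocentric and not scoreable"
            )

    @property
    def sort_key(self) -> tuple[int, int]:
        return (_CHROM_ORDER[self.chromosome], 0 if self.arm == "p" else 1)

    def __str__(self) -> str:
        return f"{self.chromosome}{self.arm}"

    @classmethod
    def parse(cls, text: str) -> "ArmId":
        text = text.strip()
        if not text or text[-1] not in ("p", "q"):
            raise ValueError(f"cannot parse arm id {text!r}")
        return cls(text[:-1], text[-1])


def arm_universe() -> tuple[ArmId, ...]:
    """All 41 scoreable arms in canonical order (1p, 1q, ..., Xp, Xq)."""
    arms = []
    for chrom in CHROMOSOMES:
        if chrom not in EXCLUDED_P_ARMS:
            arms.append(ArmId(chrom, "p"))
        arms.append(ArmId(chrom, "q"))
    return tuple(arms)


ARM_UNIVERSE: tuple[ArmId, ...] = arm_universe()
N_ARMS: int = len(ARM_UNIVERSE)


def arms_of(chromosome: str) -> tuple[ArmId, ...]:
    """Scoreable arms of one chromosome (one arm for acrocentrics)."""
    return tuple(a for a in ARM_UNIVERSE if a.chromosome == chromosome)


def iter_chromosomes() -> Iterator[str]:
    return iter(CHROMOSOMES)
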