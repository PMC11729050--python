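"""Sample-level karyotype synthesis: pattern classes, massive-loss and
genome-doubling detection, purity and ploidy estimates.

Pattern classes partition interpretable samples: Pattern 1, no alterations;
Pattern 2, only loss-tier alterations (copy losses or copy-neutral LOH);
Pattern 3, only gain-tier alterations (single-allele gains or balanced AABB
gains); Pattern 4, both.  Massive-loss genomes — near-haploid (most
chromosomes at single copy) or near-homozygous (most chromosomes at
copy-neutral LOH, the doubled descendant of a near-haploid state) — are
flagged when at least 15 of the 22 autosomes carry chromosome-level LOH.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .arms import AUTOSOMES, CHROMOSOMES, arms_of
from .caller import ArmCall
from .model import GenotypeState, PloidyEstimate, estimate_purity

__all__ = [
    "SampleResult",
    "count_altered_arms",
    "classify_pattern",
    "detect_massive_loss",
    "infer_genome_doubling",
]

#: Minimum LOH'd autosomes for the massive-loss flag: includes the observed
#: near-haploid/near-homozygous cases (16-20 chromosomes) while excluding
#: ordinary Pattern 2 karyotypes (<= 6 chromosomes).
MASSIVE_LOSS_MIN_AUTOSOMES = 15

#: Dominance fraction for calling the massive-loss route (loss vs cn-LOH).
MASSIVE_LOSS_DOMINANCE = 0.60

#: Minimum LOH-tier arms before genome doubling is considered ("multiple
#: arms are affected").
DOUBLING_MIN_LOH_ARMS = 10


@dataclass(frozen=True)
class SampleResult:
    sample_id: str
    pattern: int
    altered_arms: int
    n_loss_tier: int
    n_gain_tier: int
    near_haploid: bool
    near_homozygous: bool
    doubling_inferred: bool
    purity_estimate: float | None
    ploidy_estimate: PloidyEstimate | None

    def __post_init__(self) -> None:
        ok = {
            1: self.altered_arms == 0,
            2: self.n_loss_tier > 0 and self.n_gain_tier == 0,
            3: self.n_gain_tier > 0 and self.n_loss_tier == 0,
            4: self.n_loss_tier > 0 and self.n_gain_tier > 0,
        }
        if self.pattern not in ok:
            raise ValueError(f"pattern must be 1-4, got {self.pattern}")
        if not ok[self.pattern]:
            raise ValueError(
                f"pattern {self.pattern} inconsistent with tier counts "
                f"(loss={self.n_loss_tier}, gain={self.n_gain_tier})"
            )


def _check_unique_arms(calls: list[ArmCall]) -> None:
    seen = set()
    for c in calls:
        if c.arm in seen:
            raise ValueError(f"duplicate arm {c.arm} in calls")
        seen.add(c.arm)


def count_altered_arms(calls: list[ArmCall], count_balanced_gain: bool = True) -> int:
    """Number of arms with any alteration (<= 41); no-calls excluded.

    Male hemizygous X arms count only when their coverage tier changed, which
    is the only mechanism they can carry.  ``count_balanced_gain`` controls
    whether balanced AABB gains are tallied (default yes).
    """
    _check_unique_arms(calls)
    mechanisms = {"loss", "gain", "cn_loh"}
    if count_balanced_gain:
        mechanisms.add("balanced_gain")
    return sum(1 for c in calls if c.mechanism in mechanisms)


def detect_massive_loss(calls: list[ArmCall]) -> tuple[bool, bool, float]:
    """Detect near-haploid / near-homozygous genomes.

    A chromosome is LOH'd when at least one of its scoreable arms carries an
    LOH-tier state ((1,0) or (2,0)).  Returns ``(near_haploid,
    near_homozygous, loh_autosome_fraction)``; either flag requires
    >= 15 of the 22 autosomes LOH'd, with the route decided by whether the
    LOH'd chromosomes are predominantly single-copy (near-haploid) or
    copy-neutral (near-homozygous, post-doubling).
    """
    by_arm = {c.arm: c for c in calls}
    loh_route: list[str] = []  # per-LOH'd-autosome dominant mechanism
    n_loh_autosomes = 0
    for chrom in AUTOSOMES:
        mechanisms = [
            by_arm[a].mechanism
            for a in arms_of(chrom)
            if a in by_arm and by_arm[a].is_loh_tier
        ]
        if mechanisms:
            n_loh_autosomes += 1
            n_loss = sum(1 for m in mechanisms if m == "loss")
            loh_route.append("loss" if n_loss * 2 >= len(mechanisms) else "cn_loh")
    fraction = n_loh_autosomes / len(AUTOSOMES)
    if n_loh_autosomes < MASSIVE_LOSS_MIN_AUTOSOMES:
        return (False, False, fraction)
    frac_loss = loh_route.count("loss") / len(loh_route)
    frac_cnloh = loh_route.count("cn_loh") / len(loh_route)
    return (
        frac_loss >= MASSIVE_LOSS_DOMINANCE,
        frac_cnloh >= MASSIVE_LOSS_DOMINANCE,
        fraction,
    )


def infer_genome_doubling(calls: list[ArmCall]) -> bool:
    """Endoreduplication/genome-doubling inference.

    True when the genome shows multiple LOH-tier arms and either (a) every
    remaining heterozygous arm carries the doubled AABB state, or (b) the
    LOH'd chromosomes are predominantly copy-neutral (AA/BB at diploid
    coverage, the post-doubling signature).
    """
    loh_arms = [c for c in calls if c.is_loh_tier]
    if len(loh_arms) < DOUBLING_MIN_LOH_ARMS:
        return False
    het_arms = [
        c for c in calls
        if c.state is not None and not c.state.is_loh and not c.hemizygous_baseline
    ]
    if het_arms and all(c.state == GenotypeState(2, 2) for c in het_arms):
        return True
    n_cnloh = sum(1 for c in loh_arms if c.mechanism == "cn_loh")
    return n_cnloh / len(loh_arms) >= MASSIVE_LOSS_DOMINANCE


def _ploidy_from_calls(calls: list[ArmCall]) -> PloidyEstimate | None:
    """Equal-weight mean over chromosomes of mean arm total copies."""
    by_arm = {c.arm: c for c in calls}
    totals = []
    for chrom in CHROMOSOMES:
        arm_totals = [
            by_arm[a].state.total
            for a in arms_of(chrom)
            if a in by_arm and by_arm[a].state is not None
        ]
        if not arm_totals:
            return None
        totals.append(sum(arm_totals) / len(arm_totals))
    return PloidyEstimate(raw=sum(totals) / len(totals))


def _purity_from_calls(calls: list[ArmCall]) -> float | None:
    """Median of per-LOH-arm purity estimates; None without LOH arms."""
    estimates = []
    for c in calls:
        if not c.is_loh_tier:
            continue
        m = c.stats.median_mirrored_baf
        if m != m or c.stats.n_informative < 1:  # NaN guard
            continue
        try:
            estimates.append(estimate_purity(m, c.mechanism))
        except ValueError:
            continue
    return statistics.median(estimates) if estimates else None


def classify_pattern(
    calls: list[ArmCall],
    sample_id: str = "",
    count_balanced_gain: bool = True,
) -> SampleResult:
    """Synthesize all per-arm calls into one SampleResult."""
    _check_unique_arms(calls)
    interpretable = [c for c in calls if c.mechanism != "no_call"]
    if not interpretable:
        raise UninterpretableError(f"sample {sample_id}: all arms no-call")
    loss_mechs = {"loss", "cn_loh"}
    gain_mechs = {"gain", "balanced_gain"} if count_balanced_gain else {"gain"}
    n_loss = sum(1 for c in interpretable if c.mechanism in loss_mechs)
    n_gain = sum(1 for c in interpretable if c.mechanism in gain_mechs)
    if n_loss and n_gain:
        pattern = 4
    elif n_loss:
        pattern = 2
    elif n_gain:
        pattern = 3
        if all(c.mechanism == "balanced_gain" for c in interpretable
               if c.mechanism in gain_mechs):
            import warnings

            warnings.warn(
                f"sample {sample_id}: only balanced AABB gains; pattern "
                "polarity is ambiguous, reporting Pattern 3",
                stacklevel=2,
            )
    else:
        pattern = 1
    near_haploid, near_homozygous, _ = detect_massive_loss(interpretable)
    return SampleResult(
        sample_id=sample_id,
        pattern=pattern,
        altered_arms=count_altered_arms(calls, count_balanced_gain),
        n_loss_tier=n_loss,
        n_gain_tier=n_gain,
        near_haploid=near_haploid,
        near_homozygous=near_homozygous,
        doubling_inferred=infer_genome_doubling(interpretable),
        purity_estimate=_purity_from_calls(interpretable),
        ploidy_estimate=_ploidy_from_calls(interpretable),
    )


class UninterpretableError(RuntimeError):
    """All arms of a sample were uncallable."""
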