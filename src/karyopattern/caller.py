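"""Per-arm genotype calling from SNP-panel allele counts.

The caller reduces each arm's loci to two signals — the mirrored B-allele
frequency of the heterozygous-compatible band and the log2 depth ratio
against the sample's own balanced-diploid arms — then classifies the arm by
a two-tier ladder:

* allelic tier: balanced / imbalance / LOH.  LOH is scored when the mirrored
  BAF reaches the 0.75 marking, or when the heterozygous band has emptied
  (at high purity LOH pushes germline hets to BAF 0/1, so a tumor-only panel
  must also score the *deficit* of heterozygous loci).
* coverage tier: loss / neutral / gain from the log2 depth ratio.

Strong tier combinations map directly to allele-copy states (LOH+loss ->
A0/0B, LOH+neutral -> copy-neutral AA/BB, imbalance+gain -> AAB/ABB,
balanced+neutral -> AB).  Weak or contradictory combinations are arbitrated
by the nearest expected (BAF, log2) signature over the state universe at
purities in the caller's design operating range [0.4, 1], with each axis
standardized by its typical arm-level sampling noise — the BAF axis is far
less noisy than the depth axis, and an unscaled distance would let depth
noise override clear allelic evidence.

Depth normalization is tumor-only and two-pass: allelically balanced
autosomal arms anchor the diploid baseline, and when those arms split into
distinct coverage clusters (heterozygous AB arms coexisting with doubled
AABB arms) the lowest cluster is the diploid anchor, mirroring how copy
number "height" is read against the heterozygous chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .arms import ARM_UNIVERSE, ArmId
from .model import (
    GenotypeState,
    expected_baf,
    expected_log2_ratio,
)
from .panel import PanelDesign, SnpObservation

__all__ = [
    "ArmStats",
    "CallThresholds",
    "ArmCall",
    "summarize_arm",
    "classify_arm",
    "call_sample",
    "UninterpretableSampleError",
]


class UninterpretableSampleError(RuntimeError):
    """Raised when too many arms are uncallable (FFPE failure contract)."""


@dataclass(frozen=True)
class CallThresholds:
    """Decision thresholds; defaults are the package's calibrated set.

    ``loh_mbaf`` = 0.75 is the published plot marking; ``imbalance_mbaf`` is
    set so a single-copy gain is scored as imbalance at purity >= 0.4; the
    coverage thresholds detect single-copy events at purity >= 0.4 while
    tolerating FFPE-level depth dispersion.
    """

    imbalance_mbaf: float = 0.58
    loh_mbaf: float = 0.75
    gain_log2: float = 0.13
    loss_log2: float = -0.15
    min_informative: int = 8
    het_deficit_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.5 < self.imbalance_mbaf < self.loh_mbaf <= 1.0):
            raise ValueError("require 0.5 < imbalance_mbaf < loh_mbaf <= 1")
        if not (self.loss_log2 < 0.0 < self.gain_log2):
            raise ValueError("require loss_log2 < 0 < gain_log2")


@dataclass(frozen=True)
class ArmStats:
    """Per-arm summary statistics over one sample's loci."""

    arm: ArmId
    n_loci: int
    n_nonzero: int
    n_informative: int
    het_fraction: float
    expected_het_fraction: float
    median_mirrored_baf: float  # NaN when no informative loci
    median_log2_ratio: float  # NaN when no covered loci
    arm_median_depth: float


@dataclass(frozen=True)
class ArmCall:
    arm: ArmId
    stats: ArmStats
    state: GenotypeState | None
    mechanism: str  # none | loss | gain | cn_loh | balanced_gain | no_call
    hemizygous_baseline: bool = False
    low_confidence: bool = False

    @property
    def label(self) -> str:
        return self.state.label if self.state is not None else "NA"

    @property
    def is_loh_tier(self) -> bool:
        return self.state is not None and self.state.is_loh and self.state.total >= 1 \
            and not self.hemizygous_baseline and self.mechanism in ("loss", "cn_loh")

    @property
    def is_altered(self) -> bool:
        return self.mechanism in ("loss", "gain", "cn_loh", "balanced_gain")


# informative ("heterozygous-compatible") band
MIN_INFORMATIVE_DEPTH = 20
BAF_BAND = (0.05, 0.95)

# typical arm-level noise scales at the default design (36 loci, depth 500,
# dispersion 0.2), used to standardize the arbitration distance
_BAF_NOISE = 0.015
_LOG2_NOISE = 0.06
_ARBITRATION_PURITIES = np.minimum(np.arange(0.40, 1.0001, 0.02), 1.0)


def summarize_arm(
    observations: Sequence[SnpObservation],
    panel: PanelDesign,
    arm: ArmId,
    balanced_depth: float,
) -> ArmStats:
    """Summarize one arm's observations against a diploid baseline depth."""
    loci = panel.loci_on(arm)
    by_id = {o.locus_id: o for o in observations}
    obs = [by_id[loc.locus_id] for loc in loci if loc.locus_id in by_id]
    depths = np.array([o.depth for o in obs], dtype=float)
    nonzero = depths > 0
    n_nonzero = int(nonzero.sum())
    exp_het = float(np.mean([2 * loc.pop_baf * (1 - loc.pop_baf) for loc in loci])) \
        if loci else float("nan")
    if n_nonzero == 0:
        return ArmStats(arm, len(loci), 0, 0, float("nan"), exp_het,
                        float("nan"), float("nan"), float("nan"))
    bafs = np.array([o.baf for o in obs])
    informative = nonzero & (depths >= MIN_INFORMATIVE_DEPTH) \
        & (bafs > BAF_BAND[0]) & (bafs < BAF_BAND[1])
    n_inf = int(informative.sum())
    het_fraction = n_inf / n_nonzero
    if n_inf:
        mirrored = np.maximum(bafs[informative], 1 - bafs[informative])
        med_mbaf = float(np.median(mirrored))
    else:
        med_mbaf = float("nan")
    arm_median_depth = float(np.median(depths[nonzero]))
    med_log2 = float(np.log2(arm_median_depth / balanced_depth)) \
        if balanced_depth > 0 and arm_median_depth > 0 else float("nan")
    return ArmStats(arm, len(loci), n_nonzero, n_inf, het_fraction, exp_het,
                    med_mbaf, med_log2, arm_median_depth)


def _coverage_tier(log2: float, thresholds: CallThresholds) -> str:
    if math.isnan(log2):
        return "neutral"
    if log2 <= thresholds.loss_log2:
        return "loss"
    if log2 >= thresholds.gain_log2:
        return "gain"
    return "neutral"


def _allelic_tier(stats: ArmStats, thresholds: CallThresholds) -> str | None:
    """balanced / imbalance / loh, or None when the arm is uninformative.

    When the heterozygous band holds enough loci, the mirrored BAF decides.
    The het-deficit route fires only when the band is too thin to judge:
    at high purity full LOH pushes every germline het to BAF 0/1, emptying
    the band, and the deficit itself is then the LOH evidence.  (Letting a
    low het fraction override a clearly balanced mirrored BAF would turn
    germline-sampling shortfalls of heterozygous loci into false LOH calls.)
    """
    het_floor = thresholds.het_deficit_fraction * stats.expected_het_fraction
    het_ok = stats.het_fraction >= het_floor
    mbaf = stats.median_mirrored_baf
    if not math.isnan(mbaf) and stats.n_informative >= thresholds.min_informative:
        if mbaf >= thresholds.loh_mbaf:
            return "loh"
        if mbaf < thresholds.imbalance_mbaf:
            return "balanced"
        return "imbalance"
    # heterozygous band empty or too thin: the het deficit itself is the call
    if not het_ok:
        return "loh"
    return None


_MECHANISM_OF_STATE = {
    GenotypeState(1, 1): "none",
    GenotypeState(1, 0): "loss",
    GenotypeState(2, 0): "cn_loh",
    GenotypeState(2, 1): "gain",
    GenotypeState(2, 2): "balanced_gain",
}

_ALLELIC_CANDIDATES = {
    "balanced": (GenotypeState(1, 1), GenotypeState(2, 2)),
    "imbalance": (GenotypeState(1, 0), GenotypeState(2, 0), GenotypeState(2, 1)),
    "loh": (GenotypeState(1, 0), GenotypeState(2, 0)),
}


def _arbitrate(stats: ArmStats, allelic: str) -> GenotypeState:
    """Nearest expected signature among allelically consistent states.

    Distance on (mirrored BAF, log2 ratio), each axis standardized by its
    typical arm-level noise, minimized over purities in [0.4, 1].

    When the heterozygous band is empty (LOH saturated the band), only
    (state, purity) combinations whose expected BAF actually leaves the band
    are admissible — e.g. a one-copy loss at purity 0.4 keeps hets at BAF
    0.625, so it cannot explain an empty band and must not compete on depth
    alone.  If no combination qualifies, all are considered.
    """
    candidates = _ALLELIC_CANDIDATES[allelic]
    mbaf = stats.median_mirrored_baf
    log2 = stats.median_log2_ratio
    band_empty = math.isnan(mbaf)
    pairs = [
        (state, p)
        for state in candidates
        for p in _ARBITRATION_PURITIES
        if not band_empty
        or not (BAF_BAND[0] < expected_baf(state, p) < BAF_BAND[1])
    ]
    if not pairs:
        pairs = [(s, p) for s in candidates for p in _ARBITRATION_PURITIES]
    best, best_d = pairs[0][0], float("inf")
    for state, p in pairs:
        d = 0.0
        if not math.isnan(mbaf):
            ebaf = max(expected_baf(state, p), 1 - expected_baf(state, p))
            d += ((mbaf - ebaf) / _BAF_NOISE) ** 2
        if not math.isnan(log2):
            d += ((log2 - expected_log2_ratio(state, p)) / _LOG2_NOISE) ** 2
        if d < best_d:
            best, best_d = state, d
    return best


def _classify_male_x(stats: ArmStats, thresholds: CallThresholds) -> ArmCall:
    """Male X: hemizygous germline, coverage evidence only.

    The baseline signature is one copy (log2 = -1 against diploid autosomes);
    gains/losses are scored relative to that.  A tier crossing must also be
    nearer to the altered state's expected signature (over purities in the
    operating range) than to the baseline, so depth noise just past the
    threshold does not fabricate X alterations.
    """
    log2 = stats.median_log2_ratio
    delta = log2 - (-1.0)
    tier = _coverage_tier(delta, thresholds)
    if tier != "neutral":
        candidate = GenotypeState(2, 0) if tier == "gain" else GenotypeState(0, 0)
        best, best_d = GenotypeState(1, 0), abs(delta)
        for p in _ARBITRATION_PURITIES:
            rel = (p * candidate.total + (1.0 - p)) / 2.0
            if rel <= 0:
                continue
            d = abs(log2 - math.log2(rel))
            if d < best_d:
                best, best_d = candidate, d
        if best == candidate:
            return ArmCall(stats.arm, stats, candidate,
                           "gain" if tier == "gain" else "loss",
                           hemizygous_baseline=True)
    return ArmCall(stats.arm, stats, GenotypeState(1, 0), "none",
                   hemizygous_baseline=True)


def classify_arm(
    stats: ArmStats, thresholds: CallThresholds, sex: str
) -> ArmCall:
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if stats.n_nonzero == 0 or math.isnan(stats.median_log2_ratio):
        return ArmCall(stats.arm, stats, None, "no_call", low_confidence=True)
    if sex == "male" and stats.arm.chromosome == "X":
        return _classify_male_x(stats, thresholds)

    allelic = _allelic_tier(stats, thresholds)
    if allelic is None:
        return ArmCall(stats.arm, stats, None, "no_call", low_confidence=True)
    coverage = _coverage_tier(stats.median_log2_ratio, thresholds)

    strong = {
        ("loh", "neutral"): GenotypeState(2, 0),
        ("imbalance", "gain"): GenotypeState(2, 1),
        ("balanced", "neutral"): GenotypeState(1, 1),
    }
    key = (allelic, coverage)
    if key in strong:
        state = strong[key]
        return ArmCall(stats.arm, stats, state, _MECHANISM_OF_STATE[state])
    if key == ("imbalance", "loss"):
        # diluted / subclonal one-copy loss; kept integral
        return ArmCall(stats.arm, stats, GenotypeState(1, 0), "loss",
                       low_confidence=True)
    state = _arbitrate(stats, allelic)
    # an arbitration that lands on the naive mapping for its combination is
    # an ordinary confident call; anything rescued across tiers is flagged
    naive = {("loh", "loss"): GenotypeState(1, 0),
             ("balanced", "gain"): GenotypeState(2, 2)}.get(key)
    return ArmCall(stats.arm, stats, state, _MECHANISM_OF_STATE[state],
                   low_confidence=state != naive)


def _balanced_baseline(
    stats_by_arm: dict[ArmId, ArmStats], thresholds: CallThresholds,
    depths_by_arm: dict[ArmId, np.ndarray], fallback: float,
) -> float:
    """Diploid depth anchor from allelically balanced autosomal arms."""
    balanced_arms = []
    for arm, st in stats_by_arm.items():
        if arm.chromosome == "X" or st.n_nonzero == 0:
            continue
        het_floor = thresholds.het_deficit_fraction * st.expected_het_fraction
        if (
            st.n_informative >= thresholds.min_informative
            and not math.isnan(st.median_mirrored_baf)
            and st.median_mirrored_baf < thresholds.imbalance_mbaf
            and st.het_fraction >= het_floor
        ):
            balanced_arms.append(arm)
    if not balanced_arms:
        return fallback
    arm_medians = {a: stats_by_arm[a].arm_median_depth for a in balanced_arms}
    lowest = min(arm_medians.values())
    # AB arms vs doubled AABB arms separate by ~1.4-1.8x in coverage; noise
    # on an arm median is a few percent, so a 1.25x window isolates the
    # diploid cluster
    cluster = [a for a in balanced_arms if arm_medians[a] <= 1.25 * lowest]
    pooled = np.concatenate([depths_by_arm[a] for a in cluster])
    return float(np.median(pooled[pooled > 0]))


def call_sample(
    panel: PanelDesign,
    observations: Sequence[SnpObservation],
    sex: str,
    thresholds: CallThresholds | None = None,
) -> list[ArmCall]:
    """Call all 41 arms of one sample with two-pass self-normalization."""
    if thresholds is None:
        thresholds = CallThresholds()
    by_id = {o.locus_id: o for o in observations}
    missing = [lid for lid in panel.locus_ids if lid not in by_id]
    if missing:
        raise ValueError(f"observations missing {len(missing)} panel loci")

    depths_by_arm: dict[ArmId, np.ndarray] = {}
    obs_by_arm: dict[ArmId, list[SnpObservation]] = {}
    for arm in ARM_UNIVERSE:
        arm_obs = [by_id[loc.locus_id] for loc in panel.loci_on(arm)]
        obs_by_arm[arm] = arm_obs
        depths_by_arm[arm] = np.array([o.depth for o in arm_obs], dtype=float)

    autosomal_depths = np.concatenate(
        [depths_by_arm[a] for a in ARM_UNIVERSE if a.chromosome != "X"]
    )
    nz = autosomal_depths[autosomal_depths > 0]
    if nz.size == 0:
        raise UninterpretableSampleError("no covered loci in sample")
    provisional = float(np.median(nz))

    pass_a = {
        arm: summarize_arm(obs_by_arm[arm], panel, arm, provisional)
        for arm in ARM_UNIVERSE
    }
    baseline = _balanced_baseline(pass_a, thresholds, depths_by_arm, provisional)

    calls = []
    for arm in ARM_UNIVERSE:
        stats = summarize_arm(obs_by_arm[arm], panel, arm, baseline)
        calls.append(classify_arm(stats, thresholds, sex))
    n_no_call = sum(1 for c in calls if c.mechanism == "no_call")
    if n_no_call > 0.5 * len(calls):
        raise UninterpretableSampleError(
            f"{n_no_call} of {len(calls)} arms uncallable"
        )
    return calls
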