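"""Forward simulation of targeted SNP-panel read counts.

Emulates the statistical structure of a tumor-only FFPE SNP panel: germline
genotypes drawn Hardy-Weinberg from population B-allele frequencies, tumor
arm states diluted by purity, per-locus depth from a gamma-Poisson
(overdispersed) model scaled by the arm's expected relative coverage, and
binomial allele sampling.  Truth (the ``TumorSpec``) never leaks into the
observation table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .arms import ARM_UNIVERSE, ArmId
from .model import (
    GenotypeState,
    expected_baf,
    expected_relative_coverage,
)
from .panel import PanelDesign, SnpLocus, SnpObservation

#: Male-X tumor states consistent with a hemizygous germline.
MALE_X_STATES = (GenotypeState(1, 0), GenotypeState(2, 0))


@dataclass(frozen=True)
class TumorSpec:
    """Simulation ground truth: per-arm genotypes, purity and sex."""

    sample_id: str
    sex: str
    purity: float
    arm_states: Mapping[ArmId, GenotypeState]
    doubling: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        missing = [str(a) for a in ARM_UNIVERSE if a not in self.arm_states]
        if missing:
            raise ValueError(f"arm_states incomplete; missing {missing}")
        if self.sex == "male":
            for arm in ARM_UNIVERSE:
                if arm.chromosome == "X" and self.arm_states[arm] not in MALE_X_STATES:
                    raise ValueError(
                        "male X arm states must be hemizygous-consistent "
                        f"{[s.label for s in MALE_X_STATES]}"
                    )


@dataclass(frozen=True)
class SimulationConfig:
    mean_depth: int = 500
    depth_dispersion: float = 0.2  # CV of the gamma mixing distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be non-negative")


def make_default_panel(seed: int, n_loci: int = 1500) -> PanelDesign:
    """Default panel: ``n_loci`` SNPs spread evenly over the 41 arms.

    Each arm receives floor(n/41) loci; the remainder arms (chosen
    reproducibly from ``seed``) get one extra.  All population BAFs are 0.5,
    so the expected germline heterozygous fraction is 0.5 per arm.
    """
    rng = np.random.default_rng(seed)
    base = n_loci // len(ARM_UNIVERSE)
    extra = n_loci - base * len(ARM_UNIVERSE)
    bonus = set(rng.choice(len(ARM_UNIVERSE), size=extra, replace=False).tolist())
    loci: list[SnpLocus] = []
    for i, arm in enumerate(ARM_UNIVERSE):
        count = base + (1 if i in bonus else 0)
        for k in range(count):
            loci.append(SnpLocus(f"snp_{arm}_{k:03d}", arm, 0.5))
    return PanelDesign(loci=tuple(loci))


def simulate_sample(
    spec: TumorSpec, panel: PanelDesign, config: SimulationConfig
) -> list[SnpObservation]:
    """Draw one sample's observation table from the forward model.

    Per locus: the germline genotype is Hardy-Weinberg given the locus
    population BAF (hemizygous on the male X); depth is gamma-Poisson with
    mean ``mean_depth`` times the arm's expected relative coverage at the
    sample purity; the B-read count is binomial at the expected BAF given
    germline genotype, arm state and purity.  Germline-homozygous loci stay
    at BAF 0 or 1 whatever the arm state.
    """
    rng = np.random.default_rng(config.seed)
    n = len(panel)
    pop_baf = np.array([loc.pop_baf for loc in panel.loci])
    is_male_x = np.array(
        [spec.sex == "male" and loc.arm.chromosome == "X" for loc in panel.loci]
    )

    # per-locus expected relative coverage and het-orientation BAF
    rel = np.empty(n)
    het_baf = np.empty(n)  # B-major orientation at a germline het
    for i, loc in enumerate(panel.loci):
        state = spec.arm_states[loc.arm]
        normal_copies = 1 if is_male_x[i] else 2
        rel[i] = expected_relative_coverage(state, spec.purity, normal_copies)
        if is_male_x[i]:
            het_baf[i] = np.nan  # no germline hets on the male X
        else:
            het_baf[i] = expected_baf(state, spec.purity)

    # germline genotypes: expected B fraction per locus
    u = rng.random(n)
    q = pop_baf
    p_expected = np.empty(n)
    # male X: one germline allele, B with probability q
    male_b = u < q
    # autosomes / female X: AA, AB, BB with HW probabilities
    aa = u < (1 - q) ** 2
    ab = (u >= (1 - q) ** 2) & (u < (1 - q) ** 2 + 2 * q * (1 - q))
    p_expected[:] = 1.0  # BB (and male B) default
    p_expected[aa & ~is_male_x] = 0.0
    # random per-locus orientation of which parental allele is 'B'
    flip = rng.random(n) < 0.5
    het_vals = np.where(flip, het_baf, 1.0 - het_baf)
    p_expected[ab & ~is_male_x] = het_vals[ab & ~is_male_x]
    p_expected[is_male_x & ~male_b] = 0.0
    p_expected[is_male_x & male_b] = 1.0

    # depth: gamma-Poisson with mean = mean_depth * rel, CV = dispersion
    mean = config.mean_depth * rel
    if config.depth_dispersion > 0:
        shape = 1.0 / config.depth_dispersion**2
        lam = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    else:
        lam = mean
    depth = rng.poisson(lam)
    depth[mean <= 0] = 0

    b_count = rng.binomial(depth, np.clip(p_expected, 0.0, 1.0))
    return [
        SnpObservation(loc.locus_id, int(d), int(b))
        for loc, d, b in zip(panel.loci, depth, b_count)
    ]


def spec_from_chromosome_states(
    sample_id: str,
    sex: str,
    purity: float,
    chromosome_states: Mapping[str, GenotypeState] | None = None,
    arm_states: Mapping[ArmId, GenotypeState] | None = None,
    doubling: bool = False,
) -> TumorSpec:
    """Build a complete 41-arm TumorSpec from whole-chromosome (and optional
    per-arm) state assignments; unassigned arms default to balanced (1,1),
    or hemizygous (1,0) on the male X."""
    states: dict[ArmId, GenotypeState] = {}
    for arm in ARM_UNIVERSE:
        if sex == "male" and arm.chromosome == "X":
            states[arm] = GenotypeState(1, 0)
        else:
            states[arm] = GenotypeState(1, 1)
    if chromosome_states:
        for chrom, state in chromosome_states.items():
            for arm in ARM_UNIVERSE:
                if arm.chromosome == str(chrom):
                    states[arm] = state
    if arm_states:
        states.update(arm_states)
    return TumorSpec(sample_id, sex, purity, states, doubling)


# pattern -> (loss-tier pool, gain-tier pool) used by the cohort generator
_PATTERN_POOLS = {
    2: ((GenotypeState(1, 0), GenotypeState(2, 0)), ()),
    3: ((), (GenotypeState(2, 1), GenotypeState(2, 2))),
    4: ((GenotypeState(1, 0), GenotypeState(2, 0)),
        (GenotypeState(2, 1), GenotypeState(2, 2))),
}


def random_spec(
    sample_id: str, pattern: int, rng: np.random.Generator, purity: float | None = None
) -> TumorSpec:
    """One random TumorSpec whose true pattern class matches ``pattern``."""
    if pattern not in (1, 2, 3, 4):
        raise ValueError("pattern must be 1-4")
    sex = "male" if rng.random() < 0.5 else "female"
    if purity is None:
        purity = float(rng.uniform(0.6, 0.95))
    if pattern == 1:
        return spec_from_chromosome_states(sample_id, sex, purity)
    loss_pool, gain_pool = _PATTERN_POOLS[pattern]
    # alterations restricted to autosomal arms so male X stays baseline
    autosomal = [a for a in ARM_UNIVERSE if a.chromosome != "X"]
    k = int(rng.integers(3, 16))
    chosen = rng.choice(len(autosomal), size=k, replace=False)
    arm_states: dict[ArmId, GenotypeState] = {}
    pools = list(loss_pool) + list(gain_pool)
    for j, idx in enumerate(chosen):
        if pattern == 4 and j == 0:
            state = loss_pool[int(rng.integers(len(loss_pool)))]
        elif pattern == 4 and j == 1:
            state = gain_pool[int(rng.integers(len(gain_pool)))]
        else:
            state = pools[int(rng.integers(len(pools)))]
        arm_states[autosomal[int(idx)]] = state
    return spec_from_chromosome_states(
        sample_id, sex, purity, arm_states=arm_states
    )


def simulate_cohort(
    n_per_pattern: Mapping[int, int],
    config: SimulationConfig,
    panel: PanelDesign | None = None,
) -> list[tuple[TumorSpec, list[SnpObservation]]]:
    """Simulate a cohort with the requested number of samples per pattern."""
    bad = [p for p in n_per_pattern if p not in (1, 2, 3, 4)]
    if bad:
        raise ValueError(f"unknown pattern keys: {bad}")
    rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = make_default_panel(seed=config.seed)
    out = []
    for pattern in sorted(n_per_pattern):
        for i in range(n_per_pattern[pattern]):
            spec = random_spec(f"sim_p{pattern}_{i:03d}", pattern, rng)
            sub = SimulationConfig(
                mean_depth=config.mean_depth,
                depth_dispersion=config.depth_dispersion,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append((spec, simulate_sample(spec, panel, sub)))
    return out


def truth_table(specs: Sequence[TumorSpec]):
    """Truth TSV rows (sample_id, chrom, arm, major, minor) for emitted specs."""
    import pandas as pd

    rows = []
    for spec in specs:
        for arm in ARM_UNIVERSE:
            st = spec.arm_states[arm]
            rows.append(
                {
                    "sample_id": spec.sample_id,
                    "chrom": arm.chromosome,
                    "arm": arm.arm,
                    "major": st.major,
                    "minor": st.minor,
                }
            )
    return pd.DataFrame(rows)
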