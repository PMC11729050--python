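import math

import pytest

from karyopattern.arms import ARM_UNIVERSE, ArmId
from karyopattern.caller import ArmCall, ArmStats
from karyopattern.model import GenotypeState, expected_baf, expected_log2_ratio
from karyopattern.simulate import TumorSpec, make_default_panel


@pytest.fixture(scope="session")
def panel():
    return make_default_panel(seed=17)


def expected_stats(
    arm: ArmId,
    state: GenotypeState,
    purity: float,
    n_loci: int = 36,
    expected_het: float = 0.5,
) -> ArmStats:
    """Noise-free ArmStats at the expected values of the admixture model.

    Mirrors what the summarizer would produce from infinitely deep, noiseless
    data: the heterozygous band empties when the expected BAF leaves the
    (0.05, 0.95) informative window.
    """
    baf = expected_baf(state, purity)
    mbaf = max(baf, 1 - baf)
    in_band = 0.05 < baf < 0.95
    n_nonzero = n_loci
    n_inf = round(n_loci * expected_het) if in_band else 0
    return ArmStats(
        arm=arm,
        n_loci=n_loci,
        n_nonzero=n_nonzero,
        n_informative=n_inf,
        het_fraction=n_inf / n_nonzero,
        expected_het_fraction=expected_het,
        median_mirrored_baf=mbaf if in_band else math.nan,
        median_log2_ratio=expected_log2_ratio(state, purity),
        arm_median_depth=500.0,
    )


_MECHANISM_OF_STATE = {
    GenotypeState(1, 1): "none",
    GenotypeState(1, 0): "loss",
    GenotypeState(2, 0): "cn_loh",
    GenotypeState(2, 1): "gain",
    GenotypeState(2, 2): "balanced_gain",
}


def truth_calls(spec: TumorSpec) -> list[ArmCall]:
    """Noise-free ArmCall list matching a TumorSpec's ground truth."""
    calls = []
    for arm in ARM_UNIVERSE:
        state = spec.arm_states[arm]
        hemi = spec.sex == "male" and arm.chromosome == "X"
        if hemi:
            mechanism = "none" if state == GenotypeState(1, 0) else "gain"
        else:
            mechanism = _MECHANISM_OF_STATE[state]
        calls.append(
            ArmCall(
                arm=arm,
                stats=expected_stats(arm, state, spec.purity),
                state=state,
                mechanism=mechanism,
                hemizygous_baseline=hemi,
            )
        )
    return calls
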