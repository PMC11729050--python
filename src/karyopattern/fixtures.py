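"""Worked-example tumor specifications and printed cohort tallies.

Six patients with published arm-resolution karyotype descriptions serve as
ground-truth fixtures for end-to-end recovery tests, and the published
per-lineage pattern tallies let cohort-level summaries be reproduced without
access to the unpublished per-patient data.
"""

from __future__ import annotations

from .arms import ArmId
from .model import GenotypeState
from .panel import CohortRecord
from .simulate import TumorSpec, spec_from_chromosome_states

AB = GenotypeState(1, 1)
A0 = GenotypeState(1, 0)
AA = GenotypeState(2, 0)
AAB = GenotypeState(2, 1)
AABB = GenotypeState(2, 2)

#: Caption-derived pattern classes of the six worked patients.
FIXTURE_PATTERNS = {51: 1, 49: 2, 20: 3, 22: 4, 52: 2, 56: 2}

#: Chromosomes with LOH in the near-haploid patient 56 ("23" read as X).
PATIENT_56_LOH_CHROMOSOMES = (
    "1", "2", "3", "4", "6", "8", "10", "11", "13", "15",
    "17", "19", "20", "21", "22", "X",
)


def fixture(patient_id: int) -> TumorSpec:
    """Ground-truth TumorSpec for one of the six worked patients.

    Patient 51: quiet genome (Pattern 1).  Patient 49: copy-loss LOH of 1p,
    2, 8, 11 and copy-neutral 13q (Pattern 2; the chromosome-13 genotype is
    ambiguous in the source and encoded AA).  Patient 20: single-allele gains
    on 8 chromosomes (Pattern 3).  Patient 22: copy-neutral LOH plus gains
    plus AABB chromosomes 5 and 9 (Pattern 4).  Patient 52: near-homozygous
    genome, 19 autosomes + X at copy-neutral LOH after endoreduplication
    (Pattern 2; the partial 5q event is encoded as whole-arm 5q at this
    resolution).  Patient 56: near-haploid genome, 16 chromosomes at single
    copy, purity 0.65 (Pattern 2; the doubling flag records the reported
    endoreduplication without altering the single-copy encoding).
    """
    if patient_id == 51:
        return spec_from_chromosome_states("patient_51", "female", 0.8)
    if patient_id == 49:
        return spec_from_chromosome_states(
            "patient_49",
            "male",
            0.8,
            chromosome_states={"2": A0, "8": A0, "11": A0},
            arm_states={ArmId("1", "p"): A0, ArmId("13", "q"): AA},
        )
    if patient_id == 20:
        return spec_from_chromosome_states(
            "patient_20",
            "male",
            0.8,
            chromosome_states={c: AAB for c in
                               ("3", "7", "8", "9", "12", "19", "21", "22")},
        )
    if patient_id == 22:
        chrom_states: dict[str, GenotypeState] = {}
        for c in ("1", "2", "4", "10", "20", "22"):
            chrom_states[c] = AA
        for c in ("3", "7", "8", "11", "12", "14", "17", "19", "X"):
            chrom_states[c] = AAB
        for c in ("5", "9"):
            chrom_states[c] = AABB
        return spec_from_chromosome_states(
            "patient_22", "female", 0.8, chromosome_states=chrom_states
        )
    if patient_id == 52:
        chroms = ("1", "2", "3", "4", "6", "8", "10", "11", "12", "14", "15",
                  "16", "17", "18", "19", "20", "21", "22", "X")
        return spec_from_chromosome_states(
            "patient_52",
            "female",
            0.8,
            chromosome_states={c: AA for c in chroms},
            arm_states={ArmId("5", "q"): AA},
            doubling=True,
        )
    if patient_id == 56:
        return spec_from_chromosome_states(
            "patient_56",
            "female",
            0.65,
            chromosome_states={c: A0 for c in PATIENT_56_LOH_CHROMOSOMES},
            doubling=True,
        )
    raise ValueError(f"unknown fixture patient id {patient_id}")


#: Published pattern tallies per lineage (patterns 1-4).  The single
#: multilineage tumor is altered; its pattern class is not published and is
#: recorded here as Pattern 4.
LINEAGE_PATTERN_TALLIES: dict[str, dict[int, int]] = {
    "PIT1": {1: 2, 2: 6, 3: 9, 4: 13},
    "TPIT": {1: 1, 2: 6, 3: 2, 4: 1},
    "SF1": {1: 16, 2: 0, 3: 4, 4: 0},
    "multilineage": {1: 0, 2: 0, 3: 0, 4: 1},
}

#: Published lactotroph subtype tallies: 16 sparsely granulated tumors
#: (11 Pattern 4, 5 Pattern 3) and 4 densely granulated (3 Pattern 3,
#: 1 Pattern 1), i.e. 19/20 altered.
LACTOTROPH_SUBTYPE_TALLIES: dict[str, dict[int, int]] = {
    "sparsely granulated lactotroph": {1: 0, 2: 0, 3: 5, 4: 11},
    "densely granulated lactotroph": {1: 1, 2: 0, 3: 3, 4: 0},
}

#: Published per-lineage summaries of altered-arm counts: (mean, sd, n).
PRINTED_ARM_COUNT_SUMMARIES: dict[str, tuple[float, float, int]] = {
    "TPIT": (14.1, 13.04, 10),
    "PIT1": (11.6, 7.69, 30),
    "SF1": (1.4, 3.69, 20),
    "sparsely granulated lactotroph": (16.81, 6.06, 16),
    "densely granulated lactotroph": (8.25, 5.68, 4),
}

#: Published silent/functional x pattern contingency counts.
FUNCTIONAL_STATUS_TABLE = {
    "silent": (16, 3, 3, 0),
    "functional": (3, 9, 14, 13),
}


def build_printed_cohort():
    """Construct (results, annotations) matching the published tallies.

    Pattern labels and lineage/subtype annotations follow the printed counts
    exactly; per-sample altered-arm counts are synthetic placeholders (the
    per-patient counts are unpublished), consistent with each sample's
    pattern class.  Lactotroph subtypes are embedded within the PIT1 tallies.
    """
    from .patterns import SampleResult

    results: list[SampleResult] = []
    records: list[CohortRecord] = []
    idx = 0
    # expand lactotroph subtypes first, then the remaining PIT1 samples
    expanded: list[tuple[str, str, int]] = []
    remaining_pit1 = {k: v for k, v in LINEAGE_PATTERN_TALLIES["PIT1"].items()}
    for subtype, tallies in LACTOTROPH_SUBTYPE_TALLIES.items():
        for pattern, n in tallies.items():
            for _ in range(n):
                expanded.append(("PIT1", subtype, pattern))
                remaining_pit1[pattern] -= 1
    for pattern, n in remaining_pit1.items():
        for _ in range(n):
            expanded.append(("PIT1", "other PIT1", pattern))
    for lineage in ("TPIT", "SF1", "multilineage"):
        for pattern, n in LINEAGE_PATTERN_TALLIES[lineage].items():
            for _ in range(n):
                expanded.append((lineage, lineage.lower(), pattern))

    for lineage, subtype, pattern in expanded:
        idx += 1
        sid = f"cohort_{idx:03d}"
        n_loss = {1: 0, 2: 5, 3: 0, 4: 4}[pattern]
        n_gain = {1: 0, 2: 0, 3: 6, 4: 7}[pattern]
        results.append(
            SampleResult(
                sample_id=sid,
                pattern=pattern,
                altered_arms=n_loss + n_gain,
                n_loss_tier=n_loss,
                n_gain_tier=n_gain,
                near_haploid=False,
                near_homozygous=False,
                doubling_inferred=False,
                purity_estimate=None,
                ploidy_estimate=None,
            )
        )
        records.append(
            CohortRecord(
                sample_id=sid,
                lineage=lineage,
                subtype=subtype,
                sex="female",
                invasive="unknown",
                functional="functional",
                recurrent="no",
            )
        )
    return results, records
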