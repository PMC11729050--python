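"""Panel, observation, arm-call and cohort-annotation file formats.

All formats are plain tab-separated text with a header row.  Floats are
serialized at 6 decimals; arm-call rows are ordered chromosome 1..22, X with
p before q, so outputs are byte-stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .arms import ARM_UNIVERSE, EXCLUDED_P_ARMS, ArmId

if TYPE_CHECKING:  # pragma: no cover
    from .caller import ArmCall


class PanelFormatError(ValueError):
    """A panel/observation/annotation file violates its format contract."""


@dataclass(frozen=True)
class SnpLocus:
    locus_id: str
    arm: ArmId
    pop_baf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pop_baf < 1.0):
            raise PanelFormatError(
                f"locus {self.locus_id}: pop_baf must be strictly inside (0,1)"
            )


@dataclass(frozen=True)
class PanelDesign:
    """Ordered SNP panel; loci sorted by chromosome, arm, then input order."""

    loci: tuple[SnpLocus, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for loc in self.loci:
            if loc.locus_id in seen:
                raise PanelFormatError(f"duplicate locus_id {loc.locus_id!r}")
            seen.add(loc.locus_id)
        counts: dict[ArmId, int] = {}
        for loc in self.loci:
            counts[loc.arm] = counts.get(loc.arm, 0) + 1
        thin = [str(a) for a in ARM_UNIVERSE if counts.get(a, 0) < 8]
        if thin:
            warnings.warn(
                "arm coverage incomplete: fewer than 8 loci on arms "
                + ", ".join(thin),
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(loc.locus_id for loc in self.loci)

    def loci_on(self, arm: ArmId) -> tuple[SnpLocus, ...]:
        return tuple(loc for loc in self.loci if loc.arm == arm)


@dataclass(frozen=True)
class SnpObservation:
    locus_id: str
    depth: int
    b_count: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise PanelFormatError(f"locus {self.locus_id}: negative depth")
        if not (0 <= self.b_count <= self.depth):
            raise PanelFormatError(
                f"locus {self.locus_id}: b_count {self.b_count} outside "
                f"[0, depth={self.depth}]"
            )

    @property
    def baf(self) -> float:
        return self.b_count / self.depth if self.depth > 0 else float("nan")


@dataclass(frozen=True)
class CohortRecord:
    sample_id: str
    lineage: str
    subtype: str
    sex: str
    invasive: str
    functional: str
    recurrent: str

    def __post_init__(self) -> None:
        if not self.lineage:
            raise PanelFormatError(f"sample {self.sample_id}: empty lineage")
        if self.sex not in ("male", "female"):
            raise PanelFormatError(
                f"sample {self.sample_id}: sex must be male/female"
            )


def _sorted_loci(loci: Iterable[SnpLocus]) -> tuple[SnpLocus, ...]:
    # stable: chromosome, then arm, then input order
    indexed = list(enumerate(loci))
    indexed.sort(key=lambda t: (t[1].arm.sort_key, t[0]))
    return tuple(x for _, x in indexed)


def load_panel(path: str | Path) -> PanelDesign:
    """Read a panel design TSV (columns locus_id, chrom, arm, pop_baf)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["locus_id", "chrom", "arm", "pop_baf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file missing columns: {missing}")
    loci = []
    for row in df.itertuples(index=True):
        chrom, arm = str(row.chrom), str(row.arm)
        if arm == "p" and chrom in EXCLUDED_P_ARMS:
            raise PanelFormatError(
                f"row {row.Index}: arm {chrom}p is acrocentric and not scoreable"
            )
        try:
            arm_id = ArmId(chrom, arm)
            loci.append(SnpLocus(str(row.locus_id), arm_id, float(row.pop_baf)))
        except ValueError as exc:
            raise PanelFormatError(f"row {row.Index}: {exc}") from exc
    return PanelDesign(loci=_sorted_loci(loci))


def write_panel(panel: PanelDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "locus_id": [loc.locus_id for loc in panel.loci],
            "chrom": [loc.arm.chromosome for loc in panel.loci],
            "arm": [loc.arm.arm for loc in panel.loci],
            "pop_baf": [f"{loc.pop_baf:.6f}" for loc in panel.loci],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_observations(path: str | Path, panel: PanelDesign) -> list[SnpObservation]:
    """Read an observation TSV (locus_id, depth, b_count) against a panel.

    Panel loci missing from the file are padded as depth-0 observations so
    partial FFPE dropout stays representable; loci absent from the panel are
    a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    required = ["locus_id", "depth", "b_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"observation file missing columns: {missing}")
    known = set(panel.locus_ids)
    by_id: dict[str, SnpObservation] = {}
    for row in df.itertuples(index=True):
        if row.locus_id not in known:
            raise PanelFormatError(
                f"row {row.Index}: unknown locus_id {row.locus_id!r}"
            )
        by_id[row.locus_id] = SnpObservation(
            row.locus_id, int(row.depth), int(row.b_count)
        )
    return [
        by_id.get(lid, SnpObservation(lid, 0, 0)) for lid in panel.locus_ids
    ]


def write_observations(obs: Sequence[SnpObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "locus_id": [o.locus_id for o in obs],
            "depth": [o.depth for o in obs],
            "b_count": [o.b_count for o in obs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


ARM_CALL_COLUMNS = [
    "chrom",
    "arm",
    "n_informative",
    "median_mirrored_baf",
    "median_log2_ratio",
    "state",
    "genotype_label",
    "mechanism",
]


def write_arm_calls(calls: Sequence["ArmCall"], path: str | Path) -> None:
    """Write per-arm calls as a SEG-like arm-resolution TSV."""
    if not calls:
        raise ValueError("no arm calls to write")
    rows = []
    for call in sorted(calls, key=lambda c: c.arm.sort_key):
        st = call.stats
        rows.append(
            {
                "chrom": call.arm.chromosome,
                "arm": call.arm.arm,
                "n_informative": st.n_informative,
                "median_mirrored_baf": _fmt6(st.median_mirrored_baf),
                "median_log2_ratio": _fmt6(st.median_log2_ratio),
                "state": f"{call.state.major},{call.state.minor}" if call.state else "NA",
                "genotype_label": call.label,
                "mechanism": call.mechanism,
            }
        )
    pd.DataFrame(rows, columns=ARM_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_arm_calls(path: str | Path) -> pd.DataFrame:
    """Read an arm-call TSV back as a DataFrame (analysis-side convenience)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})


def _fmt6(x: float) -> str:
    import math

    return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.6f}"


def load_cohort_annotations(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["sample_id", "lineage", "subtype", "sex", "invasive",
                "functional", "recurrent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"annotation file missing columns: {missing}")
    return [
        CohortRecord(
            row.sample_id, row.lineage, row.subtype, row.sex,
            row.invasive, row.functional, row.recurrent,
        )
        for row in df.itertuples(index=False)
    ]


def write_cohort_annotations(records: Sequence[CohortRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(path, sep="\t", index=False)
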