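import itertools

import numpy as np
import pytest
from scipy import stats as sps

from karyopattern.fixtures import (
    FUNCTIONAL_STATUS_TABLE,
    PRINTED_ARM_COUNT_SUMMARIES,
    build_printed_cohort,
)
from karyopattern.stats import (
    ContingencyTable,
    chi_square_independence,
    mann_whitney_u,
    pattern_lineage_summary,
    t_confidence_interval,
)

#: Published per-group 95% CIs at 2 decimals, keyed like the printed summaries.
PRINTED_CONFIDENCE_INTERVALS = {
    "TPIT": (4.77, 23.43),
    "PIT1": (8.73, 14.47),
    "SF1": (-0.33, 3.13),
    "sparsely granulated lactotroph": (13.58, 20.04),
    "densely granulated lactotroph": (-0.79, 17.29),
}


class TestTConfidenceInterval:
    @pytest.mark.parametrize("group", sorted(PRINTED_CONFIDENCE_INTERVALS))
    def test_reproduces_published_intervals(self, group):
        mean, sd, n = PRINTED_ARM_COUNT_SUMMARIES[group]
        iv = t_confidence_interval(mean, sd, n)
        assert iv.rounded == PRINTED_CONFIDENCE_INTERVALS[group]

    def test_zero_variance(self):
        iv = t_confidence_interval(5.0, 0.0, 10)
        assert iv.rounded == (5.00, 5.00)

    def test_contains_mean(self):
        iv = t_confidence_interval(3.0, 2.0, 12)
        assert iv.lower <= iv.mean <= iv.upper

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            t_confidence_interval(1.0, 1.0, 1)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            t_confidence_interval(1.0, -1.0, 5)


class TestChiSquare:
    def test_functional_status_significant(self):
        table = ContingencyTable(
            ("silent", "functional"),
            ("pattern_1", "pattern_2", "pattern_3", "pattern_4"),
            (FUNCTIONAL_STATUS_TABLE["silent"],
             FUNCTIONAL_STATUS_TABLE["functional"]),
        )
        with pytest.warns(UserWarning, match="below 5"):
            stat, df, p = chi_square_independence(table)
        assert df == 3
        assert p < 0.0001

    def test_identical_rows(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), ((5, 7), (5, 7)))
        stat, df, p = chi_square_independence(table)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), ((10, 0), (0, 10)))
        stat, df, p = chi_square_independence(table)
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_zero_column_rejected(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), ((5, 0), (7, 0)))
        with pytest.raises(ValueError, match="all-zero"):
            chi_square_independence(table)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a",), ("x", "y"), ((1,),))


def oracle_exact_p(x, y):
    """Independent exact two-tailed p: brute force over label assignments,
    computing U by pair counting (not rank sums)."""
    def u_of(xs, ys):
        return sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0
            for xi in xs for yi in ys
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    dev = abs(u_of(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(xs, ys) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney_u((1, 2, 3), (1, 2, 3))
        assert u == pytest.approx(4.5)
        assert p == pytest.approx(1.0)

    def test_complete_separation(self):
        u, p = mann_whitney_u((1, 2), (10, 11))
        assert u == 0.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            # integer values force ties regularly
            x = rng.integers(0, 6, size=n1).tolist()
            y = rng.integers(0, 6, size=n2).tolist()
            u, p = mann_whitney_u(x, y)
            assert p == pytest.approx(oracle_exact_p(x, y), abs=1e-12), (x, y)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, size=20).tolist()
        y = rng.normal(0.5, 1, size=15).tolist()
        u, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


@pytest.fixture(scope="module")
def printed():
    return build_printed_cohort()


class TestPatternLineageSummary:
    def test_printed_lineage_tallies(self, printed):
        results, records = printed
        summary = pattern_lineage_summary(results, records, group_field="lineage")
        assert summary.n_pattern1 == 19
        assert summary.n_altered == 42
        assert summary.percent_altered == 68.9  # 42/61, printed as 69%
        frame = summary.table.to_frame()
        assert list(frame["PIT1"]) == [2, 6, 9, 13]
        assert list(frame["TPIT"]) == [1, 6, 2, 1]
        assert list(frame["SF1"]) == [16, 0, 4, 0]

    def test_lactotroph_subtypes_95_percent_altered(self, printed):
        results, records = printed
        lacto_ids = {
            r.sample_id for r in records if "lactotroph" in r.subtype
        }
        assert len(lacto_ids) == 20
        summary = pattern_lineage_summary(
            [r for r in results if r.sample_id in lacto_ids],
            records,
            group_field="lineage",
        )
        assert summary.percent_altered == 95.0

    def test_single_sample_cohort(self, printed):
        results, records = printed
        summary = pattern_lineage_summary(results[:1], records)
        assert summary.table.total == 1
        assert all(iv is None for iv in summary.intervals.values())

    def test_order_invariant(self, printed):
        results, records = printed
        a = pattern_lineage_summary(results, records)
        b = pattern_lineage_summary(list(reversed(results)), records)
        assert a.table == b.table
        assert a.percent_altered == b.percent_altered
        assert a.intervals == b.intervals

    def test_unmatched_sample_rejected(self, printed):
        results, records = printed
        with pytest.raises(ValueError, match="without annotations"):
            pattern_lineage_summary(results, records[1:])
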