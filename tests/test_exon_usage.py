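"""Per-read exon status calls and allele-level usage aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlasplice import (
    AlignedRead,
    AlleleName,
    AlleleReference,
    ExonStatus,
    aggregate_usage,
    call_exons,
    call_exons_bulk,
    load_alignments,
    partition_by_snp,
)
from hlasplice.exon_usage import read_usage, write_usage
from tests.conftest import brute_force_exon_calls

R, E, U = ExonStatus.RETAINED, ExonStatus.EXCLUDED, ExonStatus.UNASSESSED

SIX_EXONS = ((0, 50), (100, 200), (250, 300), (350, 400), (450, 474), (500, 600))


@pytest.fixture(scope="module")
def allele6():
    return AlleleReference(AlleleName.parse("DQB1*05:03:01:01"), "A" * 600, SIX_EXONS)


def read_over(allele, blocks):
    return AlignedRead("r", allele.name, tuple(blocks))


@pytest.mark.parametrize(
    "blocks, expected",
    [
        # covers exons 1-4 and 6, skipping the 24-nt exon 5: splicing
        ([(0, 400), (500, 600)], [R, R, R, R, E, R]),
        # 5'-truncated read reaching only exons 3-6: truncation, not splicing
        ([(250, 600)], [U, U, R, R, R, R]),
        # covers exons 1,2,4 only: exon 3 excluded, 5-6 unassessed
        ([(0, 200), (350, 400)], [R, R, E, R, U, U]),
        # single-base overlap counts as retained
        ([(473, 474)], [U, U, U, U, R, U]),
        ([(49, 50), (500, 501)], [R, E, E, E, E, R]),
        # purely intronic alignment: everything unassessed
        ([(60, 90)], [U, U, U, U, U, U]),
    ],
)
def test_call_exons_examples(allele6, blocks, expected):
    cs = call_exons(read_over(allele6, blocks), allele6)
    assert list(cs.calls) == expected


def test_call_exons_rejects_mismatched_allele(allele6):
    other = AlignedRead("r", AlleleName.parse("DQB1*05:01:01:01"), ((0, 10),))
    with pytest.raises(ValueError):
        call_exons(other, allele6)


def test_call_exons_rejects_out_of_bounds(allele6):
    with pytest.raises(ValueError):
        call_exons(read_over(allele6, [(590, 700)]), allele6)


@st.composite
def random_instance(draw):
    n_exons = draw(st.integers(1, 6))
    bounds = draw(
        st.lists(st.integers(0, 120), min_size=2 * n_exons, max_size=2 * n_exons,
                 unique=True).map(sorted)
    )
    exons = tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons))
    length = 130
    n_blocks = draw(st.integers(1, 5))
    bpts = draw(
        st.lists(st.integers(0, length), min_size=2 * n_blocks,
                 max_size=2 * n_blocks, unique=True).map(sorted)
    )
    blocks = tuple((bpts[2 * i], bpts[2 * i + 1]) for i in range(n_blocks))
    return exons, blocks, length


@settings(deadline=None, max_examples=400)
@given(random_instance())
def test_call_exons_matches_per_base_oracle(instance):
    """Interval-based calls equal the boolean coverage-vector brute force."""
    exons, blocks, length = instance
    allele = AlleleReference(AlleleName.parse("A*02:01:01:01"), "A" * length, exons)
    cs = call_exons(AlignedRead("r", allele.name, blocks), allele)
    assert [c.value for c in cs.calls] == brute_force_exon_calls(blocks, exons, length)


@settings(deadline=None, max_examples=400)
@given(random_instance())
def test_terminal_exons_never_excluded(instance):
    exons, blocks, length = instance
    allele = AlleleReference(AlleleName.parse("A*02:01:01:01"), "A" * length, exons)
    cs = call_exons(AlignedRead("r", allele.name, blocks), allele)
    assert cs.calls[0] is not E and cs.calls[-1] is not E
    # any excluded exon is flanked by retained exons
    for i, c in enumerate(cs.calls):
        if c is E:
            assert any(x is R for x in cs.calls[:i])
            assert any(x is R for x in cs.calls[i + 1:])


class TestAggregateUsage:
    def test_counts_partition_reads(self, bundle, sim):
        reads = load_alignments(sim.sam_path, bundle)
        usage = aggregate_usage(call_exons_bulk(reads, bundle), bundle, "s1")
        for _, row in usage.iterrows():
            total = row.n_retained + row.n_excluded + row.n_unassessed
            assert total == row.n_reads_allele
        # terminal exons never excluded
        for allele in bundle.alleles:
            sub = usage[usage.allele == str(allele.name)]
            assert sub[sub.exon_index == 1].n_excluded.item() == 0
            assert sub[sub.exon_index == allele.n_exons].n_excluded.item() == 0

    def test_retention_rate_and_threshold(self, allele6):
        from hlasplice import ReferenceBundle

        bundle = ReferenceBundle("s", (allele6,), ())
        full = [(0, 600)]
        skip5 = [(0, 400), (500, 600)]
        callsets = [
            call_exons(AlignedRead(f"r{i}", allele6.name, tuple(full if i < 72 else skip5)), allele6)
            for i in range(100)
        ]
        usage = aggregate_usage(callsets, bundle, "s")
        row = usage[usage.exon_index == 5].iloc[0]
        assert row.n_retained == 72 and row.n_excluded == 28
        assert row.retention_rate == pytest.approx(0.72)
        assert row.passes_threshold  # 100 ≥ 10 for class II

    def test_class_ii_threshold_boundary(self, allele6):
        from hlasplice import ReferenceBundle

        bundle = ReferenceBundle("s", (allele6,), ())
        make = lambda n: [
            call_exons(AlignedRead(f"r{i}", allele6.name, ((0, 600),)), allele6)
            for i in range(n)
        ]
        assert not aggregate_usage(make(9), bundle, "s").passes_threshold.any()
        assert aggregate_usage(make(10), bundle, "s").passes_threshold.all()

    def test_class_i_threshold_is_20(self):
        from hlasplice import ReferenceBundle

        a = AlleleReference(AlleleName.parse("A*02:01:01:01"), "A" * 600, SIX_EXONS)
        bundle = ReferenceBundle("s", (a,), ())
        callsets = [
            call_exons(AlignedRead(f"r{i}", a.name, ((0, 600),)), a)
            for i in range(19)
        ]
        assert not aggregate_usage(callsets, bundle, "s").passes_threshold.any()

    def test_all_unassessed_gives_undefined_rate(self, allele6):
        from hlasplice import ReferenceBundle

        bundle = ReferenceBundle("s", (allele6,), ())
        # reads overlapping only exon 6: exons 1-5 unassessed
        callsets = [
            call_exons(AlignedRead(f"r{i}", allele6.name, ((500, 600),)), allele6)
            for i in range(12)
        ]
        usage = aggregate_usage(callsets, bundle, "s")
        assert np.isnan(usage[usage.exon_index == 1].retention_rate.item())
        assert usage[usage.exon_index == 6].retention_rate.item() == 1.0

    def test_empty_input_gives_zero_rows_per_exon(self, bundle):
        usage = aggregate_usage([], bundle, "s")
        assert len(usage) == sum(a.n_exons for a in bundle.alleles)
        assert (usage.n_reads_allele == 0).all()
        assert not usage.passes_threshold.any()

    def test_all_reads_denominator_mode(self, allele6):
        from hlasplice import ReferenceBundle

        bundle = ReferenceBundle("s", (allele6,), ())
        callsets = [
            call_exons(AlignedRead("r1", allele6.name, ((0, 600),)), allele6),
            call_exons(AlignedRead("r2", allele6.name, ((500, 600),)), allele6),
        ]
        assess = aggregate_usage(callsets, bundle, "s", denominator="assessable")
        all_mode = aggregate_usage(callsets, bundle, "s", denominator="all")
        assert assess[assess.exon_index == 1].retention_rate.item() == 1.0
        assert all_mode[all_mode.exon_index == 1].retention_rate.item() == 0.5

    def test_monotonicity_adding_retaining_read(self, allele6):
        """Adding a read that retains exon k never decreases its retention rate."""
        from hlasplice import ReferenceBundle

        bundle = ReferenceBundle("s", (allele6,), ())
        base = [
            call_exons(AlignedRead(f"r{i}", allele6.name,
                                   ((0, 400), (500, 600))), allele6)
            for i in range(5)
        ]
        extra = call_exons(AlignedRead("rx", allele6.name, ((0, 600),)), allele6)
        before = aggregate_usage(base, bundle, "s")
        after = aggregate_usage(base + [extra], bundle, "s")
        for k in range(1, 7):
            b = before[before.exon_index == k].retention_rate.item()
            a = after[after.exon_index == k].retention_rate.item()
            assert np.isnan(b) or a >= b


def test_usage_tsv_round_trip(bundle, sim, tmp_path):
    reads = load_alignments(sim.sam_path, bundle)
    usage = aggregate_usage(call_exons_bulk(reads, bundle), bundle, "s1")
    path = tmp_path / "usage.tsv"
    write_usage(usage, path)
    back = read_usage(path)
    pd.testing.assert_frame_equal(
        back, usage, check_exact=False, atol=1e-6, check_dtype=False
    )


class TestSnpPartition:
    @staticmethod
    def usage_table():
        rows = []
        rates = {
            ("d1", "DQB1*05:03:01:01"): 0.72,
            ("d1", "DQB1*05:01:01:01"): 0.04,
            ("d2", "DQB1*02:01:01:01"): 0.0,
            ("d2", "DQB1*03:01:01:01"): 0.01,
        }
        for (s, a), r in rates.items():
            rows.append((s, a, 5, int(100 * r), 100 - int(100 * r), 0, r, 100, True))
        from hlasplice.exon_usage import USAGE_COLUMNS

        return pd.DataFrame(rows, columns=USAGE_COLUMNS)

    def test_groups_and_medians(self):
        snp_map = {
            ("d1", "DQB1*05:03:01:01"): "G",
            ("d1", "DQB1*05:01:01:01"): "A",
            ("d2", "DQB1*02:01:01:01"): "A",
            ("d2", "DQB1*03:01:01:01"): "A",
        }
        part = partition_by_snp(self.usage_table(), snp_map, exon_index=5)
        assert part.medians["G"] == pytest.approx(0.72)
        assert part.medians["A"] == pytest.approx(0.01)
        # heterozygous donor d1 vs homozygous-A donor d2
        assert part.medians_by_zygosity[("AG", "G")] == pytest.approx(0.72)
        assert part.medians_by_zygosity[("AG", "A")] == pytest.approx(0.04)
        assert part.medians_by_zygosity[("AA", "A")] == pytest.approx(0.005)
        assert part.ungrouped == []

    def test_empty_map_leaves_everything_ungrouped(self):
        part = partition_by_snp(self.usage_table(), {}, exon_index=5)
        assert len(part.table) == 0
        assert len(part.ungrouped) == 4

    def test_single_allele_group_median_is_value(self):
        snp_map = {("d1", "DQB1*05:03:01:01"): "G"}
        part = partition_by_snp(self.usage_table(), snp_map, exon_index=5)
        assert part.medians == {"G": pytest.approx(0.72)}
        assert len(part.ungrouped) == 3
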