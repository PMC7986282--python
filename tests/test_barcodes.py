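"""Read trimming, barcode collapsing, guide matching, and fate assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crispri_screenkit.barcodes import (
    ASSIGN_ADAPTER,
    COUNT_ADAPTER,
    EMPTY_GUIDE_ID,
    GUIDE_3_ADAPTER,
    GUIDE_5_ADAPTER,
    MatchOutcome,
    assign_barcode,
    assign_barcodes,
    collapse_barcodes,
    filter_count_table,
    match_guide,
    trim_barcode_read,
    trim_guide_read,
)

Q38 = chr(38 + 33)


class TestTrimming:
    def test_clean_barcode_trim(self):
        assert trim_barcode_read("ACGTACGTACGT" + COUNT_ADAPTER) == (
            "ACGTACGTACGT",
            None,
        )

    def test_missing_adapter_rejected(self):
        barcode, reason = trim_barcode_read("ACGT" * 20)
        assert barcode is None and reason == "no_adapter"

    def test_nine_nt_residual_rejected_at_min_ten(self):
        barcode, reason = trim_barcode_read("ACGTACGTA" + COUNT_ADAPTER, min_len=10)
        assert barcode is None and reason == "too_short"

    def test_twelve_nt_minimum_for_assignment_workflow(self):
        read = "ACGTACGTACG" + ASSIGN_ADAPTER  # 11 nt barcode
        assert trim_barcode_read(read, ASSIGN_ADAPTER, 12)[0] is None
        read = "ACGTACGTACGT" + ASSIGN_ADAPTER
        assert trim_barcode_read(read, ASSIGN_ADAPTER, 12)[0] == "ACGTACGTACGT"

    def test_clean_guide_trim(self):
        guide = "ATGCATGCATGCATGCATGC"
        read = GUIDE_5_ADAPTER + guide + GUIDE_3_ADAPTER + "TTTT"
        span, reason = trim_guide_read(read)
        assert reason is None
        assert read[span[0] : span[1]] == guide

    def test_nineteen_nt_residual_rejected(self):
        read = GUIDE_5_ADAPTER + "A" * 19 + GUIDE_3_ADAPTER
        assert trim_guide_read(read) == (None, "too_short")

    def test_missing_three_prime_adapter_rejected(self):
        read = GUIDE_5_ADAPTER + "A" * 25
        assert trim_guide_read(read) == (None, "no_3_adapter")


def naive_collapse(raw_counts):
    """Independent exhaustive-pairwise-Hamming restatement of collapsing."""
    def hamming(a, b):
        return sum(x != y for x, y in zip(a, b)) if len(a) == len(b) else 99

    order = sorted(raw_counts, key=lambda bc: (-raw_counts[bc], bc))
    records = {}  # rep -> [count, {member: count}]
    for bc in order:
        near = [rep for rep in records if hamming(bc, rep) == 1]
        if near:
            rep = max(near, key=lambda r: (records[r][0], tuple(-ord(c) for c in r)))
            records[rep][0] += raw_counts[bc]
            records[rep][1][bc] = raw_counts[bc]
        else:
            records[bc] = [raw_counts[bc], {bc: raw_counts[bc]}]
    return {rep: count for rep, (count, _m) in records.items()}


barcode_sets = st.dictionaries(
    st.text(alphabet="ACGT", min_size=8, max_size=8),
    st.integers(min_value=1, max_value=100),
    min_size=1,
    max_size=30,
)


class TestCollapse:
    def test_single_mismatch_absorbed(self):
        records = collapse_barcodes({"AAAAAAAAAA": 10, "AAAAAAAAAT": 2})
        assert len(records) == 1
        assert records[0].barcode == "AAAAAAAAAA"
        assert records[0].count == 12

    def test_distance_two_stays_separate(self):
        records = collapse_barcodes({"AAAAAAAAAA": 10, "AAAAAAAATT": 2})
        assert len(records) == 2

    def test_different_lengths_never_collapse(self):
        records = collapse_barcodes({"AAAAAAAAAA": 10, "AAAAAAAAA": 2})
        assert len(records) == 2

    @given(barcode_sets)
    def test_count_conserved_and_idempotent(self, raw):
        records = collapse_barcodes(raw)
        assert sum(r.count for r in records) == sum(raw.values())
        for r in records:
            assert sum(r.members.values()) == r.count
        again = collapse_barcodes({r.barcode: r.count for r in records})
        assert {r.barcode: r.count for r in again} == {
            r.barcode: r.count for r in records
        }

    @given(barcode_sets)
    def test_matches_exhaustive_hamming_oracle(self, raw):
        got = {r.barcode: r.count for r in collapse_barcodes(raw)}
        assert got == naive_collapse(raw)

    def test_matches_oracle_on_large_random_set(self, rng):
        barcodes = set()
        while len(barcodes) < 400:
            barcodes.add("".join(rng.choice(list("ACGT"), 10)))
        raw = {bc: int(rng.integers(1, 200)) for bc in barcodes}
        # add planted 1-mismatch neighbors to force absorptions
        for bc in list(raw)[:60]:
            mutated = ("T" if bc[0] != "T" else "A") + bc[1:]
            raw.setdefault(mutated, int(rng.integers(1, 20)))
        got = {r.barcode: r.count for r in collapse_barcodes(raw)}
        assert got == naive_collapse(raw)


class TestFilter:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["lib1", "lib2", "lib3", "lib4"]
        ).set_axis(list(rows), axis=0)

    def test_single_library_removed(self):
        counts = pd.DataFrame({"lib1": [40], "lib2": [0], "lib3": [0], "lib4": [0]},
                              index=["AAAAAAAAAA"])
        assert len(filter_count_table(counts)) == 0

    def test_total_below_33_removed(self):
        counts = pd.DataFrame(
            {"lib1": [10], "lib2": [10], "lib3": [6], "lib4": [6]},
            index=["AAAAAAAAAA"],
        )
        assert len(filter_count_table(counts)) == 0
        counts.iloc[0, 0] = 11  # total 33 kept
        assert len(filter_count_table(counts)) == 1

    def test_xhoi_site_removed_regardless_of_counts(self):
        counts = pd.DataFrame(
            {"lib1": [100], "lib2": [100], "lib3": [100], "lib4": [100]},
            index=["AACTCGAGAA"],
        )
        assert len(filter_count_table(counts)) == 0


class TestMatchGuide:
    library = {
        "g1": "ATGCATGCATGCATGCATGC",
        "g2": "TTTTGGGGCCCCAAAATTTT",
        EMPTY_GUIDE_ID: "GTTTTAGAGCTAGAAATAGC",
    }

    def test_exact_match_perfect(self):
        out = match_guide(self.library["g1"], Q38 * 20, self.library)
        assert out.status == "perfect" and out.guide_id == "g1" and out.edits == 0

    def test_single_substitution_imperfect(self):
        seq = "ATGCATGCATGCATGCATGA"
        out = match_guide(seq, Q38 * 20, self.library)
        assert out.status == "imperfect" and out.guide_id == "g1" and out.edits == 1

    def test_single_deletion_imperfect(self):
        seq = self.library["g1"][:9] + self.library["g1"][10:]
        out = match_guide(seq, Q38 * 19, self.library)
        assert out.status == "imperfect" and out.edits == 1

    def test_low_quality_base_discarded(self):
        qual = Q38 * 10 + chr(29 + 33) + Q38 * 9  # one base at Q29
        out = match_guide(self.library["g1"], qual, self.library)
        assert out.status == "low_quality"

    def test_far_sequence_unmatched(self):
        out = match_guide("ACACACACACACACACACAC", Q38 * 20, self.library)
        assert out.status == "unmatched"

    def test_edit_distances_match_dp_oracle(self, rng):
        def levenshtein(a, b):
            prev = list(range(len(b) + 1))
            for i, ca in enumerate(a, 1):
                cur = [i]
                for j, cb in enumerate(b, 1):
                    cur.append(min(prev[j] + 1, cur[-1] + 1,
                                   prev[j - 1] + (ca != cb)))
                prev = cur
            return prev[-1]

        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), 20))
            out = match_guide(seq, Q38 * 20, self.library)
            dists = {gid: levenshtein(seq, g) for gid, g in self.library.items()}
            best = min(dists.values())
            if best > 3:
                assert out.status == "unmatched"
            elif sorted(dists.values())[1] == best:
                assert out.status == "ambiguous"
            else:
                assert out.edits == best
                assert dists[out.guide_id] == best


def perfect(guide, n):
    return [MatchOutcome("perfect", guide, 0)] * n


def imperfect(guide, n, edits=1):
    return [MatchOutcome("imperfect", guide, edits)] * n


def brute_force_fate(outcomes):
    """Independent rule-table classifier for a barcode's read outcomes."""
    hq = [o for o in outcomes if o.status != "low_quality"]
    if len(hq) < 3:
        return "insufficient"
    usable = [o for o in hq if o.status in ("perfect", "imperfect")]
    counts = {}
    for o in usable:
        counts[o.guide_id] = counts.get(o.guide_id, 0) + 1
    if not counts:
        return "heterogeneous"
    major = max(counts, key=lambda g: (counts[g], g))
    if counts[major] / len(usable) < 0.9:
        return "heterogeneous"
    major_reads = [o for o in usable if o.guide_id == major]
    n_perfect = sum(o.edits == 0 for o in major_reads)
    if n_perfect > len(major_reads) - n_perfect:
        return "empty" if major == EMPTY_GUIDE_ID else "assigned"
    return "defective"


class TestAssignment:
    def test_two_hq_reads_insufficient(self):
        rec = assign_barcode(perfect("g1", 2), "BC")
        assert rec.fate == "insufficient"

    def test_low_quality_reads_do_not_count(self):
        outcomes = perfect("g1", 2) + [MatchOutcome("low_quality")] * 5
        assert assign_barcode(outcomes).fate == "insufficient"

    def test_eight_of_ten_heterogeneous(self):
        outcomes = perfect("g1", 8) + perfect("g2", 2)
        rec = assign_barcode(outcomes)
        assert rec.fate == "heterogeneous"
        assert rec.majority_fraction == pytest.approx(0.8)

    def test_nine_of_ten_assigned(self):
        outcomes = perfect("g1", 9) + perfect("g2", 1)
        rec = assign_barcode(outcomes)
        assert rec.fate == "assigned" and rec.guide_id == "g1"

    def test_all_perfect_assigned(self):
        rec = assign_barcode(perfect("g1", 5))
        assert rec.fate == "assigned" and rec.guide_id == "g1"

    def test_consistent_deletion_defective(self):
        rec = assign_barcode(imperfect("g1", 5))
        assert rec.fate == "defective"

    def test_lone_sequencing_error_tolerated(self):
        rec = assign_barcode(perfect("g1", 5) + imperfect("g1", 1))
        assert rec.fate == "assigned"

    def test_scaffold_majority_is_empty_fate(self):
        rec = assign_barcode(perfect(EMPTY_GUIDE_ID, 4))
        assert rec.fate == "empty" and rec.guide_id == EMPTY_GUIDE_ID

    def test_fates_partition_and_tally_sums(self):
        grouped = {
            "b1": perfect("g1", 5),
            "b2": perfect("g1", 2),
            "b3": perfect("g1", 8) + perfect("g2", 2),
            "b4": imperfect("g1", 4),
            "b5": perfect(EMPTY_GUIDE_ID, 3),
        }
        table, tally = assign_barcodes(grouped)
        assert tally.sum() == len(grouped)
        assert set(table["fate"]) <= set(tally.index)
        assert tally["assigned"] == 1 and tally["empty"] == 1

    def test_exhaustive_grid_matches_brute_force(self):
        """All (n reads, majority split, perfection) combinations, n = 1-12."""
        for n in range(1, 13):
            for n_major in range(0, n + 1):
                n_other = n - n_major
                for major_perfect, n_lq in itertools.product([True, False],
                                                             [0, 1, 2]):
                    major = (perfect if major_perfect else imperfect)("g1", n_major)
                    outcomes = (
                        major
                        + perfect("g2", n_other)
                        + [MatchOutcome("low_quality")] * n_lq
                    )
                    got = assign_barcode(outcomes).fate
                    assert got == brute_force_fate(outcomes), (
                        n, n_major, major_perfect, n_lq
                    )

    def test_unmatched_reads_excluded_from_majority(self):
        outcomes = perfect("g1", 5) + [MatchOutcome("unmatched")] * 3
        rec = assign_barcode(outcomes)
        assert rec.fate == "assigned"
        assert rec.majority_fraction == 1.0


class TestSimulatedReadRecovery:
    def test_planted_rates_recovered(self, tmp_path):
        """Defective/heterogeneous fractions match the planted 10%/5% rates."""
        from crispri_screenkit import io
        from crispri_screenkit.barcodes import assign_from_fastq
        from crispri_screenkit.simulate import (
            SimScreenSpec,
            simulate_assignment_reads,
        )

        rng = np.random.default_rng(17)
        guides = {
            f"g{i:03d}": "".join(rng.choice(list("ACGT"), 20)) for i in range(60)
        }
        spec = SimScreenSpec(n_guides=60, seed=17)
        reads = simulate_assignment_reads(guides, spec)
        io.write_fastq(tmp_path / "r1.fq", reads.r1)
        io.write_fastq(tmp_path / "r2.fq", reads.r2)
        table, tally = assign_from_fastq(
            tmp_path / "r1.fq", tmp_path / "r2.fq", reads.library
        )
        n = tally.sum()
        for fate, rate in (("defective", spec.synthesis_error_rate),
                           ("heterogeneous", spec.chimera_rate)):
            frac = tally[fate] / n
            sd = np.sqrt(rate * (1 - rate) / n)
            assert abs(frac - rate) < 3 * sd, (fate, frac, rate)

    def test_noiseless_reads_recover_truth_exactly(self, tmp_path):
        from crispri_screenkit import io
        from crispri_screenkit.barcodes import assign_from_fastq
        from crispri_screenkit.simulate import (
            SimScreenSpec,
            simulate_assignment_reads,
        )

        rng = np.random.default_rng(3)
        guides = {
            f"g{i:03d}": "".join(rng.choice(list("ACGT"), 20)) for i in range(20)
        }
        spec = SimScreenSpec(
            n_guides=20, seed=3, synthesis_error_rate=0.0, chimera_rate=0.0,
            empty_fraction=0.0, sequencing_error_rate=0.0, low_quality_rate=0.0,
            low_read_fraction=0.0,
        )
        reads = simulate_assignment_reads(guides, spec)
        io.write_fastq(tmp_path / "r1.fq", reads.r1)
        io.write_fastq(tmp_path / "r2.fq", reads.r2)
        table, tally = assign_from_fastq(
            tmp_path / "r1.fq", tmp_path / "r2.fq", reads.library
        )
        merged = table.set_index("barcode").join(reads.truth, rsuffix="_true")
        ok = merged["fate_true"].isin(["assigned"])
        assert (merged.loc[ok, "fate"] == "assigned").all()
        assert (merged.loc[ok, "guide_id"] == merged.loc[ok, "guide_id_true"]).all()
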