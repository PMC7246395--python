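"""The presence/absence sex-specificity screen and its exclusion filters."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import ddradsex
from ddradsex.samples import Sample
from ddradsex.seqs import revcomp
from ddradsex.sexscreen import (
    CandidateMarker,
    ScreenParams,
    build_presence_matrix,
    consolidate_pe_pairs,
    exclude_cross_sex_matches,
    screen_sex_specific,
)


def make_cohort(n_m=20, n_f=20):
    # barcodes are irrelevant here but must be unique/equal-length
    from itertools import product

    codes = ["".join(p) for p in product("ACGT", repeat=3)]
    samples = [Sample(f"M{i+1:02d}", "M", codes[i]) for i in range(n_m)]
    samples += [Sample(f"F{i+1:02d}", "F", codes[n_m + i]) for i in range(n_f)]
    return samples


def matches_for(catalog_id, individuals):
    return [(ind, catalog_id) for ind in individuals]


class TestPresenceMatrix:
    def test_empty_matches_all_false(self):
        samples = make_cohort(2, 2)
        matrix = build_presence_matrix([], samples)
        assert matrix.table.empty

    def test_single_cell(self):
        samples = make_cohort(2, 2)
        matrix = build_presence_matrix([("M01", "c7")], samples)
        assert matrix.table.values.sum() == 1
        assert bool(matrix.table.at["c7", "M01"])

    def test_full_row(self):
        samples = make_cohort(20, 20)
        matrix = build_presence_matrix(
            matches_for("c1", [s.sample_id for s in samples]), samples
        )
        assert matrix.table.loc["c1"].all()

    def test_unknown_individual_rejected(self):
        with pytest.raises(ValueError, match="sample sheet"):
            build_presence_matrix([("ghost", "c1")], make_cohort(2, 2))


class TestScreenRule:
    samples = make_cohort(20, 20)
    males = [s.sample_id for s in samples if s.sex == "M"]
    females = [s.sample_id for s in samples if s.sex == "F"]

    def screen(self, matches):
        matrix = build_presence_matrix(matches, self.samples)
        return screen_sex_specific(matrix, ScreenParams(tolerance=1))

    def test_19_of_20_males_zero_females_is_candidate(self):
        out = self.screen(matches_for("c1", self.males[:19]))
        assert out["M"] == ["c1"] and out["F"] == []

    def test_20_of_20_males_is_candidate(self):
        out = self.screen(matches_for("c1", self.males))
        assert out["M"] == ["c1"]

    def test_18_of_20_males_fails_threshold(self):
        out = self.screen(matches_for("c1", self.males[:18]))
        assert out["M"] == []

    def test_single_female_presence_disqualifies(self):
        matches = matches_for("c1", self.males[:19]) + [(self.females[0], "c1")]
        out = self.screen(matches)
        assert out["M"] == []

    def test_tolerance_must_be_below_cohort_size(self):
        matrix = build_presence_matrix([("M01", "c1")], make_cohort(3, 3))
        with pytest.raises(ValueError, match="tolerance"):
            screen_sex_specific(matrix, ScreenParams(tolerance=3))

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.booleans()), min_size=1, max_size=30
        ),
        st.integers(0, 3),
    )
    def test_tolerance_monotonicity(self, rows, tolerance):
        """Raising the tolerance can only grow each candidate set."""
        samples = make_cohort(5, 5)
        ids = [s.sample_id for s in samples]
        matches = []
        for cat_idx, (n_males, add_female) in enumerate(rows):
            cid = f"c{cat_idx}"
            matches += matches_for(cid, ids[:n_males])
            if add_female:
                matches += [(ids[5], cid)]
        matrix = build_presence_matrix(matches, samples)
        lo = screen_sex_specific(matrix, ScreenParams(tolerance=tolerance))
        hi = screen_sex_specific(matrix, ScreenParams(tolerance=tolerance + 1))
        for sex in ("M", "F"):
            assert set(lo[sex]) <= set(hi[sex])

    @given(st.data())
    def test_sex_relabel_symmetry(self, data):
        """Swapping every individual's sex label swaps the candidate sets."""
        n = 4
        cells = data.draw(
            st.lists(
                st.tuples(st.integers(0, 4), st.integers(0, 2 * n - 1)),
                max_size=40,
            )
        )
        samples = make_cohort(n, n)
        swapped = [
            Sample(s.sample_id, "F" if s.sex == "M" else "M", s.barcode) for s in samples
        ]
        ids = [s.sample_id for s in samples]
        matches = [(ids[i], f"c{c}") for c, i in cells]
        params = ScreenParams(tolerance=1)
        if not matches:
            return
        out = screen_sex_specific(build_presence_matrix(matches, samples), params)
        out_swapped = screen_sex_specific(build_presence_matrix(matches, swapped), params)
        assert out["M"] == out_swapped["F"] and out["F"] == out_swapped["M"]


class TestConsolidation:
    consensus = {"r1_00001": "A" * 135, "r2_00004": "C" * 135, "r1_00002": "G" * 135}
    member = {"r1_00001": 1, "r2_00004": 2, "r1_00002": 1}

    def test_shared_pair_ids_merge_into_one_marker(self):
        pair_ids = {"r1_00001": {"p1", "p2"}, "r2_00004": {"p2", "p3"}}
        markers = consolidate_pe_pairs(
            ["r1_00001", "r2_00004"], "M", pair_ids, self.consensus, self.member
        )
        assert len(markers) == 1
        assert markers[0].pe_consolidated
        assert markers[0].member_catalog_ids == {1: "r1_00001", 2: "r2_00004"}
        assert markers[0].marker_id == "MSL1"

    def test_disjoint_pair_ids_stay_separate(self):
        pair_ids = {"r1_00001": {"p1"}, "r2_00004": {"p9"}}
        markers = consolidate_pe_pairs(
            ["r1_00001", "r2_00004"], "M", pair_ids, self.consensus, self.member
        )
        assert len(markers) == 2
        assert not any(m.pe_consolidated for m in markers)

    def test_same_member_candidates_never_merge(self):
        pair_ids = {"r1_00001": {"p1"}, "r1_00002": {"p1"}}
        markers = consolidate_pe_pairs(
            ["r1_00001", "r1_00002"], "M", pair_ids, self.consensus, self.member
        )
        assert len(markers) == 2

    def test_empty_candidates(self):
        assert consolidate_pe_pairs([], "M", {}, {}, {}) == []


class TestCrossSexExclusion:
    def marker(self, seq1, seq2=None, marker_id="MSL1"):
        members = {1: seq1} if seq2 is None else {1: seq1, 2: seq2}
        return CandidateMarker(marker_id, "M", {m: f"r{m}_x" for m in members}, members)

    def test_exact_female_read_removes_marker(self):
        seq = ("ACGT" * 40)[:135]
        survivors = exclude_cross_sex_matches([self.marker(seq)], [seq, "T" * 135])
        assert survivors == []

    def test_published_marker_read_survives_unrelated_reads(self):
        records = {r.id: str(r.seq) for r in ddradsex.load_msl_fixture()}
        msl4 = self.marker(records["MSL4/1"], records["MSL4/2"], "MSL4")
        female_reads = [records["MSL1/1"][:135], "A" * 135, "C" * 135]
        survivors = exclude_cross_sex_matches([msl4], female_reads)
        assert len(survivors) == 1 and not survivors[0].cross_sex_excluded

    def test_one_mismatch_does_not_exclude(self):
        seq = ("ACGT" * 40)[:135]
        near = "T" + seq[1:]
        assert len(exclude_cross_sex_matches([self.marker(seq)], [near])) == 1

    def test_revcomp_matching_off_by_default(self):
        seq = ("AACGT" * 27)[:135]
        assert len(exclude_cross_sex_matches([self.marker(seq)], [revcomp(seq)])) == 1
        assert (
            exclude_cross_sex_matches([self.marker(seq)], [revcomp(seq)], include_revcomp=True)
            == []
        )

    def test_agrees_with_bruteforce_equality_scan(self):
        """Set-based exclusion equals the quadratic all-pairs scan."""
        import random

        rng = random.Random(5)
        alphabet = "ACGT"
        reads = ["".join(rng.choice(alphabet) for _ in range(20)) for _ in range(2000)]
        markers = [self.marker(rng.choice(reads), marker_id=f"MSL{i}") for i in range(3)]
        markers += [
            self.marker("".join(rng.choice(alphabet) for _ in range(20)), marker_id=f"MSL{i+3}")
            for i in range(3)
        ]

        def brute_force(markers, reads):
            kept = []
            for mk in markers:
                if not any(r == s for r in reads for s in mk.sequences):
                    kept.append(mk.marker_id)
            return kept

        expected = brute_force(markers, reads)
        got = [m.marker_id for m in exclude_cross_sex_matches(markers, reads)]
        assert got == expected
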