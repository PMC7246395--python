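"""Digestion, size selection and library simulation."""

import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddradsex.samples import Sample
from ddradsex.seqs import matches_iupac_prefix, revcomp
from ddradsex.simdata import (
    AVAII,
    MSPI,
    Fragment,
    SimulationParams,
    digest,
    digest_named,
    generate_library,
    make_genome_pair,
    pe_template,
    select_fragments,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=500)


def oracle_cuts(seq: str) -> list[int]:
    """Independent brute-force scan: regex match at every offset, cut 1 nt in."""
    cuts = set()
    for pattern, offset in (("GG[AT]CC", 1), ("CCGG", 1)):
        for i in range(len(seq)):
            if re.match(pattern, seq[i:]):
                cuts.add(i + offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


class TestDigest:
    @pytest.mark.parametrize(
        "seq,enzymes,expected",
        [
            ("AAGGACCAA", [AVAII], ["AAG", "GACCAA"]),
            ("TTCCGGTT", [MSPI], ["TTC", "CGGTT"]),
            ("AAATTTAAA", [AVAII, MSPI], ["AAATTTAAA"]),
        ],
    )
    def test_worked_examples(self, seq, enzymes, expected):
        assert [f.sequence for f in digest(seq, enzymes)] == expected

    def test_boundary_enzymes_recorded(self):
        frags = digest("AAGGACCAACCGGAA")
        assert [(f.left_enzyme, f.right_enzyme) for f in frags] == [
            ("terminus", "AvaII"),
            ("AvaII", "MspI"),
            ("MspI", "terminus"),
        ]

    def test_n_never_matches_a_site(self):
        assert len(digest("AAGGNCCAA")) == 1
        assert len(digest("AACNGGAA")) == 1

    def test_empty_and_invalid_input(self):
        assert digest("") == []
        with pytest.raises(ValueError):
            digest("AAXGG")
        with pytest.raises(ValueError):
            digest("aacc")  # lowercase rejected

    @given(dna)
    def test_fragments_partition_sequence(self, seq):
        frags = digest(seq)
        assert "".join(f.sequence for f in frags) == seq
        # non-overlapping, ordered, coordinates consistent
        pos = 0
        for f in frags:
            assert (f.start, f.end) == (pos, pos + len(f.sequence))
            pos = f.end

    @given(dna)
    def test_cut_positions_match_bruteforce_oracle(self, seq):
        got = [f.end for f in digest(seq)][:-1] if seq else []
        assert got == oracle_cuts(seq)


class TestSelectFragments:
    def _frag(self, length, left, right):
        return Fragment("s", 0, length, "A" * length, left, right)

    @pytest.mark.parametrize(
        "length,left,right,kept",
        [
            (550, "AvaII", "MspI", True),
            (550, "MspI", "AvaII", True),
            (500, "AvaII", "MspI", True),
            (600, "MspI", "AvaII", True),
            (499, "AvaII", "MspI", False),
            (601, "AvaII", "MspI", False),
            (550, "AvaII", "AvaII", False),
            (550, "MspI", "MspI", False),
            (550, "terminus", "MspI", False),
        ],
    )
    def test_size_window_and_mixed_flanks(self, length, left, right, kept):
        params = SimulationParams()
        got = select_fragments([self._frag(length, left, right)], params)
        assert bool(got) == kept


class TestPETemplate:
    def _sitefree(self, rng, n):
        while True:
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            if not re.search("GG[AT]CC|CCGG", s):
                return s

    @pytest.mark.parametrize("avaii_first", [True, False])
    def test_orientation_normalised_to_avaii_end(self, avaii_first):
        rng = np.random.default_rng(3)
        core = self._sitefree(rng, 540)
        if avaii_first:
            seq = self._sitefree(rng, 60) + "GGACC" + core + "CCGG" + self._sitefree(rng, 60)
        else:
            seq = self._sitefree(rng, 60) + "CCGG" + core + "GGACC" + self._sitefree(rng, 60)
        params = SimulationParams()
        selected = select_fragments(digest_named(seq, "s"), params)
        assert len(selected) == 1
        template = pe_template(seq, selected[0])
        # read 1 always shows the AvaII half-site, read 2 the observed GG prefix
        assert matches_iupac_prefix(template, "GWCC")
        assert revcomp(template).startswith("GG")


class TestGenomePair:
    def test_planted_fragments_are_selectable_ground_truth(self, small_params):
        genomes = make_genome_pair(small_params)
        assert len(genomes.truth_table) == 2
        for t in genomes.truth_table:
            assert t.end - t.start == small_params.male_specific_fragment_length
            seq = genomes.male_extra_sequences[t.source_name]
            selected = select_fragments(digest_named(seq, t.source_name), small_params)
            assert [(f.start, f.end) for f in selected] == [(t.start, t.end)]
            assert matches_iupac_prefix(t.read1_seq, "GWCC")
            assert t.read2_seq.startswith("GG")

    def test_male_genome_is_shared_plus_extra(self, small_params):
        genomes = make_genome_pair(small_params)
        assert set(genomes.male_sequences) == set(genomes.shared_sequences) | set(
            genomes.male_extra_sequences
        )


class TestLibrary:
    def test_reads_carry_remnants_and_provenance(self, small_params, small_samples):
        genomes = make_genome_pair(small_params)
        records = list(generate_library(genomes, small_samples, small_params))
        assert records, "library should not be empty"
        bc = {s.sample_id: s.barcode for s in small_samples}
        for rec in records[:500]:
            assert rec.seq1.startswith(bc[rec.sample_id])
            assert matches_iupac_prefix(rec.seq1[len(bc[rec.sample_id]):], "GWCC")
            assert rec.seq2.startswith("GG")
            assert len(rec.seq1) == len(rec.seq2) == small_params.read_length

    def test_females_never_draw_from_male_extra(self, small_params, small_samples):
        genomes = make_genome_pair(small_params)
        male_sources = set(genomes.male_extra_sequences)
        for rec in generate_library(genomes, small_samples, small_params):
            sex = next(s.sex for s in small_samples if s.sample_id == rec.sample_id)
            if sex == "F":
                assert rec.fragment_id.split(":")[0] not in male_sources

    def test_planted_fragment_visibility_at_depth(self, small_params, small_samples):
        """Error-free, depth >= 2m: every male shows >= m identical read-1 copies."""
        m = 10
        assert small_params.error_rate == 0 and small_params.mean_depth >= 2 * m
        genomes = make_genome_pair(small_params)
        counts: dict[tuple[str, str], int] = {}
        for rec in generate_library(genomes, small_samples, small_params):
            src = rec.fragment_id.split(":")[0]
            if src in genomes.male_extra_sequences:
                counts[rec.sample_id, src] = counts.get((rec.sample_id, src), 0) + 1
        for s in small_samples:
            if s.sex == "M":
                for src in genomes.male_extra_sequences:
                    assert counts.get((s.sample_id, src), 0) >= m

    def test_seeded_determinism(self, small_params, small_samples):
        genomes = make_genome_pair(small_params)
        a = list(generate_library(genomes, small_samples, small_params))
        b = list(generate_library(genomes, small_samples, small_params))
        assert a == b

    def test_barcode_collision_rejected(self, small_params):
        genomes = make_genome_pair(small_params)
        samples = [Sample("A", "M", "AACGT"), Sample("B", "F", "AACGT")]
        with pytest.raises(ValueError, match="collision"):
            list(generate_library(genomes, samples, small_params))

    def test_params_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationParams(size_min=600, size_max=500).validate()
        with pytest.raises(ValueError):
            SimulationParams(read_length=600).validate()
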