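"""Validation-side computations and the final marker report.

When a candidate marker is amplified and Sanger-sequenced in independent
individuals, the amplicon sequences are combined into a consensus and
checked for conservation (pairwise identity, variant columns), and the
marker's ddRAD read pair is located inside the amplicon to confirm the
same genomic origin: member 1 on the forward strand, member 2 as its
reverse complement (the amplicon spans the fragment, and read 2 was
sequenced from the opposite end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

from .seqs import is_valid_sequence, revcomp
from .sexscreen import CandidateMarker


@dataclass
class AmpliconSet:
    """Amplicon sequences for one marker, one per validated individual."""

    marker_id: str
    sequences: dict[str, str]  # individual name -> sequence

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.marker_id}: empty amplicon set")
        for name, seq in self.sequences.items():
            if not seq or not is_valid_sequence(seq):
                raise ValueError(f"{self.marker_id}/{name}: invalid sequence")


@dataclass
class ConsensusResult:
    consensus: str
    length: int
    identity: float  # mean pairwise fraction of matching columns, in [0, 1]
    variant_positions: list[int] = field(default_factory=list)


@dataclass
class MemberLocation:
    member: int
    start: int | None  # 0-based half-open interval in the consensus; None if absent
    end: int | None
    strand: str  # "+" for member 1, "-" for member 2
    multiple: bool = False  # occurs more than once (first occurrence reported)

    @property
    def found(self) -> bool:
        return self.start is not None


def build_consensus(amplicons: AmpliconSet) -> ConsensusResult:
    """Column-wise majority consensus of equal-length amplicons.

    Ties break to the lexicographically smallest base. Identity is the
    mean over all sequence pairs of (matching columns / length); a single
    sequence has identity 1.0 by convention. Unequal lengths are an
    error: align externally first (indel alignment is out of scope here,
    and conserved amplicons need none).
    """
    seqs = list(amplicons.sequences.values())
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(
            f"{amplicons.marker_id}: unequal amplicon lengths {sorted(lengths)}; "
            "pre-align externally before building a consensus"
        )
    length = lengths.pop()
    consensus = []
    variants = []
    for i in range(length):
        column = [s[i] for s in seqs]
        votes: dict[str, int] = {}
        for b in column:
            votes[b] = votes.get(b, 0) + 1
        consensus.append(min(votes, key=lambda b: (-votes[b], b)))
        if len(votes) > 1:
            variants.append(i)
    if len(seqs) == 1:
        identity = 1.0
    else:
        pair_ids = [
            sum(a == b for a, b in zip(s1, s2)) / length
            for s1, s2 in combinations(seqs, 2)
        ]
        identity = sum(pair_ids) / len(pair_ids)
    return ConsensusResult("".join(consensus), length, identity, variants)


def locate_marker_reads(consensus: str, marker: CandidateMarker) -> list[MemberLocation]:
    """Find each marker member's exact occurrence within an amplicon consensus.

    Member 1 is searched on the forward strand, member 2 as a reverse
    complement. The first occurrence is reported; additional occurrences
    set ``multiple``.
    """
    locations = []
    for member in sorted(marker.member_sequences):
        seq = marker.member_sequences[member]
        query = seq if member == 1 else revcomp(seq)
        strand = "+" if member == 1 else "-"
        start = consensus.find(query)
        if start < 0:
            locations.append(MemberLocation(member, None, None, strand))
        else:
            multiple = consensus.find(query, start + 1) >= 0
            locations.append(
                MemberLocation(member, start, start + len(query), strand, multiple)
            )
    return locations


def read_amplicon_fasta(path: str | Path, marker_id: str) -> AmpliconSet:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return AmpliconSet(marker_id, seqs)


def write_marker_report(
    markers: Sequence[CandidateMarker],
    consensus_results: Mapping[str, ConsensusResult],
    metadata: Mapping[str, object],
    tsv_path: str | Path,
    summary_path: str | Path,
) -> None:
    """Machine-readable TSV plus human-readable summary, ordered by marker id.

    ``consensus_results`` maps marker id -> amplicon consensus (may be
    empty when no validation sequences exist). Output is deterministic:
    reruns on the same inputs are byte-identical.
    """
    ordered = sorted(markers, key=lambda m: (m.sex, m.marker_id))
    with open(tsv_path, "w") as fh:
        fh.write(
            "marker_id\tsex\tmembers\tpe_consolidated\tcross_sex_excluded\t"
            "presence_counts\tconsensus_length\tconsensus_identity\t"
            "variant_positions\tsequences\n"
        )
        for mk in ordered:
            cons = consensus_results.get(mk.marker_id)
            counts = ";".join(
                f"member{m}:" + ",".join(f"{s}={c}" for s, c in sorted(mk.presence_counts[m].items()))
                for m in sorted(mk.presence_counts)
            )
            fh.write(
                f"{mk.marker_id}\t{mk.sex}\t{len(mk.member_sequences)}\t"
                f"{mk.pe_consolidated}\t{mk.cross_sex_excluded}\t{counts}\t"
                f"{cons.length if cons else ''}\t"
                f"{f'{cons.identity:.6f}' if cons else ''}\t"
                f"{','.join(map(str, cons.variant_positions)) if cons else ''}\t"
                f"{','.join(mk.sequences)}\n"
            )
    with open(summary_path, "w") as fh:
        fh.write("Sex-specific marker report\n")
        fh.write("==========================\n")
        for key in sorted(metadata):
            fh.write(f"{key}: {metadata[key]}\n")
        fh.write(f"markers: {len(ordered)}\n\n")
        for mk in ordered:
            sex_name = {"M": "male", "F": "female"}.get(mk.sex, mk.sex)
            fh.write(
                f"{mk.marker_id}: {sex_name}-specific, "
                f"{len(mk.member_sequences)} member sequence(s), "
                f"PE-consolidated={mk.pe_consolidated}\n"
            )
            for m in sorted(mk.presence_counts):
                counts = ", ".join(f"{s}: {c}" for s, c in sorted(mk.presence_counts[m].items()))
                fh.write(f"  member {m} presence — {counts}\n")
            cons = consensus_results.get(mk.marker_id)
            if cons:
                fh.write(
                    f"  amplicon consensus: {cons.length} nt, identity {cons.identity:.4f}, "
                    f"{len(cons.variant_positions)} variant position(s)\n"
                )
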