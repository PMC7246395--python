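"""Presence/absence screening for sex-specific catalog loci.

The inference at the heart of the pipeline: from the per-individual
catalog match records, build a catalog-by-individual presence matrix,
then call a catalog locus sex-specific when it is present in at least
N - tolerance individuals of one sex (default tolerance 1, i.e. >= N-1)
and in ZERO individuals of the other sex — the absence side is a hard
zero and is never relaxed. Candidate loci that are the two read members
of the same sequenced fragments are consolidated into one genomic
marker, and any marker whose sequence is exactly matched by a clean read
of the opposite sex (a grep-style full-length identity scan) is thrown
out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .demux import CleanReadSet
from .samples import Sample
from .seqs import revcomp


@dataclass
class ScreenParams:
    """``tolerance`` = how many individuals of the target sex may lack the
    locus (default 1 -> the >= N-1 rule); absence in the other sex is
    always required of ALL individuals."""

    tolerance: int = 1
    screen_sexes: tuple[str, ...] = ("M", "F")

    def validate(self, n_by_sex: Mapping[str, int]) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        for sex in self.screen_sexes:
            n = n_by_sex.get(sex, 0)
            if n < 1:
                raise ValueError(f"no individuals of sex {sex!r}")
            if self.tolerance >= n:
                raise ValueError(
                    f"tolerance {self.tolerance} must be < number of {sex} individuals ({n})"
                )


@dataclass
class PresenceMatrix:
    """Boolean catalog-by-individual matrix plus the sex label per column."""

    table: pd.DataFrame  # index: catalog ids, columns: individual ids, bool
    sex_by_individual: dict[str, str]

    def individuals_of(self, sex: str) -> list[str]:
        return [i for i in self.table.columns if self.sex_by_individual[i] == sex]


@dataclass
class CandidateMarker:
    """A sex-specific marker: one or two PE-consolidated catalog loci."""

    marker_id: str
    sex: str
    member_catalog_ids: dict[int, str]  # read member (1/2) -> catalog id
    member_sequences: dict[int, str]
    presence_counts: dict[int, dict[str, int]] = field(default_factory=dict)
    pe_consolidated: bool = False
    cross_sex_excluded: bool = False

    @property
    def sequences(self) -> list[str]:
        return [self.member_sequences[m] for m in sorted(self.member_sequences)]


def build_presence_matrix(
    matches: Iterable[tuple[str, str]], samples: list[Sample]
) -> PresenceMatrix:
    """presence(c, i) is True iff the matches table has a row (i, c).

    *matches* yields at least (individual_id, catalog_id); extra tuple
    elements (locus id, mismatch count) are ignored — presence is any
    match row, regardless of mismatches.
    """
    known = {s.sample_id for s in samples}
    cells: set[tuple[str, str]] = set()
    for row in matches:
        individual_id, catalog_id = row[0], row[1]
        if individual_id not in known:
            raise ValueError(f"individual {individual_id!r} not in sample sheet")
        cells.add((catalog_id, individual_id))
    catalog_ids = sorted({c for c, _ in cells})
    columns = [s.sample_id for s in samples]
    table = pd.DataFrame(False, index=catalog_ids, columns=columns, dtype=bool)
    for c, i in cells:
        table.at[c, i] = True
    return PresenceMatrix(table, {s.sample_id: s.sex for s in samples})


def screen_sex_specific(
    matrix: PresenceMatrix, params: ScreenParams
) -> dict[str, list[str]]:
    """Candidate catalog ids per sex under the >=N-tolerance / absent rule."""
    n_by_sex = {
        sex: len(matrix.individuals_of(sex)) for sex in set(matrix.sex_by_individual.values())
    }
    params.validate(n_by_sex)
    out: dict[str, list[str]] = {}
    for sex in params.screen_sexes:
        own = matrix.individuals_of(sex)
        other = [i for i in matrix.table.columns if i not in own]
        threshold = len(own) - params.tolerance
        if matrix.table.empty:
            out[sex] = []
            continue
        own_counts = matrix.table[own].sum(axis=1)
        other_counts = matrix.table[other].sum(axis=1) if other else 0
        mask = (own_counts >= threshold) & (other_counts == 0)
        out[sex] = sorted(matrix.table.index[mask])
    return out


def consolidate_pe_pairs(
    candidate_ids: Sequence[str],
    sex: str,
    pair_ids_by_catalog: Mapping[str, set[str]],
    consensus_by_catalog: Mapping[str, str],
    member_by_catalog: Mapping[str, int],
    presence_matrix: PresenceMatrix | None = None,
    marker_prefix: str | None = None,
) -> list[CandidateMarker]:
    """Merge candidate loci that are two members of the same read pairs.

    Two candidates consolidate into one marker when one is a read-1 locus
    and the other a read-2 locus and their underlying loci share at least
    one originating read-pair id (the sequenced fragment is ~500 bp, so
    its two 135-nt reads are one genomic locus). Unpaired candidates
    become single-member markers, flagged pe_consolidated=False.
    """
    prefix = marker_prefix or (f"{sex}SL" if sex in ("M", "F") else "SL")
    ordered = sorted(candidate_ids)
    used: set[str] = set()
    groups: list[list[str]] = []
    for cid in ordered:
        if cid in used:
            continue
        group = [cid]
        used.add(cid)
        for other in ordered:
            if other in used or member_by_catalog[other] == member_by_catalog[cid]:
                continue
            if pair_ids_by_catalog[cid] & pair_ids_by_catalog[other]:
                group.append(other)
                used.add(other)
        groups.append(group)

    markers = []
    for idx, group in enumerate(sorted(groups), start=1):
        members = {member_by_catalog[c]: c for c in group}
        marker = CandidateMarker(
            marker_id=f"{prefix}{idx}",
            sex=sex,
            member_catalog_ids=members,
            member_sequences={m: consensus_by_catalog[c] for m, c in members.items()},
            pe_consolidated=len(members) == 2,
        )
        if presence_matrix is not None:
            for m, c in members.items():
                row = presence_matrix.table.loc[c]
                marker.presence_counts[m] = {
                    s: int(row[presence_matrix.individuals_of(s)].sum())
                    for s in sorted(set(presence_matrix.sex_by_individual.values()))
                }
        markers.append(marker)
    return markers


def exclude_cross_sex_matches(
    markers: list[CandidateMarker],
    opposite_reads: Iterable[str],
    include_revcomp: bool = False,
) -> list[CandidateMarker]:
    """Drop markers exactly matched by any opposite-sex clean read.

    A marker is removed when ANY opposite-sex clean read is an exact,
    full-length, same-orientation substring of any member sequence —
    since clean reads and locus consensi share the same fixed length,
    this is string equality, mirroring a grep over the read files.
    Reverse-complement matching is off by default (grep would not have
    matched it) and available via *include_revcomp*.
    """
    read_set = set(opposite_reads)
    lengths = {len(r) for r in read_set}
    survivors = []
    for marker in markers:
        hit = False
        for seq in marker.sequences:
            queries = [seq] + ([revcomp(seq)] if include_revcomp else [])
            for q in queries:
                if q in read_set:
                    hit = True
                elif any(len(q) > L for L in lengths):
                    # member longer than the reads: true substring scan
                    if any(r in q for r in read_set):
                        hit = True
                if hit:
                    break
            if hit:
                break
        marker.cross_sex_excluded = hit
        if not hit:
            survivors.append(marker)
    return survivors


def opposite_sex_reads(
    clean_sets: Mapping[str, CleanReadSet], sex: str
) -> list[str]:
    """All clean reads (both members) of every individual NOT of *sex*."""
    reads: list[str] = []
    for clean in clean_sets.values():
        if clean.sex != sex:
            reads.extend(clean.reads1)
            reads.extend(clean.reads2)
    return reads


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    out = matrix.table.astype(int)
    out.index.name = "catalog_id"
    out.to_csv(path, sep="\t")


def write_candidate_report(markers: Sequence[CandidateMarker], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "marker_id\tsex\tmembers\tcatalog_ids\tpe_consolidated\tcross_sex_excluded\t"
            "presence_counts\tsequences\n"
        )
        for mk in sorted(markers, key=lambda m: (m.sex, m.marker_id)):
            cats = ",".join(mk.member_catalog_ids[m] for m in sorted(mk.member_catalog_ids))
            counts = ";".join(
                f"member{m}:" + ",".join(f"{s}={c}" for s, c in sorted(mk.presence_counts[m].items()))
                for m in sorted(mk.presence_counts)
            )
            seqs = ",".join(mk.sequences)
            fh.write(
                f"{mk.marker_id}\t{mk.sex}\t{len(mk.member_catalog_ids)}\t{cats}\t"
                f"{mk.pe_consolidated}\t{mk.cross_sex_excluded}\t{counts}\t{seqs}\n"
            )


def write_marker_fasta(markers: Sequence[CandidateMarker], path: str | Path) -> None:
    """Member sequences per marker, ready for external primer design."""
    with open(path, "w") as fh:
        for mk in sorted(markers, key=lambda m: (m.sex, m.marker_id)):
            for member in sorted(mk.member_sequences):
                fh.write(f">{mk.marker_id}/member{member}\n{mk.member_sequences[member]}\n")
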