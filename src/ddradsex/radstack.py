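"""Within-individual read stacking and the cross-individual locus catalog.

A deterministic, fully specified take on the ustacks/cstacks/sstacks
stages of Stacks, restricted to fixed-length reads and Hamming distance:

* exact-identical reads of one individual are grouped; groups of depth
  >= m seed "stacks", smaller groups are "secondary" reads that can join
  a locus but never found one;
* stacks merge greedily (depth-descending, then lexicographic) into loci
  whenever they lie within M mismatches of a locus consensus; the
  consensus is the per-position depth-weighted majority;
* individual loci enter a shared catalog in sample-sheet order, merging
  into the first catalog entry within n mismatches (the catalog consensus
  is frozen at first insertion);
* finally every individual locus is matched back to its best catalog
  entry, giving the per-individual matches table the sex screen consumes.

Read members 1 and 2 are clustered as independent locus universes; the
originating read-pair ids ride along on every locus for the later PE
consolidation.

Omitted relative to Stacks proper: deleveraging, repetitive-stack
removal, gapped alignment and SNP/genotype calling — none of which the
presence/absence sex screen needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqs import hamming


@dataclass
class StackingParams:
    m: int = 10  # minimum identical reads to seed a stack
    M: int = 3   # max mismatches between a stack and a locus consensus
    n: int = 3   # max mismatches between loci in the catalog (and for matching)

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.M < 0 or self.n < 0:
            raise ValueError("M and n must be >= 0")


@dataclass
class Stack:
    """A group of identical reads from one individual."""

    sequence: str
    depth: int
    read_ids: list[str] = field(default_factory=list)


@dataclass
class Locus:
    """One individual's consensus locus built from merged stacks."""

    individual_id: str
    locus_id: int
    consensus: str
    depth: int
    member_stacks: list[Stack] = field(default_factory=list)

    @property
    def read_ids(self) -> list[str]:
        return [rid for s in self.member_stacks for rid in s.read_ids]


@dataclass
class CatalogLocus:
    catalog_id: int
    consensus: str
    contributors: list[tuple[str, int]] = field(default_factory=list)  # (individual, locus)


@dataclass(frozen=True)
class MatchRow:
    individual_id: str
    catalog_id: int
    locus_id: int
    mismatches: int


def build_stacks(
    reads: Sequence[tuple[str, str]], params: StackingParams
) -> tuple[list[Stack], list[Stack]]:
    """Group identical reads; returns (primary stacks, secondary groups).

    *reads* are (read_id, sequence) of one individual and one member.
    Primary stacks have depth >= m and are ordered depth-descending then
    lexicographic — the deterministic processing order used everywhere
    downstream. Sub-threshold groups come back as secondary: they may be
    absorbed into a locus consensus but cannot seed one.
    """
    params.validate()
    lengths = {len(seq) for _, seq in reads}
    if len(lengths) > 1:
        raise ValueError(f"reads have mixed lengths: {sorted(lengths)}")
    groups: dict[str, list[str]] = {}
    for read_id, seq in reads:
        groups.setdefault(seq, []).append(read_id)
    stacks = [Stack(seq, len(ids), ids) for seq, ids in groups.items()]
    stacks.sort(key=lambda s: (-s.depth, s.sequence))
    primary = [s for s in stacks if s.depth >= params.m]
    secondary = [s for s in stacks if s.depth < params.m]
    return primary, secondary


def _consensus(stacks: list[Stack]) -> str:
    """Per-position depth-weighted majority; ties break to the smallest base."""
    length = len(stacks[0].sequence)
    out = []
    for i in range(length):
        votes: dict[str, int] = {}
        for s in stacks:
            votes[s.sequence[i]] = votes.get(s.sequence[i], 0) + s.depth
        out.append(min(votes, key=lambda b: (-votes[b], b)))
    return "".join(out)


def merge_stacks(
    primary: list[Stack],
    params: StackingParams,
    secondary: Iterable[Stack] = (),
    individual_id: str = "",
) -> list[Locus]:
    """Greedy agglomeration of stacks into loci.

    Primary stacks are processed depth-descending (then lexicographic);
    each joins the first existing locus whose consensus lies within M
    mismatches, else founds a new locus. Secondary groups are then offered
    to the loci under the same rule (they contribute depth and consensus
    votes but never seed). The consensus is recomputed after every join,
    so the merge criterion always refers to the current consensus.
    """
    params.validate()
    ordered = sorted(primary, key=lambda s: (-s.depth, s.sequence))
    if any(s.depth < params.m for s in ordered):
        raise ValueError("primary stacks below depth m")
    loci: list[Locus] = []
    for stack in ordered:
        placed = False
        for locus in loci:
            if hamming(stack.sequence, locus.consensus, limit=params.M) <= params.M:
                locus.member_stacks.append(stack)
                locus.depth += stack.depth
                locus.consensus = _consensus(locus.member_stacks)
                placed = True
                break
        if not placed:
            loci.append(
                Locus(individual_id, len(loci) + 1, stack.sequence, stack.depth, [stack])
            )
    for stack in sorted(secondary, key=lambda s: (-s.depth, s.sequence)):
        for locus in loci:
            if hamming(stack.sequence, locus.consensus, limit=params.M) <= params.M:
                locus.member_stacks.append(stack)
                locus.depth += stack.depth
                locus.consensus = _consensus(locus.member_stacks)
                break
    return loci


def build_loci(
    reads: Sequence[tuple[str, str]], params: StackingParams, individual_id: str = ""
) -> list[Locus]:
    """Convenience: build_stacks + merge_stacks for one individual/member."""
    primary, secondary = build_stacks(reads, params)
    return merge_stacks(primary, params, secondary, individual_id)


def build_catalog(
    loci_by_individual: Sequence[tuple[str, list[Locus]]], params: StackingParams
) -> list[CatalogLocus]:
    """Merge all individuals' loci into one catalog, first-come consensus.

    Individuals are processed in the given (sample-sheet) order; within an
    individual, loci by ascending locus id. Each locus merges into the
    FIRST catalog entry within n mismatches of its consensus — the
    catalog consensus never changes after insertion — or appends a new
    entry. Fully deterministic.
    """
    params.validate()
    catalog: list[CatalogLocus] = []
    for individual_id, loci in loci_by_individual:
        for locus in sorted(loci, key=lambda l: l.locus_id):
            placed = False
            for entry in catalog:
                if len(entry.consensus) != len(locus.consensus):
                    continue
                if hamming(locus.consensus, entry.consensus, limit=params.n) <= params.n:
                    entry.contributors.append((individual_id, locus.locus_id))
                    placed = True
                    break
            if not placed:
                catalog.append(
                    CatalogLocus(len(catalog) + 1, locus.consensus,
                                 [(individual_id, locus.locus_id)])
                )
    return catalog


def match_to_catalog(
    loci: list[Locus], catalog: list[CatalogLocus], params: StackingParams
) -> list[MatchRow]:
    """Best catalog match (<= n mismatches) per individual locus.

    Ties on mismatch count go to the lowest catalog id; loci farther than
    n from every entry produce no row.
    """
    params.validate()
    rows = []
    for locus in sorted(loci, key=lambda l: l.locus_id):
        best: tuple[int, int] | None = None  # (mismatches, catalog_id)
        for entry in catalog:
            if len(entry.consensus) != len(locus.consensus):
                continue
            d = hamming(locus.consensus, entry.consensus, limit=params.n)
            if d <= params.n and (best is None or (d, entry.catalog_id) < best):
                best = (d, entry.catalog_id)
        if best is not None:
            rows.append(MatchRow(locus.individual_id, best[1], locus.locus_id, best[0]))
    return rows


# ---------------------------------------------------------------------------
# on-disk formats (the bridge to and from real Stacks runs)


def write_loci_tsv(loci_by_individual: Sequence[tuple[str, list[Locus]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tlocus_id\tconsensus\tdepth\n")
        for individual_id, loci in loci_by_individual:
            for locus in sorted(loci, key=lambda l: l.locus_id):
                fh.write(f"{individual_id}\t{locus.locus_id}\t{locus.consensus}\t{locus.depth}\n")


def write_catalog(catalog: list[CatalogLocus], fasta_path: str | Path, tsv_path: str | Path,
                  member: int | None = None) -> None:
    prefix = f"r{member}_" if member else "c"
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("catalog_id\tconsensus\tn_contributors\tcontributors\n")
        for entry in catalog:
            name = f"{prefix}{entry.catalog_id:05d}"
            fa.write(f">{name}\n{entry.consensus}\n")
            contribs = ",".join(f"{ind}:{loc}" for ind, loc in entry.contributors)
            tsv.write(f"{name}\t{entry.consensus}\t{len(entry.contributors)}\t{contribs}\n")


def write_matches_tsv(rows: Iterable[MatchRow], path: str | Path, member: int | None = None,
                      append: bool = False) -> None:
    prefix = f"r{member}_" if member else "c"
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("individual_id\tcatalog_id\tlocus_id\tmismatches\n")
        for r in rows:
            fh.write(f"{r.individual_id}\t{prefix}{r.catalog_id:05d}\t{r.locus_id}\t{r.mismatches}\n")


def read_matches_tsv(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Rows of (individual_id, catalog_id, locus_id, mismatches); catalog ids are strings."""
    rows = []
    for line in Path(path).read_text().splitlines()[1:]:
        f = line.split("\t")
        rows.append((f[0], f[1], int(f[2]), int(f[3])))
    return rows
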