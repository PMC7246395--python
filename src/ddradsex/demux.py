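"""Demultiplexing and read cleaning.

Raw barcoded PE reads are assigned to samples by the inline barcode on
read 1 (exact match by default — a single mismatch makes the barcode
ambiguous and the pair is dropped), then filtered: pairs with either
member's mean Phred below Q10 are removed, pairs missing the expected
restriction-site remnants (read 1: GWCC from AvaII, read 2: GG) are
removed, and surviving reads are truncated to a fixed 135-nt final
length. Filtering is always pair-level — both members survive or
neither — so read-pair linkage is intact for the later PE-pair
consolidation of candidate loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .samples import Sample, validate_samples
from .seqs import hamming, matches_iupac_prefix


@dataclass
class QCParams:
    """Read-cleaning thresholds.

    ``q_threshold`` is compared with the arithmetic mean Phred score of a
    read (strictly below fails). ``final_length`` is the fixed clean-read
    length after barcode removal and 3'-end truncation. The remnant
    patterns are IUPAC prefixes that clean reads must start with; the
    read-2 default GG follows the observed structure of published
    AvaII/MspI marker reads (one base inside the CGG fill-in remnant).
    """

    q_threshold: float = 10.0
    final_length: int = 135
    read1_remnant: str = "GWCC"
    read2_remnant: str = "GG"
    barcode_mismatches_allowed: int = 0
    adapter: str | None = None  # optional exact adapter-prefix scan

    def validate(self) -> None:
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be >= 0")
        if self.final_length <= 0:
            raise ValueError("final_length must be > 0")
        if self.barcode_mismatches_allowed < 0:
            raise ValueError("barcode_mismatches_allowed must be >= 0")


@dataclass
class RawPair:
    """A PE read pair after barcode assignment (barcode already stripped)."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class CleanReadSet:
    """One sample's clean reads; index i of member 1 pairs index i of member 2."""

    sample_id: str
    sex: str
    pair_ids: list[str] = field(default_factory=list)
    reads1: list[str] = field(default_factory=list)
    reads2: list[str] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pair_ids)


DISCARD_REASONS = ("low_quality", "missing_site", "adapter", "too_short")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (pair_id, seq1, qual1, seq2, qual2) from two FASTQ files.

    The trailing /1 and /2 member suffixes are stripped from the ids;
    the files must be in the same order.
    """
    with _maybe_gzip(path1) as f1, _maybe_gzip(path2) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for (id1, seq1, q1), (id2, seq2, q2) in zip(it1, it2, strict=True):
            pid1 = id1.split()[0].removesuffix("/1")
            pid2 = id2.split()[0].removesuffix("/2")
            if pid1 != pid2:
                raise ValueError(f"unpaired FASTQ records: {id1!r} vs {id2!r}")
            yield pid1, seq1, q1, seq2, q2


def _maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return gzip.open(path, "rt")
    return open(path)


def demultiplex(
    pairs: Iterable[tuple[str, str, str, str, str]],
    samples: list[Sample],
    params: QCParams,
) -> tuple[dict[str, list[RawPair]], dict[str, int]]:
    """Assign pairs to samples by the read-1 barcode prefix.

    A pair is assigned when exactly one barcode lies within
    ``barcode_mismatches_allowed`` of the read-1 prefix (default 0 =
    exact); the barcode is stripped from read 1. Returns per-sample raw
    pairs plus counters (input / assigned / unassigned).
    """
    params.validate()
    validate_samples(samples)
    bc_len = len(samples[0].barcode)
    exact = {s.barcode: s.sample_id for s in samples}
    by_sample: dict[str, list[RawPair]] = {s.sample_id: [] for s in samples}
    counters = {"input": 0, "assigned": 0, "unassigned": 0}
    k = params.barcode_mismatches_allowed
    for pair_id, seq1, qual1, seq2, qual2 in pairs:
        counters["input"] += 1
        prefix = seq1[:bc_len]
        sample_id = exact.get(prefix)
        if sample_id is None and k > 0 and len(prefix) == bc_len:
            hits = [sid for bc, sid in exact.items() if hamming(prefix, bc, limit=k) <= k]
            if len(hits) == 1:
                sample_id = hits[0]
        if sample_id is None or len(seq1) <= bc_len:
            counters["unassigned"] += 1
            continue
        counters["assigned"] += 1
        by_sample[sample_id].append(
            RawPair(pair_id, seq1[bc_len:], qual1[bc_len:], seq2, qual2)
        )
    return by_sample, counters


def mean_phred(qual: str) -> float:
    """Arithmetic mean Phred score of a Phred+33 quality string."""
    if not qual:
        raise ValueError("empty quality string")
    return sum(ord(c) - 33 for c in qual) / len(qual)


def quality_filter(pairs: list[RawPair], params: QCParams) -> tuple[list[RawPair], int]:
    """Drop a pair when EITHER member's mean Phred is strictly below Q10."""
    kept, dropped = [], 0
    for p in pairs:
        if not p.qual1 or not p.qual2 or len(p.qual1) != len(p.seq1) or len(p.qual2) != len(p.seq2):
            raise ValueError(f"pair {p.read_id}: missing or malformed quality line")
        if mean_phred(p.qual1) < params.q_threshold or mean_phred(p.qual2) < params.q_threshold:
            dropped += 1
        else:
            kept.append(p)
    return kept, dropped


def restriction_check(pairs: list[RawPair], params: QCParams) -> tuple[list[RawPair], int]:
    """Keep pairs whose reads begin with the expected enzyme remnants."""
    kept, dropped = [], 0
    for p in pairs:
        if matches_iupac_prefix(p.seq1, params.read1_remnant) and matches_iupac_prefix(
            p.seq2, params.read2_remnant
        ):
            kept.append(p)
        else:
            dropped += 1
    return kept, dropped


def adapter_filter(pairs: list[RawPair], params: QCParams) -> tuple[list[RawPair], int]:
    """Optional exact adapter-prefix scan (no-op when no adapter is set)."""
    if not params.adapter:
        return list(pairs), 0
    kept, dropped = [], 0
    for p in pairs:
        if params.adapter in p.seq1 or params.adapter in p.seq2:
            dropped += 1
        else:
            kept.append(p)
    return kept, dropped


def truncate_reads(
    pairs: list[RawPair], sample: Sample, params: QCParams
) -> CleanReadSet:
    """Cut every read to exactly ``final_length`` nt from its 5' end.

    Pairs with either member shorter than ``final_length`` are dropped
    and counted. Idempotent on already-truncated input.
    """
    out = CleanReadSet(sample.sample_id, sample.sex)
    too_short = 0
    n = params.final_length
    for p in pairs:
        if len(p.seq1) < n or len(p.seq2) < n:
            too_short += 1
            continue
        out.pair_ids.append(p.read_id)
        out.reads1.append(p.seq1[:n])
        out.reads2.append(p.seq2[:n])
    out.counters["too_short"] = too_short
    return out


def clean_sample(pairs: list[RawPair], sample: Sample, params: QCParams) -> CleanReadSet:
    """Run quality filter -> adapter scan -> restriction check -> truncation."""
    params.validate()
    kept, low_q = quality_filter(pairs, params)
    kept, adapters = adapter_filter(kept, params)
    kept, no_site = restriction_check(kept, params)
    clean = truncate_reads(kept, sample, params)
    clean.counters.update(
        {"input": len(pairs), "low_quality": low_q, "adapter": adapters,
         "missing_site": no_site, "kept": len(clean)}
    )
    return clean


def run_demux(
    fastq1: str | Path,
    fastq2: str | Path,
    samples: list[Sample],
    params: QCParams,
) -> tuple[dict[str, CleanReadSet], dict[str, int]]:
    """Full demultiplex-and-clean pass over one FASTQ pair.

    Returns per-sample clean read sets and the global counters; per-stage
    counts always conserve: assigned + unassigned = input, and per sample
    low_quality + adapter + missing_site + too_short + kept = input.
    """
    by_sample, counters = demultiplex(read_fastq_pairs(fastq1, fastq2), samples, params)
    clean_sets = {}
    for sample in samples:
        clean = clean_sample(by_sample[sample.sample_id], sample, params)
        clean_sets[sample.sample_id] = clean
    return clean_sets, counters


def write_clean_reads(clean: CleanReadSet, path1: str | Path, path2: str | Path) -> None:
    """Clean reads as FASTA, ids carrying the pair id for PE linkage."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pid, r1, r2 in zip(clean.pair_ids, clean.reads1, clean.reads2):
            f1.write(f">{pid}/1\n{r1}\n")
            f2.write(f">{pid}/2\n{r2}\n")


def read_clean_reads(path1: str | Path, path2: str | Path, sample: Sample) -> CleanReadSet:
    from Bio import SeqIO

    out = CleanReadSet(sample.sample_id, sample.sex)
    recs1 = list(SeqIO.parse(str(path1), "fasta"))
    recs2 = list(SeqIO.parse(str(path2), "fasta"))
    for r1, r2 in zip(recs1, recs2, strict=True):
        out.pair_ids.append(r1.id.removesuffix("/1"))
        out.reads1.append(str(r1.seq))
        out.reads2.append(str(r2.seq))
    return out


def write_discard_report(
    clean_sets: dict[str, CleanReadSet], global_counters: dict[str, int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tinput\tlow_quality\tadapter\tmissing_site\ttoo_short\tkept\n")
        fh.write(
            "__unassigned__\t{input}\t0\t0\t0\t0\t0\n".format(
                input=global_counters.get("unassigned", 0)
            )
        )
        for sid, clean in clean_sets.items():
            c = clean.counters
            fh.write(
                f"{sid}\t{c['input']}\t{c['low_quality']}\t{c['adapter']}\t"
                f"{c['missing_site']}\t{c['too_short']}\t{c['kept']}\n"
            )
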