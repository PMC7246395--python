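"""Synthetic ddRAD data with planted, hemizygous male-specific fragments.

The simulator emulates a double-digest RAD library the way it is built at
the bench: genomic DNA is digested with AvaII (G^GWCC) and MspI (C^CGG),
fragments of 500-600 bp flanked by one site of EACH enzyme are retained
(mixed flanks are what the two different adapters ligate to), and each
retained fragment is sequenced as a 150-nt paired-end read pair, read 1
from the AvaII end (carrying the inline sample barcode) and read 2 from
the MspI end.

Males carry, in addition to the shared background genome, a set of extra
sequences present on only one chromosome copy (hemizygous) — the situation
of a Y-linked region in an XX/XY dioecious species. Every planted
male-specific fragment is recorded in a truth table with its expected
read sequences, so downstream marker discovery can be verified exactly.

Sequencing chemistry note: after AvaII cuts, the fragment's top strand
begins with the half-site GWCC, which is what read 1 shows. At the MspI
end the physical remnant after overhang fill-in would be CGG; the
published marker read-2 sequences instead all begin GG, one base inside
that remnant, and the simulator reproduces the observed read structure:
read 2 is the reverse complement taken from one base past the top-strand
MspI cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .samples import Sample, validate_samples
from .seqs import is_valid_sequence, iupac_regex, revcomp

TERMINUS = "terminus"


@dataclass(frozen=True)
class Enzyme:
    """A type II restriction enzyme with a palindromic recognition site.

    ``cut_offset`` is the top-strand cut position, counted from the 5' end
    of the recognition site.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut_offset outside recognition site")
        iupac_regex(self.recognition)  # raises on a bad code


AVAII = Enzyme("AvaII", "GGWCC", 1)
MSPI = Enzyme("MspI", "CCGG", 1)
DEFAULT_ENZYMES = (AVAII, MSPI)


@dataclass(frozen=True)
class Fragment:
    """One digestion product; coordinates are 0-based half-open on the source."""

    source_name: str
    start: int
    end: int
    sequence: str
    left_enzyme: str
    right_enzyme: str

    @property
    def fragment_id(self) -> str:
        return f"{self.source_name}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SimulationParams:
    """Study-design knobs for the synthetic library.

    Defaults mirror the emulated study design: 500-600 bp size selection,
    150-nt paired-end reads, 5 hemizygous male-specific fragments of
    550 bp on a ~200 kb shared background, 30x expected depth per fragment
    per individual and a 0.1% per-base substitution error rate.
    """

    background_length: int = 200_000
    n_chromosomes: int = 4
    n_male_specific_fragments: int = 5
    male_specific_fragment_length: int = 550
    size_min: int = 500
    size_max: int = 600
    read_length: int = 150
    mean_depth: float = 30.0
    error_rate: float = 0.001
    barcode_length: int = 5
    low_quality_fraction: float = 0.0  # fraction of pairs given Q2 read-2 qualities
    quality_char: str = "F"  # Phred+33 'F' = Q37
    seed: int = 0

    def validate(self) -> None:
        if self.size_min >= self.size_max:
            raise ValueError("size_min must be < size_max")
        if self.read_length > self.size_min:
            raise ValueError("read_length must be <= size_min")
        if not (self.size_min <= self.male_specific_fragment_length <= self.size_max):
            raise ValueError("male_specific_fragment_length must fall inside the size window")
        for name in ("background_length", "n_chromosomes", "n_male_specific_fragments",
                     "read_length", "barcode_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_depth < 0 or not 0 <= self.error_rate < 1:
            raise ValueError("mean_depth must be >= 0 and error_rate in [0, 1)")


@dataclass(frozen=True)
class TruthFragment:
    """A planted male-specific fragment and its expected read sequences.

    ``read1_seq``/``read2_seq`` are the error-free reads at full read
    length, before barcode prepending; compare prefixes after truncation.
    """

    fragment_id: str
    source_name: str
    start: int
    end: int
    read1_seq: str
    read2_seq: str


@dataclass
class SimulatedGenomePair:
    """Female genome (shared) plus hemizygous male-extra sequences."""

    shared_sequences: dict[str, str]
    male_extra_sequences: dict[str, str]
    truth_table: list[TruthFragment] = field(default_factory=list)

    @property
    def male_sequences(self) -> dict[str, str]:
        return {**self.shared_sequences, **self.male_extra_sequences}


@dataclass(frozen=True)
class ReadPairRecord:
    """One simulated PE read pair with provenance for truth tracking."""

    read_id: str
    sample_id: str
    fragment_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


# ---------------------------------------------------------------------------
# digestion and size selection


def digest(sequence: str, enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES) -> list[Fragment]:
    """Cut *sequence* at every recognition site of every enzyme.

    Sites are scanned on the top strand only; both default enzymes have
    palindromic sites (GGWCC and CCGG are their own reverse complements),
    so no cut is missed. Cut positions are ``site_start + cut_offset``;
    the returned fragments partition the sequence in order, and each
    records the enzyme that produced each boundary (sequence ends are
    labelled "terminus").
    """
    return digest_named(sequence, "seq", enzymes)


def digest_named(
    sequence: str, source_name: str, enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES
) -> list[Fragment]:
    if not is_valid_sequence(sequence):
        raise ValueError("sequence must be uppercase A/C/G/T/N")
    if not sequence:
        return []
    cuts: list[tuple[int, str]] = []
    for enz in enzymes:
        pat = iupac_regex(enz.recognition)
        pos = 0
        while True:
            m = pat.search(sequence, pos)
            if m is None:
                break
            cut = m.start() + enz.cut_offset
            if 0 < cut < len(sequence):
                cuts.append((cut, enz.name))
            pos = m.start() + 1  # step one base so overlapping sites are seen
    cuts.sort()
    fragments: list[Fragment] = []
    prev, prev_enz = 0, TERMINUS
    for cut, enz_name in cuts:
        if cut == prev:  # two enzymes cutting the same position; keep the first
            continue
        fragments.append(
            Fragment(source_name, prev, cut, sequence[prev:cut], prev_enz, enz_name)
        )
        prev, prev_enz = cut, enz_name
    fragments.append(
        Fragment(source_name, prev, len(sequence), sequence[prev:], prev_enz, TERMINUS)
    )
    return fragments


def select_fragments(fragments: list[Fragment], params: SimulationParams) -> list[Fragment]:
    """Size selection plus the ddRAD mixed-flank requirement.

    A fragment is sequenceable only when its two ends carry the two
    DIFFERENT enzymes' half-sites (each end ligates a different adapter)
    and its length lies within ``size_min..size_max``. Orientation is
    normalised downstream: the AvaII end is always the read-1 end (see
    :func:`pe_template`).
    """
    kept = []
    for frag in fragments:
        if TERMINUS in (frag.left_enzyme, frag.right_enzyme):
            continue
        if frag.left_enzyme == frag.right_enzyme:
            continue
        if params.size_min <= len(frag) <= params.size_max:
            kept.append(frag)
    return kept


def pe_template(source_seq: str, frag: Fragment) -> str:
    """The sequenced insert, oriented with the AvaII end first.

    Read 1 is ``template[:read_length]`` (after the barcode is prepended)
    and read 2 is ``revcomp(template)[:read_length]``. The template begins
    at the AvaII top-strand cut (so read 1 starts GWCC) and ends one base
    past the MspI top-strand cut (so read 2 starts GG; see module
    docstring for why this is one base inside the physical CGG remnant).
    """
    if frag.left_enzyme == AVAII.name and frag.right_enzyme == MSPI.name:
        return source_seq[frag.start : frag.end + 1]
    if frag.left_enzyme == MSPI.name and frag.right_enzyme == AVAII.name:
        # AvaII on the right: its bottom-strand cut sits 3 bases past the
        # top-strand cut; reverse-complement to put the AvaII end first.
        return revcomp(source_seq[frag.start + 1 : frag.end + 3])
    raise ValueError(f"fragment {frag.fragment_id} is not AvaII/MspI mixed-flanked")


# ---------------------------------------------------------------------------
# genome construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_genome_pair(params: SimulationParams) -> SimulatedGenomePair:
    """Build a shared background plus planted hemizygous male fragments.

    Each male-extra sequence embeds exactly one AvaII/MspI fragment of
    ``male_specific_fragment_length`` bp (rejection-sampled so the digest
    of the construct yields that fragment intact); the fragment and its
    expected reads go into the truth table.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shared = {}
    if params.n_chromosomes > 0:
        chrom_len = params.background_length // params.n_chromosomes
        for i in range(params.n_chromosomes):
            shared[f"chr{i + 1}"] = _random_seq(rng, chrom_len)

    extra: dict[str, str] = {}
    truth: list[TruthFragment] = []
    pad = 150
    for i in range(params.n_male_specific_fragments):
        name = f"male_extra_{i + 1}"
        frag_len = params.male_specific_fragment_length
        while True:
            core = "GACC" + _random_seq(rng, frag_len - 5) + "C"
            seq = _random_seq(rng, pad) + "G" + core + "CGG" + _random_seq(rng, pad)
            start, end = pad + 1, pad + 1 + frag_len
            selected = select_fragments(digest_named(seq, name), params)
            hit = [f for f in selected if (f.start, f.end) == (start, end)]
            if len(hit) == 1 and len(selected) == 1:
                frag = hit[0]
                break
        template = pe_template(seq, frag)
        extra[name] = seq
        truth.append(
            TruthFragment(
                fragment_id=f"msf{i + 1}",
                source_name=name,
                start=start,
                end=end,
                read1_seq=template[: params.read_length],
                read2_seq=revcomp(template)[: params.read_length],
            )
        )
    return SimulatedGenomePair(shared, extra, truth)


# ---------------------------------------------------------------------------
# library generation


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    k = rng.binomial(len(seq), error_rate)
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def generate_library(
    genomes: SimulatedGenomePair,
    samples: list[Sample],
    params: SimulationParams,
) -> Iterator[ReadPairRecord]:
    """Simulate the sequenced library, one read pair at a time.

    For every individual and every selected fragment of its genome
    (males: shared + male-extra; females: shared only) a Poisson
    (``mean_depth``) number of pairs is emitted. Read ids encode sample,
    fragment and pair index so provenance survives into the FASTQ.
    Identical params (incl. seed) give a byte-identical stream.
    """
    params.validate()
    validate_samples(samples)
    rng = np.random.default_rng(params.seed)

    def fragments_of(sequences: dict[str, str]) -> list[tuple[str, str]]:
        out = []
        for name, seq in sequences.items():
            for frag in select_fragments(digest_named(seq, name), params):
                out.append((frag.fragment_id, pe_template(seq, frag)))
        return out

    shared_frags = fragments_of(genomes.shared_sequences)
    male_frags = shared_frags + fragments_of(genomes.male_extra_sequences)

    q_high = params.quality_char
    q_low = "#"  # Phred+33 '#' = Q2
    for sample in samples:
        frags = male_frags if sample.sex == "M" else shared_frags
        bc_len = len(sample.barcode)
        for fragment_id, template in frags:
            n_pairs = int(rng.poisson(params.mean_depth))
            for k in range(n_pairs):
                seq1 = sample.barcode + template[: params.read_length - bc_len]
                seq2 = revcomp(template)[: params.read_length]
                seq1 = _mutate(seq1, rng, params.error_rate)
                seq2 = _mutate(seq2, rng, params.error_rate)
                qual2 = q_high * len(seq2)
                if params.low_quality_fraction > 0 and rng.random() < params.low_quality_fraction:
                    qual2 = q_low * len(seq2)
                yield ReadPairRecord(
                    read_id=f"{sample.sample_id}.{fragment_id}.{k}",
                    sample_id=sample.sample_id,
                    fragment_id=fragment_id,
                    seq1=seq1,
                    qual1=q_high * len(seq1),
                    seq2=seq2,
                    qual2=qual2,
                )


# ---------------------------------------------------------------------------
# scenario and on-disk formats


def eucommia_scenario(seed: int = 0) -> tuple[SimulationParams, list[Sample]]:
    """The packaged study-design scenario: 20 males + 20 females.

    ~200 kb shared background, five hemizygous 550-bp AvaII/MspI
    male-specific fragments, 30x depth, 0.1% error, 150-nt PE reads with
    5-nt inline barcodes.
    """
    params = SimulationParams(seed=seed)
    samples = []
    barcodes = _default_barcodes(40, 5)
    for i in range(20):
        samples.append(Sample(f"M{i + 1:02d}", "M", barcodes[i]))
    for i in range(20):
        samples.append(Sample(f"F{i + 1:02d}", "F", barcodes[20 + i]))
    return params, samples


def _default_barcodes(n: int, length: int) -> list[str]:
    """Deterministic, evenly spaced barcodes over the 4^length code space."""
    from itertools import product

    space = ["".join(p) for p in product("ACGT", repeat=length)]
    step = max(1, len(space) // n)
    codes = [space[i * step] for i in range(n)]
    if len(set(codes)) != n:
        raise ValueError(f"cannot draw {n} unique barcodes of length {length}")
    return codes


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_table(truth: list[TruthFragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tsource\tstart\tend\tread1_seq\tread2_seq\n")
        for t in truth:
            fh.write(
                f"{t.fragment_id}\t{t.source_name}\t{t.start}\t{t.end}\t"
                f"{t.read1_seq}\t{t.read2_seq}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthFragment]:
    rows = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        f = line.split("\t")
        rows.append(TruthFragment(f[0], f[1], int(f[2]), int(f[3]), f[4], f[5]))
    return rows


def write_fastq_pair(
    records: Iterable[ReadPairRecord], path1: str | Path, path2: str | Path
) -> int:
    """Write the two 4-line FASTQ files; returns the pair count."""
    n = 0
    with _maybe_gzip(path1) as f1, _maybe_gzip(path2) as f2:
        for rec in records:
            f1.write(f"@{rec.read_id}/1\n{rec.seq1}\n+\n{rec.qual1}\n")
            f2.write(f"@{rec.read_id}/2\n{rec.seq2}\n+\n{rec.qual2}\n")
            n += 1
    return n


def _maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return gzip.open(path, "wt")
    return open(path, "w")
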