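# Methods

## The marker-discovery model

The pipeline targets presence/absence sex markers: genomic fragments
carried hemizygously by one sex (the situation of a young, non-recombining
sex-linked region in a dioecious species with genetic sex determination).
In a ddRAD survey such a fragment appears as a catalog locus present in
(nearly) every individual of one sex and in none of the other. The screen
is deliberately non-statistical — with cohorts of ~20 per sex, a locus
present in ≥ N − 1 of one sex and 0 of the other is already far beyond
what sampling noise produces, and the rule mirrors how such screens are
run in practice. The absence side is a hard zero by design: a single
opposite-sex observation falsifies hemizygosity, whereas one missing
target-sex individual is expected from depth dropout, which is why only
the presence side carries a tolerance (default 1, i.e. ≥ N − 1;
configurable for other cohort sizes, and validated against the cohort
size before a run starts).

Two refinements follow the screen. First, read members 1 and 2 are
clustered as independent locus universes, so one sequenced fragment can
surface as two candidate loci; candidates sharing at least one
originating read-pair id are consolidated into a single genomic marker
(the ~500-bp insert guarantees tight linkage). Single-member candidates
are accepted and flagged `pe_consolidated=False` rather than discarded:
the screen operates on member loci, and requiring both members to pass
independently would silently discard markers whose second member just
missed the presence threshold. Second, a grep-equivalent exclusion: a
marker is removed if any opposite-sex clean read is an exact, full-length,
same-orientation match of a member sequence. Since clean reads and locus
consensi share the 135-nt length, this is string equality (implemented as
a set lookup; a brute-force all-pairs scan serves as the test oracle).
Reverse-complement matching is off by default — a grep over read files
would not match reverse complements — and available behind a flag.

## Read cleaning

"Low quality" is interpreted as the arithmetic mean Phred score of a
read, compared strictly (< Q10 fails, exactly Q10 passes); the rule is
configurable. Filtering is pair-level — both members survive or neither —
because downstream PE consolidation needs intact pair linkage. The
restriction-site check is an IUPAC-aware prefix match: read 1 must begin
`GWCC` (the AvaII half-site left by `G^GWCC`), read 2 `GG`. The read-2
default is empirical rather than chemical: MspI `C^CGG` plus overhang
fill-in predicts a `CGG` prefix, but the published marker read-2
sequences all begin `GG`, one base inside that remnant. The package
follows the observed read structure — the simulator emits read 2 starting
one base past the top-strand MspI cut, and the cleaner expects `GG` — and
records the one-base discrepancy here rather than resolving it. Adapter
handling is reduced to an optional exact-substring scan; the simulator
emits no chimeras, so full adapter alignment adds nothing testable.

## Stacking and the catalog

A simplified, fully deterministic re-implementation of the
ustacks/cstacks/sstacks stages at fixed read length, using Hamming
distance throughout (no indels — reads are fixed-length and the enzymes
anchor them to fixed genomic positions):

* **Stacks**: exact-identical reads grouped; groups of depth ≥ m (default
  10) seed stacks; smaller groups are "secondary" reads that may join a
  locus (contributing depth and consensus votes) but never found one.
* **Loci**: stacks processed depth-descending, ties broken
  lexicographically by sequence; each joins the first locus whose current
  consensus is within M mismatches (default 3), else founds a new locus.
  The consensus is the per-position depth-weighted majority, ties to the
  lexicographically smallest base, recomputed after every join. The
  ordering rule — never input order — makes locus consensus sets
  invariant under read shuffling. A member that joined within M can in
  principle end farther than M from the final consensus after later joins
  shift it; the merge criterion is defined at join time.
* **Catalog**: individuals in sample-sheet order, loci by ascending id;
  each locus merges into the first catalog entry within n mismatches
  (default 3) or appends a new entry. The catalog consensus is frozen at
  first insertion — no iterative re-consensus — trading a little accuracy
  for order-stability and determinism.
* **Matching**: each individual locus reports its minimum-mismatch
  catalog entry if ≤ n away, ties to the lowest catalog id. The same n is
  reused for matching (the matching allowance is not separately
  specified in the emulated protocol; this assumption is explicit).

Omitted Stacks machinery: deleveraging, removal of highly repetitive
stacks, gapped alignment, SNP/genotype calling. At the complexity the
simulator produces (and for a presence/absence screen generally) these
change nothing; the matches-TSV bridge lets users substitute a real
Stacks run when they do matter.

## The synthetic data generator

The generator emulates an AvaII+MspI ddRAD library end to end:
double digestion (top-strand scan only — both recognition sites, GGWCC
and CCGG, are their own reverse complements, so no site is missed, which
the tests assert), retention of 500–600 bp fragments flanked by the two
*different* enzymes (standard ddRAD adapter chemistry; the published
marker read-1 sequences all begin with the AvaII half-site, consistent
with the AvaII end defining read 1), and 150-nt PE reads with a 5-nt
inline barcode on read 1 only. Barcode length and placement are simulator
configuration, not claims about any real library. Depth is Poisson per
fragment per individual; substitution errors are i.i.d. per base;
qualities are constant Q37 with a `low_quality_fraction` knob that gives
whole read-2s Q2 to exercise the Q10 filter.

Defaults (the packaged `eucommia` scenario): 20 males + 20 females,
~200 kb shared background in 4 chromosomes, 5 planted hemizygous
male-specific fragments of 550 bp, mean depth 30×, error rate 0.001.
The background length is chosen so the random background itself yields
on the order of a dozen shared 500–600 bp AvaII/MspI fragments — enough
non-sex-specific loci to make the screen non-trivial — while a full run
completes in seconds; depth 30× and error 10⁻³ are typical of a ddRAD
experiment and leave error-free stack depths (~26× expected) comfortably
above m = 10. Planted fragments are rejection-sampled so the digest of
each male-extra sequence yields exactly one selected fragment at the
intended coordinates, with the expected read-1/read-2 sequences recorded
in a truth table at full read length (downstream comparisons slice to the
clean-read length).

What the generator does **not** emulate: indel errors, PCR duplicates,
allelic dropout, restriction-site polymorphism, background polymorphism
between individuals, repetitive DNA, or chimeric/adapter reads. Passing
the end-to-end recovery test therefore shows the pipeline's logic is
correct under clean hemizygosity — it does not show robustness to the
population-genetic and technical noise of real libraries, where the
screen's tolerance, the hard-zero absence rule and the exclusion scan do
the heavy lifting.

## Numerical and degenerate-input choices

All coordinates are 0-based half-open; all tie-breaks are lexicographic;
all processing orders are fixed (sample-sheet order, depth-descending,
ascending ids), so every stage is deterministic given the seed — the run
manifest (parameter echo, per-stage counts, SHA-256 per artifact,
no timestamps) is byte-identical across reruns. Degenerate inputs:
empty sequence digests to an empty list; a cut falling on a sequence end
produces no empty fragment; an empty matches table gives an empty
presence matrix and an empty candidate set; an empty marker set still
yields a valid, headed report. Sequences are validated as uppercase
A/C/G/T (N allowed; N never matches a recognition site); amplicon sets of
unequal length are rejected with an instruction to pre-align externally —
the conserved amplicons this module targets need no indel alignment, and
silent padding would fabricate columns.

## Problem sizes

The test suite and the acceptance script run the full 40-individual
scenario (~18,500 read pairs) end to end, oracle checks on 1,000 random
5-kb digests, catalogs of up to 50 distinct sequences against a quadratic
brute force, and the exclusion scan against 10⁴ reads — sizes at which
the independent oracles are themselves trivially verifiable.

## Known limitations

* Hamming-only clustering mis-handles indel polymorphism near a locus.
* First-come catalog consensus can chain-split borderline locus clusters
  that iterative re-consensus would merge.
* The exclusion scan is same-orientation equality, not alignment; a
  single sequencing error in an opposite-sex read defeats it (by design,
  matching the grep it reproduces).
* No statistical association test is provided; for cohorts much larger
  than ~20 per sex a depth-aware probabilistic screen would be
  preferable.
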