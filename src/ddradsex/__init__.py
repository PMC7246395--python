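"""ddradsex: sex-specific marker discovery from ddRAD-seq data.

A tested re-implementation of the presence/absence ddRAD screen for
sex-linked loci in dioecious species — demultiplexing and read cleaning,
deterministic read stacking into a cross-individual locus catalog, the
>=N-1 / absent-in-other-sex screen with PE-pair consolidation and
cross-sex exact-match exclusion — plus an in-silico double-digest
(AvaII+MspI) library simulator with planted hemizygous male-specific
fragments that gives every stage a ground truth.
"""

from .demux import CleanReadSet, QCParams
from .radstack import CatalogLocus, Locus, MatchRow, Stack, StackingParams
from .report import AmpliconSet, ConsensusResult, build_consensus, locate_marker_reads
from .samples import Sample, read_sample_sheet
from .sexscreen import (
    CandidateMarker,
    PresenceMatrix,
    ScreenParams,
    build_presence_matrix,
    consolidate_pe_pairs,
    exclude_cross_sex_matches,
    screen_sex_specific,
)
from .simdata import (
    AVAII,
    MSPI,
    Enzyme,
    Fragment,
    SimulatedGenomePair,
    SimulationParams,
    digest,
    eucommia_scenario,
    generate_library,
    make_genome_pair,
    pe_template,
    select_fragments,
)
from .pipeline import RunConfig, RunManifest, run_pipeline, validate_config

__version__ = "0.1.0"

MSL_FIXTURE = "data/msl_loci.fasta"


def load_msl_fixture():
    """The five published male-specific locus PE read pairs, as Bio.SeqRecords."""
    from importlib.resources import files

    from Bio import SeqIO

    with (files(__package__) / MSL_FIXTURE).open() as fh:
        return list(SeqIO.parse(fh, "fasta"))
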