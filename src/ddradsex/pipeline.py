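"""One-command orchestration: simulate -> demux -> stack -> screen -> report.

Every stage persists its artifacts under the output directory in the
plain-text bridge formats (FASTQ/FASTA/TSV), so any downstream stage can
be re-run alone from disk — in particular the screen stage can consume a
matches TSV produced by a real Stacks run instead of the built-in
clustering. A run manifest records parameters, per-stage record counts
and a SHA-256 checksum of every emitted file; identical config and seed
give a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import demux as dmx
from . import radstack as rs
from . import sexscreen as ss
from .report import write_marker_report
from .samples import Sample, read_sample_sheet, write_sample_sheet
from .simdata import (
    SimulationParams,
    eucommia_scenario,
    generate_library,
    make_genome_pair,
    write_fasta,
    write_fastq_pair,
    write_truth_table,
)

log = logging.getLogger("ddradsex")

SCENARIOS = ("eucommia",)


@dataclass
class RunConfig:
    out_dir: str = "ddradsex_run"
    seed: int = 0
    scenario: str | None = None
    fastq1: str | None = None
    fastq2: str | None = None
    sample_sheet: str | None = None
    log_level: str = "INFO"
    sim: SimulationParams = field(default_factory=SimulationParams)
    qc: dmx.QCParams = field(default_factory=dmx.QCParams)
    stacking: rs.StackingParams = field(default_factory=rs.StackingParams)
    screen: ss.ScreenParams = field(default_factory=ss.ScreenParams)

    def validate(self) -> None:
        if self.scenario is None and not (self.fastq1 and self.fastq2 and self.sample_sheet):
            raise ValueError(
                "config needs either 'scenario' or all of fastq1/fastq2/sample_sheet"
            )
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; available: {SCENARIOS}")
        self.sim.validate()
        self.qc.validate()
        self.stacking.validate()
        if self.qc.final_length > self.sim.read_length - self.sim.barcode_length and self.scenario:
            raise ValueError("final_length exceeds read_length - barcode_length")


_SECTIONS = {
    "simulation": ("sim", SimulationParams),
    "qc": ("qc", dmx.QCParams),
    "stacking": ("stacking", rs.StackingParams),
    "screen": ("screen", ss.ScreenParams),
}
_TOP_KEYS = {"out_dir", "seed", "scenario", "fastq1", "fastq2", "sample_sheet", "log_level"}


def validate_config(raw: str | dict) -> RunConfig:
    """Parse a YAML config (text or pre-parsed mapping) into a RunConfig.

    Unknown keys raise a warning; invariant violations raise ValueError
    naming the offending field.
    """
    data = yaml.safe_load(raw) if isinstance(raw, str) else dict(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    config = RunConfig()
    for key, value in data.items():
        if key in _TOP_KEYS:
            setattr(config, key, value)
        elif key in _SECTIONS:
            attr, cls = _SECTIONS[key]
            known = {f.name for f in fields(cls)}
            section = value or {}
            for k, v in section.items():
                if k not in known:
                    warnings.warn(f"unknown config key {key}.{k!r} ignored")
                else:
                    setattr(getattr(config, attr), k, v)
        else:
            warnings.warn(f"unknown config key {key!r} ignored")
    if "screen" in data and (data["screen"] or {}).get("tolerance") is not None:
        if config.screen.tolerance < 0:
            raise ValueError("screen.tolerance must be >= 0")
    config.sim.seed = config.seed
    try:
        config.validate()
    except ValueError as err:
        raise ValueError(f"invalid config: {err}") from err
    return config


@dataclass
class RunManifest:
    seed: int
    parameters: dict
    counts: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(manifest: RunManifest, out_dir: Path, *paths: Path) -> None:
    for p in paths:
        manifest.files[str(p.relative_to(out_dir))] = _sha256(p)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and return the run manifest.

    Fails fast: configuration (including the tolerance-vs-cohort-size
    invariant) is validated before any stage runs; a stage error aborts
    the run with the stage named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # resolve samples up front so screen parameters can be checked pre-run
    if config.scenario:
        config.sim.seed = config.seed
        _, samples = eucommia_scenario(config.seed)
    else:
        samples = read_sample_sheet(config.sample_sheet)
    n_by_sex = {sex: sum(s.sex == sex for s in samples) for sex in ("M", "F")}
    config.screen.validate(n_by_sex)

    parameters = {
        "scenario": config.scenario,
        "simulation": asdict(config.sim) if config.scenario else None,
        "qc": asdict(config.qc),
        "stacking": asdict(config.stacking),
        "screen": {"tolerance": config.screen.tolerance,
                   "screen_sexes": list(config.screen.screen_sexes)},
    }
    manifest = RunManifest(seed=config.seed, parameters=parameters)
    manifest.counts["n_samples"] = len(samples)
    manifest.counts["n_by_sex"] = n_by_sex

    # --- stage 1: simulate -------------------------------------------------
    try:
        if config.scenario:
            sim_dir = out / "simulate"
            sim_dir.mkdir(exist_ok=True)
            genomes = make_genome_pair(config.sim)
            write_fasta(genomes.shared_sequences, sim_dir / "female_genome.fasta")
            write_fasta(genomes.male_sequences, sim_dir / "male_genome.fasta")
            write_truth_table(genomes.truth_table, sim_dir / "truth_table.tsv")
            write_sample_sheet(samples, sim_dir / "sample_sheet.tsv")
            fastq1, fastq2 = sim_dir / "reads_R1.fastq", sim_dir / "reads_R2.fastq"
            n_pairs = write_fastq_pair(
                generate_library(genomes, samples, config.sim), fastq1, fastq2
            )
            manifest.counts["simulated_read_pairs"] = n_pairs
            manifest.counts["planted_male_fragments"] = len(genomes.truth_table)
            log.info("simulate: %d read pairs, %d planted fragments",
                     n_pairs, len(genomes.truth_table))
            _register(manifest, out, *sorted(sim_dir.iterdir()))
        else:
            fastq1, fastq2 = Path(config.fastq1), Path(config.fastq2)
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    # --- stage 2: demux ----------------------------------------------------
    try:
        demux_dir = out / "demux"
        demux_dir.mkdir(exist_ok=True)
        clean_sets, counters = dmx.run_demux(fastq1, fastq2, samples, config.qc)
        for sample in samples:
            clean = clean_sets[sample.sample_id]
            dmx.write_clean_reads(
                clean,
                demux_dir / f"{sample.sample_id}.clean.R1.fasta",
                demux_dir / f"{sample.sample_id}.clean.R2.fasta",
            )
            log.debug("demux %s: %s", sample.sample_id, clean.counters)
        dmx.write_discard_report(clean_sets, counters, demux_dir / "discard_report.tsv")
        manifest.counts["demux"] = dict(counters)
        manifest.counts["clean_pairs"] = {s: len(c) for s, c in clean_sets.items()}
        log.info("demux: %d pairs in, %d assigned", counters["input"], counters["assigned"])
        _register(manifest, out, *sorted(demux_dir.iterdir()))
    except Exception as err:
        raise RuntimeError(f"stage 'demux' failed: {err}") from err

    # --- stage 3: stack + catalog + match ----------------------------------
    try:
        stack_dir = out / "stack"
        stack_dir.mkdir(exist_ok=True)
        matches_path = stack_dir / "matches.tsv"
        pair_link_path = stack_dir / "catalog_pairs.tsv"
        catalog_sizes = {}
        first = True
        with open(pair_link_path, "w") as link_fh:
            link_fh.write("catalog_id\tpair_ids\n")
            for member in (1, 2):
                loci_by_ind = []
                for sample in samples:
                    clean = clean_sets[sample.sample_id]
                    reads = list(
                        zip(clean.pair_ids, clean.reads1 if member == 1 else clean.reads2)
                    )
                    loci = rs.build_loci(reads, config.stacking, sample.sample_id)
                    loci_by_ind.append((sample.sample_id, loci))
                rs.write_loci_tsv(loci_by_ind, stack_dir / f"loci.member{member}.tsv")
                catalog = rs.build_catalog(loci_by_ind, config.stacking)
                catalog_sizes[f"member{member}"] = len(catalog)
                rs.write_catalog(
                    catalog,
                    stack_dir / f"catalog.member{member}.fasta",
                    stack_dir / f"catalog.member{member}.tsv",
                    member=member,
                )
                loci_lookup = {
                    (ind, locus.locus_id): locus for ind, loci in loci_by_ind for locus in loci
                }
                for entry in catalog:
                    pair_ids = sorted(
                        {rid for contrib in entry.contributors
                         for rid in loci_lookup[contrib].read_ids}
                    )
                    link_fh.write(
                        f"r{member}_{entry.catalog_id:05d}\t{','.join(pair_ids)}\n"
                    )
                for sample_id, loci in loci_by_ind:
                    rows = rs.match_to_catalog(loci, catalog, config.stacking)
                    rs.write_matches_tsv(rows, matches_path, member=member, append=not first)
                    first = False
        manifest.counts["catalog_loci"] = catalog_sizes
        log.info("stack: catalog sizes %s", catalog_sizes)
        _register(manifest, out, *sorted(stack_dir.iterdir()))
    except Exception as err:
        raise RuntimeError(f"stage 'stack' failed: {err}") from err

    # --- stage 4: screen ----------------------------------------------------
    try:
        screen_dir = out / "screen"
        screen_dir.mkdir(exist_ok=True)
        markers, screen_counts = run_screen_stage(
            matches_path, pair_link_path,
            {f"member{m}": stack_dir / f"catalog.member{m}.tsv" for m in (1, 2)},
            samples, clean_sets, config.screen, screen_dir,
        )
        manifest.counts.update(screen_counts)
        log.info("screen: %s", screen_counts)
        _register(manifest, out, *sorted(screen_dir.iterdir()))
    except Exception as err:
        raise RuntimeError(f"stage 'screen' failed: {err}") from err

    # --- stage 5: report ----------------------------------------------------
    try:
        report_dir = out / "report"
        report_dir.mkdir(exist_ok=True)
        metadata = {
            "seed": config.seed,
            "scenario": config.scenario or "(external input)",
            "samples": len(samples),
        }
        write_marker_report(
            markers, {}, metadata, report_dir / "markers.tsv", report_dir / "summary.txt"
        )
        _register(manifest, out, *sorted(report_dir.iterdir()))
    except Exception as err:
        raise RuntimeError(f"stage 'report' failed: {err}") from err

    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def run_screen_stage(
    matches_path: Path,
    pair_link_path: Path,
    catalog_tsvs: dict[str, Path],
    samples: list[Sample],
    clean_sets: dict[str, dmx.CleanReadSet],
    params: ss.ScreenParams,
    screen_dir: Path,
) -> tuple[list[ss.CandidateMarker], dict]:
    """The screen stage, runnable alone from persisted stage-3 artifacts."""
    matches = rs.read_matches_tsv(matches_path)
    matrix = ss.build_presence_matrix([(r[0], r[1]) for r in matches], samples)
    ss.write_presence_matrix(matrix, screen_dir / "presence_matrix.tsv")

    consensus_by_catalog: dict[str, str] = {}
    member_by_catalog: dict[str, int] = {}
    for member_name, tsv in catalog_tsvs.items():
        member = int(member_name[-1])
        for line in Path(tsv).read_text().splitlines()[1:]:
            cid, consensus = line.split("\t")[:2]
            consensus_by_catalog[cid] = consensus
            member_by_catalog[cid] = member
    pair_ids_by_catalog: dict[str, set[str]] = {}
    for line in Path(pair_link_path).read_text().splitlines()[1:]:
        parts = line.split("\t")
        cid = parts[0]
        ids = parts[1].split(",") if len(parts) > 1 and parts[1] else []
        pair_ids_by_catalog[cid] = set(ids)

    candidates = ss.screen_sex_specific(matrix, params)
    all_markers: list[ss.CandidateMarker] = []
    counts: dict = {"candidate_loci": {s: len(c) for s, c in candidates.items()}}
    for sex in params.screen_sexes:
        markers = ss.consolidate_pe_pairs(
            candidates.get(sex, []), sex, pair_ids_by_catalog, consensus_by_catalog,
            member_by_catalog, presence_matrix=matrix,
        )
        survivors = ss.exclude_cross_sex_matches(
            markers, ss.opposite_sex_reads(clean_sets, sex)
        )
        counts.setdefault("markers_after_consolidation", {})[sex] = len(markers)
        counts.setdefault("final_markers", {})[sex] = len(survivors)
        all_markers.extend(survivors)
    ss.write_candidate_report(all_markers, screen_dir / "candidates.tsv")
    ss.write_marker_fasta(all_markers, screen_dir / "markers.fasta")
    return all_markers, counts
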