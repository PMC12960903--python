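"""End-to-end pipeline: configuration, orchestration, logging, run report.

The run is a single-process stream over transcripts: parse the annotation,
reconstruct each transcript from the genome, enumerate and score ORFs,
classify, project the primary ORF back to exon-aware CDS/UTR blocks, collect
translational context, then write the annotated GTF/GFF3, the summary TSV,
the five FASTA exports and a plain-text log. Deterministic given the config;
the seed affects only model training, never annotation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .annotate import annotate_transcript
from .annotation_io import build_feature_records, parse_annotation, write_annotation
from .genome import open_genome
from .scoring import SPECIES_CUTOFFS, CodingModel, fixture_model
from .summary import summarize_transcript, write_sequence_exports, write_summary

logger = logging.getLogger(__name__)

_CONFIG_DEFAULTS = dict(
    gtf_path=None,
    genome_path=None,
    model_selector=None,
    n_top=5,
    coding_cutoff=None,
    uorf_min_prob=0.5,
    nmd_threshold_nt=50,
    min_uorf_length_nt=9,
    output_dir="orfannotate_out",
    dialect="auto",
    seed=0,
)


@dataclass
class PipelineConfig:
    gtf_path: str
    genome_path: str
    model_selector: object  # path, 'fixture', 'length', or a CodingModel
    n_top: int = 5
    coding_cutoff: float | None = None
    uorf_min_prob: float = 0.5
    nmd_threshold_nt: int = 50
    min_uorf_length_nt: int = 9
    output_dir: str = "orfannotate_out"
    dialect: str = "auto"
    seed: int = 0

    def validate(self) -> None:
        if not self.gtf_path or not self.genome_path or self.model_selector is None:
            raise ValueError("gtf_path, genome_path and model_selector are required")
        if self.n_top < 1:
            raise ValueError(f"n_top must be >= 1, got {self.n_top}")
        if self.coding_cutoff is not None and not 0.0 <= self.coding_cutoff <= 1.0:
            raise ValueError(f"coding_cutoff must be in [0,1], got {self.coding_cutoff}")
        if not 0.0 <= self.uorf_min_prob <= 1.0:
            raise ValueError(f"uorf_min_prob must be in [0,1], got {self.uorf_min_prob}")
        if self.nmd_threshold_nt < 0:
            raise ValueError(f"nmd_threshold_nt must be >= 0, got {self.nmd_threshold_nt}")
        if self.dialect not in {"gtf", "gff3", "auto"}:
            raise ValueError(f"dialect must be gtf/gff3/auto, got {self.dialect!r}")


def load_config(config_path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Resolve a config: CLI flags override file values override defaults."""
    values = dict(_CONFIG_DEFAULTS)
    if config_path is not None:
        with open(config_path) as handle:
            file_values = json.load(handle)
        for key, value in file_values.items():
            if key not in values:
                logger.warning("config %s: unknown key %r ignored", config_path, key)
                continue
            values[key] = value
    for key, value in overrides.items():
        if key not in values:
            raise ValueError(f"unknown configuration key {key!r}")
        if value is not None:
            values[key] = value
    config = PipelineConfig(**values)
    config.validate()
    return config


def resolve_model(selector, seed: int = 0) -> CodingModel:
    """Turn the model selector into a CodingModel.

    Accepts a CodingModel instance, a path to a serialized model JSON,
    'fixture' (demo model trained on synthetic sets) or 'length'
    (length-dominant diagnostic scorer). Species labels are recognised but
    have no bundled model: train one with `orfannotate train` (the published
    cutoff for the species is applied automatically at training time via
    --species-label, or per run with --cutoff).
    """
    if isinstance(selector, CodingModel):
        return selector
    selector = str(selector)
    if selector == "fixture":
        return fixture_model(seed=seed)
    if selector in ("length", "length-dominant"):
        return CodingModel.length_dominant()
    if selector in SPECIES_CUTOFFS:
        raise ValueError(
            f"no bundled model for species {selector!r}: train one with 'orfannotate train' "
            f"(recommended cutoff {SPECIES_CUTOFFS[selector]}) and pass its path"
        )
    path = Path(selector)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    return CodingModel.from_json(path)


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)


def _setup_run_logger(log_path: Path) -> logging.Logger:
    run_logger = logging.getLogger("orfannotate.run")
    run_logger.setLevel(logging.INFO)
    for handler in list(run_logger.handlers):
        run_logger.removeHandler(handler)
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    run_logger.addHandler(handler)
    return run_logger


def run(config: PipelineConfig) -> RunReport:
    """Execute the full annotation pipeline; returns the run report."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _setup_run_logger(out_dir / "run.log")
    report = RunReport()
    cfg_echo = {k: (str(v) if isinstance(v, (Path, CodingModel)) else v) for k, v in asdict(config).items()}
    log.info("configuration: %s", json.dumps(cfg_echo, default=str, sort_keys=True))

    t0 = time.perf_counter()
    log.info("step 1: parsing annotation %s", config.gtf_path)
    annotation_set = parse_annotation(config.gtf_path, dialect=config.dialect)
    for warning in annotation_set.warnings:
        log.warning("%s", warning)
    if not annotation_set.transcripts:
        log.warning("no transcripts parsed from %s", config.gtf_path)
    report.timings_s["parse"] = time.perf_counter() - t0

    log.info("step 1b: opening genome %s", config.genome_path)
    genome = open_genome(config.genome_path)
    model = resolve_model(config.model_selector, seed=config.seed)
    log.info("scorer: %s (cutoff %.4f%s)", model.species_label, model.cutoff,
             f", overridden to {config.coding_cutoff}" if config.coding_cutoff is not None else "")

    t0 = time.perf_counter()
    log.info("steps 2-7: annotating %d transcripts", len(annotation_set.transcripts))
    rows, inserted, exports = [], {}, []
    n_coding = n_dropped_contig = 0
    for tx in annotation_set:
        if tx.chrom not in genome:
            log.warning("transcript %s dropped: contig %s absent from genome", tx.transcript_id, tx.chrom)
            n_dropped_contig += 1
            continue
        ann = annotate_transcript(
            tx,
            genome,
            model,
            n_top=config.n_top,
            cutoff=config.coding_cutoff,
            uorf_min_prob=config.uorf_min_prob,
            min_uorf_length=config.min_uorf_length_nt,
            nmd_threshold_nt=config.nmd_threshold_nt,
        )
        if ann.coding:
            n_coding += 1
            inserted[tx.transcript_id] = build_feature_records(tx, ann)
        rows.append(summarize_transcript(tx, ann))
        exports.append((tx, ann))
    report.timings_s["annotate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    suffix = "gff3" if annotation_set.dialect == "gff3" else "gtf"
    annotated_path = out_dir / f"annotated.{suffix}"
    write_annotation(annotation_set, inserted, annotated_path)
    summary_path = out_dir / "summary.tsv"
    write_summary(rows, summary_path)
    fasta_paths = write_sequence_exports(exports, out_dir)
    report.timings_s["write"] = time.perf_counter() - t0

    report.counts = {
        "parsed": len(annotation_set.transcripts),
        "dropped_parse": annotation_set.n_dropped,
        "dropped_contig": n_dropped_contig,
        "annotated": len(rows),
        "coding": n_coding,
        "noncoding": len(rows) - n_coding,
    }
    report.outputs = {"annotated": str(annotated_path), "summary": str(summary_path)}
    report.outputs.update({k: str(v) for k, v in fasta_paths.items()})
    log.info("final counts: %s", json.dumps(report.counts, sort_keys=True))
    log.info("timings (s): %s", json.dumps({k: round(v, 3) for k, v in report.timings_s.items()}))
    return report
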