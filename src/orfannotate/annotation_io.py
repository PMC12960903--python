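"""Reading and writing GTF/GFF3 transcript annotations.

Internal coordinates are 0-based half-open throughout the package;
GTF/GFF3 serialization is 1-based inclusive. The conversion happens only
here, at the I/O boundary, so projection arithmetic elsewhere never deals
with inclusive endpoints.

Original input lines are kept verbatim so that the annotated output file
contains every input record byte-identically, with inserted CDS/UTR records
grouped immediately after the last original line of their transcript.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

UTR5_TYPE = "five_prime_utr"
UTR3_TYPE = "three_prime_utr"

_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')
_TRANSCRIPT_LEVEL_TYPES = {"transcript", "mrna", "mRNA"}


@dataclass
class TranscriptModel:
    """One transcript: chromosome, strand, and ordered exon intervals.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted ascending by genomic start regardless of strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    attributes: dict[str, str] = field(default_factory=dict)
    source_line_order: int = 0
    source: str = "orfannotate"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty/inverted exon ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def biotype(self) -> str | None:
        for key in ("transcript_biotype", "transcript_type", "biotype"):
            if key in self.attributes:
                return self.attributes[key]
        return None


@dataclass
class FeatureRecord:
    """One annotation line: CDS, five_prime_utr, three_prime_utr, exon or transcript.

    Stored 0-based half-open; serialized 1-based inclusive. ``frame`` is the
    GTF column-8 value: bases to skip at the block's 5' end to reach the next
    codon boundary. It is an integer for CDS records and "." otherwise.
    """

    chrom: str
    source: str
    feature_type: str
    start: int
    end: int
    strand: str
    frame: int | str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature with end <= start: ({self.start}, {self.end})")
        if self.feature_type == "CDS":
            if self.frame not in (0, 1, 2):
                raise ValueError(f"CDS record requires frame in {{0,1,2}}, got {self.frame!r}")
        elif self.frame != ".":
            raise ValueError(f"non-CDS record must have frame '.', got {self.frame!r}")

    def to_line(self, dialect: str) -> str:
        start1 = self.start + 1  # 1-based inclusive on output
        if dialect == "gtf":
            attrs = "".join(f'{k} "{v}"; ' for k, v in self.attributes.items()).rstrip()
        else:
            attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        cols = [
            self.chrom,
            self.source,
            self.feature_type,
            str(start1),
            str(self.end),
            ".",
            self.strand,
            str(self.frame),
            attrs,
        ]
        return "\t".join(cols)


@dataclass
class AnnotationSet:
    """Parsed annotation file: transcript models plus the verbatim input lines."""

    transcripts: list[TranscriptModel]
    lines: list[str]
    dialect: str
    last_line_of: dict[str, int]  # transcript_id -> index of its last input line
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(text))


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        if "=" in part:
            key, _, value = part.partition("=")
            out[key.strip()] = value.strip()
    return out


def sniff_dialect(path: str | Path) -> str:
    """Guess gtf vs gff3 from the file suffix, falling back to column-9 syntax."""
    name = str(path).lower()
    if name.endswith((".gff3", ".gff")):
        return "gff3"
    if name.endswith(".gtf"):
        return "gtf"
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 9:
                return "gtf" if '"' in cols[8] else "gff3"
    return "gtf"


def parse_annotation(path: str | Path, dialect: str = "auto") -> AnnotationSet:
    """Read a GTF or GFF3 file into TranscriptModels.

    Transcripts are grouped by ``transcript_id`` (GTF) or the exon ``Parent``
    chain (GFF3). A transcript-level line is not required: exon features alone
    define the model, with the transcript interval inferred as the exon span.
    Duplicate exons are deduplicated with a warning; transcripts with invalid
    intervals or unknown strand are dropped and counted, never fatal.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = sniff_dialect(path)
    if dialect not in {"gtf", "gff3"}:
        raise ValueError(f"unknown dialect {dialect!r}")

    lines: list[str] = []
    # transcript_id -> accumulated state
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    last_line_of: dict[str, int] = {}
    order: dict[str, int] = {}
    bad: dict[str, str] = {}  # transcript_id -> reason for drop
    warnings: list[str] = []
    # GFF3: ID of transcript-level features -> its own id (for Parent chains)
    gff3_tx_gene: dict[str, str] = {}

    with open(path) as handle:
        for idx, raw in enumerate(handle):
            lines.append(raw.rstrip("\n"))
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                warnings.append(f"line {idx + 1}: fewer than 9 columns, skipped")
                continue
            chrom, source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols[:9]
            if dialect == "gtf":
                attrs = _parse_gtf_attributes(attr_s)
                tid = attrs.get("transcript_id")
                gid = attrs.get("gene_id", tid or "")
            else:
                attrs = _parse_gff3_attributes(attr_s)
                if ftype.lower() in {"mrna", "transcript"} or (
                    ftype.lower() not in {"exon", "gene", "cds"} and "ID" in attrs and "Parent" in attrs
                ):
                    tid = attrs.get("ID")
                    if tid:
                        gff3_tx_gene[tid] = attrs.get("Parent", tid)
                    gid = attrs.get("Parent", tid or "")
                elif ftype.lower() == "exon":
                    tid = attrs.get("Parent")
                    if tid and "," in tid:
                        tid = tid.split(",")[0]
                        warnings.append(f"line {idx + 1}: multi-parent exon, using first parent")
                    gid = gff3_tx_gene.get(tid or "", tid or "")
                else:
                    continue
            if not tid:
                continue
            last_line_of[tid] = idx
            order.setdefault(tid, idx)
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError:
                bad[tid] = f"non-numeric coordinates at line {idx + 1}"
                continue
            info = meta.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "attributes": {}, "source": source}
            )
            # transcript-level attributes win over exon-level ones for the model
            if ftype.lower() in _TRANSCRIPT_LEVEL_TYPES or not info["attributes"]:
                info["attributes"] = {**info["attributes"], **attrs}
                info["source"] = source
            if ftype.lower() != "exon":
                continue
            if end <= start:
                bad[tid] = f"exon with end <= start at line {idx + 1}"
                continue
            if strand not in {"+", "-"}:
                bad[tid] = f"unknown strand {strand!r} at line {idx + 1}"
                continue
            if info["strand"] not in {"+", "-"}:
                info["strand"] = strand
            exons.setdefault(tid, []).append((start, end))

    transcripts: list[TranscriptModel] = []
    n_dropped = 0
    for tid in sorted(meta, key=order.get):
        if tid in bad:
            warnings.append(f"transcript {tid} dropped: {bad[tid]}")
            n_dropped += 1
            continue
        if tid not in exons:
            warnings.append(f"transcript {tid} skipped: no exon features")
            n_dropped += 1
            continue
        info = meta[tid]
        if info["strand"] not in {"+", "-"}:
            warnings.append(f"transcript {tid} dropped: unknown strand {info['strand']!r}")
            n_dropped += 1
            continue
        exon_list = sorted(set(exons[tid]))
        if len(exon_list) < len(exons[tid]):
            warnings.append(f"transcript {tid}: duplicate exon lines deduplicated")
        try:
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"] or tid,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exon_list,
                attributes=info["attributes"],
                source_line_order=order[tid],
                source=info["source"],
            )
        except ValueError as exc:
            warnings.append(f"transcript {tid} dropped: {exc}")
            n_dropped += 1
            continue
        transcripts.append(model)

    for msg in warnings:
        logger.warning(msg)
    return AnnotationSet(
        transcripts=transcripts,
        lines=lines,
        dialect=dialect,
        last_line_of=last_line_of,
        n_dropped=n_dropped,
        warnings=warnings,
    )


def _check_transcript_order(blocks: Sequence[tuple[int, int]], strand: str, label: str) -> None:
    starts = [b[0] for b in blocks]
    ordered = starts == sorted(starts) if strand == "+" else starts == sorted(starts, reverse=True)
    if not ordered:
        raise ValueError(f"{label}: genomic blocks are not in transcript (5'->3') order")


def build_feature_records(model: TranscriptModel, annotation) -> list[FeatureRecord]:
    """Build the CDS and UTR records to insert for one coding transcript.

    ``annotation`` must carry genomic CDS/UTR blocks in transcript (5'->3')
    order. Frame of each CDS block is (3 - (cumulative CDS nt 5' of the
    block mod 3)) mod 3, accumulated along transcript order — on the minus
    strand accumulation therefore starts from the block with the larger
    genomic coordinate. Non-coding transcripts yield no records.
    """
    if not getattr(annotation, "coding", False):
        return []
    cds_blocks = annotation.cds_blocks
    if not cds_blocks:
        raise ValueError(f"{model.transcript_id}: coding annotation without CDS blocks")
    _check_transcript_order(cds_blocks, model.strand, f"{model.transcript_id} CDS")

    base_attrs = {"gene_id": model.gene_id, "transcript_id": model.transcript_id}
    records: list[FeatureRecord] = []
    cumulative = 0
    for g_start, g_end in cds_blocks:
        frame = (3 - (cumulative % 3)) % 3
        records.append(
            FeatureRecord(
                chrom=model.chrom,
                source="orfannotate",
                feature_type="CDS",
                start=g_start,
                end=g_end,
                strand=model.strand,
                frame=frame,
                attributes=dict(base_attrs),
            )
        )
        cumulative += g_end - g_start
    for ftype, blocks in ((UTR5_TYPE, annotation.utr5_blocks), (UTR3_TYPE, annotation.utr3_blocks)):
        for g_start, g_end in blocks:
            records.append(
                FeatureRecord(
                    chrom=model.chrom,
                    source="orfannotate",
                    feature_type=ftype,
                    start=g_start,
                    end=g_end,
                    strand=model.strand,
                    frame=".",
                    attributes=dict(base_attrs),
                )
            )
    return records


def write_annotation(
    annotation_set: AnnotationSet,
    inserted: Mapping[str, Iterable[FeatureRecord]],
    path: str | Path,
    dialect: str | None = None,
) -> None:
    """Write the annotated file: every input line verbatim, plus inserted records.

    Inserted CDS/UTR records follow the last original line of their
    transcript, in the order given (CDS blocks 5'->3', then UTRs), so output
    order is deterministic. GFF3 records gain ID/Parent attributes.
    """
    dialect = dialect or annotation_set.dialect
    insert_after: dict[int, list[FeatureRecord]] = {}
    for tid, records in inserted.items():
        records = list(records)
        if not records:
            continue
        if tid not in annotation_set.last_line_of:
            raise ValueError(f"inserted records for unknown transcript {tid!r}")
        if dialect == "gff3":
            counters: dict[str, int] = {}
            for rec in records:
                counters[rec.feature_type] = counters.get(rec.feature_type, 0) + 1
                attrs = {"ID": f"{rec.feature_type}:{tid}:{counters[rec.feature_type]}", "Parent": tid}
                attrs.update({k: v for k, v in rec.attributes.items() if k not in ("gene_id", "transcript_id")})
                rec = FeatureRecord(
                    rec.chrom, rec.source, rec.feature_type, rec.start, rec.end, rec.strand, rec.frame, attrs
                )
                insert_after.setdefault(annotation_set.last_line_of[tid], []).append(rec)
        else:
            insert_after.setdefault(annotation_set.last_line_of[tid], []).extend(records)

    with open(path, "w") as out:
        for idx, line in enumerate(annotation_set.lines):
            out.write(line + "\n")
            for rec in insert_after.get(idx, ()):
                out.write(rec.to_line(dialect) + "\n")


def write_transcript_models(models: Iterable[TranscriptModel], path: str | Path, dialect: str = "gtf") -> None:
    """Serialize bare transcript models (transcript + exon lines); fixture/export helper."""
    with open(path, "w") as out:
        for model in models:
            attrs = {"gene_id": model.gene_id, "transcript_id": model.transcript_id}
            attrs.update({k: v for k, v in model.attributes.items() if k not in attrs})
            span = model.span
            if dialect == "gtf":
                tx = FeatureRecord(model.chrom, model.source, "transcript", span[0], span[1], model.strand, ".", attrs)
                out.write(tx.to_line("gtf") + "\n")
                for start, end in model.exons:
                    out.write(
                        FeatureRecord(model.chrom, model.source, "exon", start, end, model.strand, ".", dict(attrs)).to_line("gtf")
                        + "\n"
                    )
            else:
                tx_attrs = {"ID": model.transcript_id, "Parent": model.gene_id}
                tx_attrs.update({k: v for k, v in model.attributes.items() if k not in ("gene_id", "transcript_id")})
                out.write(
                    FeatureRecord(model.chrom, model.source, "mRNA", span[0], span[1], model.strand, ".", tx_attrs).to_line("gff3")
                    + "\n"
                )
                for i, (start, end) in enumerate(model.exons, 1):
                    ex_attrs = {"ID": f"exon:{model.transcript_id}:{i}", "Parent": model.transcript_id}
                    out.write(
                        FeatureRecord(model.chrom, model.source, "exon", start, end, model.strand, ".", ex_attrs).to_line("gff3")
                        + "\n"
                    )
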