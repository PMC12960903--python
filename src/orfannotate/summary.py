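"""Transcript-level summary table and FASTA sequence exports.

The summary is a TSV with one row per parsed transcript, coding and
non-coding alike; non-coding rows carry "NA" in every ORF-dependent field.
uORFs are packed as semicolon-joined "t_start-t_end:prob" triplets.
Sequence exports (CDS, protein, 5'/3' UTR, top-N ORFs) cover coding
transcripts only, 60-column wrapped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotate import TranscriptAnnotation
from .annotation_io import TranscriptModel

SUMMARY_COLUMNS = [
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "transcript_length",
    "orf_t_start",
    "orf_t_end",
    "orf_genomic_start",
    "orf_genomic_end",
    "coding_prob",
    "coding_class",
    "kozak_context",
    "kozak_strength",
    "nmd_flag",
    "utr5_length",
    "utr3_length",
    "utr5_junctions",
    "utr3_junctions",
    "uorf_count",
    "uorf_details",
    "biotype",
]

NA = "NA"


def _fmt_prob(prob: float) -> str:
    return f"{prob:.4f}"


def summarize_transcript(model: TranscriptModel, ann: TranscriptAnnotation) -> dict[str, str]:
    """One summary row; every value already stringified for stable TSV output."""
    row = dict.fromkeys(SUMMARY_COLUMNS, NA)
    row["transcript_id"] = model.transcript_id
    row["gene_id"] = model.gene_id
    row["chrom"] = model.chrom
    row["strand"] = model.strand
    row["transcript_length"] = str(model.length)
    row["coding_class"] = "coding" if ann.coding else "noncoding"
    row["biotype"] = model.biotype or row["coding_class"]
    if ann.coding:
        bounds = ann.genomic_orf_bounds
        row["orf_t_start"] = str(ann.primary.t_start)
        row["orf_t_end"] = str(ann.primary.t_end)
        row["orf_genomic_start"] = str(bounds[0])
        row["orf_genomic_end"] = str(bounds[1])
        row["coding_prob"] = _fmt_prob(ann.primary.coding_prob)
        row["kozak_context"] = ann.kozak.context
        row["kozak_strength"] = ann.kozak.strength
        row["nmd_flag"] = str(ann.nmd.flagged)
        row["utr5_length"] = str(ann.utr.utr5_length)
        row["utr3_length"] = str(ann.utr.utr3_length)
        row["utr5_junctions"] = str(ann.utr.utr5_junctions)
        row["utr3_junctions"] = str(ann.utr.utr3_junctions)
        row["uorf_count"] = str(len(ann.uorfs))
        row["uorf_details"] = (
            ";".join(f"{u.t_start}-{u.t_end}:{_fmt_prob(u.coding_prob)}" for u in ann.uorfs) if ann.uorfs else ""
        )
    for key, value in row.items():
        if "\t" in value or "\n" in value:
            raise ValueError(f"summary field {key} contains a tab/newline")
    return row


def write_summary(rows: Sequence[Mapping[str, str]], path: str | Path) -> None:
    """Write the TSV summary: fixed header, input order, deterministic bytes."""
    with open(path, "w") as out:
        out.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            out.write("\t".join(row[col] for col in SUMMARY_COLUMNS) + "\n")


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for header, seq in records:
            out.write(f">{header}\n{_wrap(seq)}\n")


def write_sequence_exports(
    annotations: Sequence[tuple[TranscriptModel, TranscriptAnnotation]],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write cds/protein/utr5/utr3/orfs FASTA files for coding transcripts.

    Zero-length UTRs are omitted from the UTR files; the ORF file holds the
    top-N candidates of each coding transcript with rank, coordinates and
    coding probability in the header.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cds, protein, utr5, utr3, orfs = [], [], [], [], []
    for model, ann in annotations:
        if not ann.coding:
            continue
        tid = model.transcript_id
        cds.append((tid, ann.cds_seq))
        protein.append((tid, ann.protein))
        if ann.utr5_seq:
            utr5.append((tid, ann.utr5_seq))
        if ann.utr3_seq:
            utr3.append((tid, ann.utr3_seq))
        for cand in ann.top_orfs:
            header = (
                f"{tid} rank={cand.rank} t_start={cand.t_start} "
                f"t_end={cand.t_end} coding_prob={_fmt_prob(cand.coding_prob)}"
            )
            orfs.append((header, cand.orf_seq))
    paths = {}
    for name, records in (("cds", cds), ("protein", protein), ("utr5", utr5), ("utr3", utr3), ("orfs", orfs)):
        paths[name] = out_dir / f"{name}.fa"
        write_fasta(records, paths[name])
    return paths
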