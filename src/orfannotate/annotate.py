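"""Per-transcript orchestration: sequence -> ORFs -> classification -> context.

This is the unit of work of the pipeline: given one transcript model, the
genome and a coding-potential scorer, produce the consolidated
TranscriptAnnotation that downstream modules turn into GTF records, summary
rows and FASTA exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import TranscriptModel
from .context import (
    NMD_THRESHOLD_NT,
    KozakResult,
    NmdResult,
    UtrMetrics,
    kozak_context,
    nmd_status,
    translate_cds,
    utr_metrics,
)
from .genome import build_coordinate_map, junction_positions, project_to_genome, reconstruct_sequence
from .orfs import OrfCandidate, UorfRecord, detect_uorfs, enumerate_orfs, rank_and_select
from .scoring import CodingModel, classify


@dataclass
class TranscriptAnnotation:
    """Consolidated per-transcript result."""

    transcript_id: str
    transcript_seq: str
    junctions: list[int]
    coding: bool
    primary: OrfCandidate | None = None
    top_orfs: list[OrfCandidate] = field(default_factory=list)
    uorfs: list[UorfRecord] = field(default_factory=list)
    kozak: KozakResult | None = None
    nmd: NmdResult | None = None
    utr: UtrMetrics | None = None
    protein: str | None = None
    cds_blocks: list[tuple[int, int]] = field(default_factory=list)
    utr5_blocks: list[tuple[int, int]] = field(default_factory=list)
    utr3_blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def coding_prob(self) -> float | None:
        return self.primary.coding_prob if self.primary else None

    @property
    def cds_seq(self) -> str | None:
        return self.transcript_seq[self.primary.t_start : self.primary.t_end] if self.coding else None

    @property
    def utr5_seq(self) -> str | None:
        return self.transcript_seq[: self.primary.t_start] if self.coding else None

    @property
    def utr3_seq(self) -> str | None:
        return self.transcript_seq[self.primary.t_end :] if self.coding else None

    @property
    def genomic_orf_bounds(self) -> tuple[int, int] | None:
        if not self.cds_blocks:
            return None
        return min(b[0] for b in self.cds_blocks), max(b[1] for b in self.cds_blocks)


def annotate_transcript(
    model: TranscriptModel,
    genome,
    scorer: CodingModel,
    *,
    n_top: int = 5,
    cutoff: float | None = None,
    uorf_min_prob: float = 0.5,
    min_uorf_length: int = 9,
    nmd_threshold_nt: int = NMD_THRESHOLD_NT,
) -> TranscriptAnnotation:
    """Annotate one transcript end to end.

    The highest-probability complete ORF is the primary ORF; the transcript
    is coding iff its probability reaches the cutoff (scorer default unless
    overridden). Kozak/NMD/UTR/uORF annotation and coordinate projection run
    only for coding transcripts.
    """
    seq = reconstruct_sequence(model, genome)
    cmap = build_coordinate_map(model)
    junctions = junction_positions(cmap)

    candidates = enumerate_orfs(seq)
    primary, top = rank_and_select(candidates, scorer, n_top, transcript_seq=seq)
    effective_cutoff = scorer.cutoff if cutoff is None else cutoff
    coding = primary is not None and classify(primary.coding_prob, effective_cutoff) == "coding"

    ann = TranscriptAnnotation(
        transcript_id=model.transcript_id,
        transcript_seq=seq,
        junctions=junctions,
        coding=coding,
        primary=primary if coding else None,
        top_orfs=top,
    )
    if not coding:
        return ann

    ann.cds_blocks = project_to_genome(cmap, (primary.t_start, primary.t_end))
    if primary.t_start > 0:
        ann.utr5_blocks = project_to_genome(cmap, (0, primary.t_start))
    if primary.t_end < cmap.transcript_length:
        ann.utr3_blocks = project_to_genome(cmap, (primary.t_end, cmap.transcript_length))

    ann.uorfs = detect_uorfs(seq, primary, scorer, min_prob=uorf_min_prob, min_length=min_uorf_length)
    ann.kozak = kozak_context(seq, primary.t_start)
    ann.nmd = nmd_status(primary, junctions, threshold_nt=nmd_threshold_nt)
    ann.utr = utr_metrics(cmap.transcript_length, primary, junctions)
    ann.protein = translate_cds(ann.cds_seq)
    return ann
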