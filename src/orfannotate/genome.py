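"""Indexed genome access, transcript sequence reconstruction, and coordinate projection.

Transcript space is 0-based along the mature (spliced) transcript, 5'->3'.
A CoordinateMap ties transcript intervals to genomic exon blocks; on the
minus strand the first transcript block maps to the highest-coordinate exon
and each block reads in reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import reverse_complement

from .annotation_io import TranscriptModel


class FastaGenome:
    """Random-access genome backed by an indexed FASTA (pyfaidx).

    Retrieval is case-insensitive (soft-masking uppercased) and strict about
    bounds: fetching past a contig end is a range error, never silent
    truncation.
    """

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self.path = Path(path)

    @property
    def contigs(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fasta.records.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} not in genome")
        length = len(self._fasta.records[chrom])
        if start < 0 or end > length or end < start:
            raise ValueError(f"interval [{start},{end}) out of range for {chrom} (length {length})")
        if start == end:
            return ""
        return str(self._fasta[chrom][start:end])


class InMemoryGenome:
    """Dict-backed genome with the same retrieval contract; used by fixtures and tests."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @property
    def contigs(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"contig {chrom!r} not in genome")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or end < start:
            raise ValueError(f"interval [{start},{end}) out of range for {chrom} (length {len(seq)})")
        return seq[start:end]


def open_genome(fasta_path: str | Path) -> FastaGenome:
    """Open an indexed genome FASTA, building the .fai index if absent."""
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    return FastaGenome(path)


def reconstruct_sequence(model: TranscriptModel, genome) -> str:
    """Spliced transcript sequence, 5'->3'.

    Plus strand: concatenation of exon substrings in ascending genomic order;
    minus strand: reverse complement of that concatenation.
    """
    spliced = "".join(genome.fetch(model.chrom, start, end) for start, end in model.exons)
    if model.strand == "-":
        return reverse_complement(spliced)
    return spliced


@dataclass(frozen=True)
class CoordinateMap:
    """Bidirectional transcript<->genome block map in 5'->3' transcript order.

    blocks: (t_start, t_end, g_start, g_end) tuples; transcript intervals
    tile [0, transcript_length); each block's transcript and genomic lengths
    match. On '-', genomic blocks appear in descending genomic order.
    """

    strand: str
    transcript_length: int
    blocks: tuple[tuple[int, int, int, int], ...]


def build_coordinate_map(model: TranscriptModel) -> CoordinateMap:
    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    blocks = []
    t = 0
    for g_start, g_end in exons:
        span = g_end - g_start
        blocks.append((t, t + span, g_start, g_end))
        t += span
    return CoordinateMap(strand=model.strand, transcript_length=t, blocks=tuple(blocks))


def project_to_genome(cmap: CoordinateMap, t_interval: tuple[int, int]) -> list[tuple[int, int]]:
    """Project a transcript interval to genomic blocks, split at exon junctions.

    Returned in transcript (5'->3') order, so on '-' the genomic intervals
    descend. Total genomic length equals the transcript interval length.
    """
    a, b = t_interval
    if not (0 <= a < b <= cmap.transcript_length):
        raise ValueError(f"transcript interval [{a},{b}) out of range [0,{cmap.transcript_length})")
    out: list[tuple[int, int]] = []
    for t_start, t_end, g_start, g_end in cmap.blocks:
        lo, hi = max(a, t_start), min(b, t_end)
        if lo >= hi:
            continue
        if cmap.strand == "+":
            out.append((g_start + (lo - t_start), g_start + (hi - t_start)))
        else:
            # transcript position p maps to genomic base g_end-1-(p - t_start)
            out.append((g_start + (t_end - hi), g_start + (t_end - lo)))
    return out


def junction_positions(cmap: CoordinateMap) -> list[int]:
    """Exon-exon junction positions in transcript coordinates.

    A junction at p lies between transcript bases p-1 and p; single-exon
    transcripts have none.
    """
    return [t_end for _, t_end, _, _ in cmap.blocks[:-1]]
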