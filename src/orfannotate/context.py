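"""Translational context of the primary ORF: Kozak, NMD, UTR metrics, translation.

Kozak strength follows the canonical determinants: a purine at position -3
and a G at +4. The NMD heuristic is the positional 50-nt rule — a stop codon
lying strictly more than 50 nt upstream of the final exon-exon junction
(measured in transcript coordinates from the 3' end of the stop) flags the
transcript as NMD-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .orfs import STOP_CODONS, OrfCandidate

NMD_THRESHOLD_NT = 50


@dataclass(frozen=True)
class KozakResult:
    """10-character start-codon context (-6..-1, ATG, +4) and its strength class."""

    context: str
    strength: str  # strong | moderate | weak

    def __post_init__(self) -> None:
        if len(self.context) != 10 or self.context[6:9] != "ATG":
            raise ValueError(f"malformed Kozak context {self.context!r}")


@dataclass(frozen=True)
class NmdResult:
    flagged: bool
    stop_to_last_junction: int | None  # None for single-exon transcripts


@dataclass(frozen=True)
class UtrMetrics:
    utr5_length: int
    utr3_length: int
    utr5_junctions: int
    utr3_junctions: int


def kozak_context(seq: str, t_start: int) -> KozakResult:
    """Assemble and classify the Kozak context around the start codon.

    Positions outside the transcript are N-padded; N never satisfies a
    condition, so an edge start codon can be at best moderate. Strong needs
    both -3 in {A,G} and +4 = G; moderate exactly one; weak neither.
    """
    seq = seq.upper()
    if seq[t_start : t_start + 3] != "ATG":
        raise ValueError(f"no ATG at transcript position {t_start}")
    upstream = seq[max(0, t_start - 6) : t_start].rjust(6, "N")
    plus4 = seq[t_start + 3] if t_start + 4 <= len(seq) else "N"
    context = upstream + "ATG" + plus4
    conditions = (context[3] in "AG") + (plus4 == "G")
    strength = {2: "strong", 1: "moderate", 0: "weak"}[conditions]
    return KozakResult(context=context, strength=strength)


def nmd_status(
    orf: OrfCandidate,
    junctions: Sequence[int],
    threshold_nt: int = NMD_THRESHOLD_NT,
) -> NmdResult:
    """Apply the 50-nt rule against the final exon-exon junction.

    Distance is last_junction - orf.t_end (3' end of the stop codon);
    flagged iff distance > threshold (strict). No junction (single exon)
    means never flagged.
    """
    if not junctions:
        return NmdResult(flagged=False, stop_to_last_junction=None)
    distance = junctions[-1] - orf.t_end
    return NmdResult(flagged=distance > threshold_nt, stop_to_last_junction=distance)


def utr_metrics(transcript_length: int, orf: OrfCandidate, junctions: Sequence[int]) -> UtrMetrics:
    """UTR lengths and junction counts around the ORF.

    A junction exactly at the ORF start counts for the 5'UTR and one exactly
    at the ORF end for the 3'UTR; junctions strictly inside the CDS count for
    neither. Lengths always satisfy utr5 + ORF + utr3 = transcript length.
    """
    if not (0 <= orf.t_start and orf.t_end <= transcript_length):
        raise ValueError("ORF outside transcript bounds")
    return UtrMetrics(
        utr5_length=orf.t_start,
        utr3_length=transcript_length - orf.t_end,
        utr5_junctions=sum(1 for j in junctions if j <= orf.t_start),
        utr3_junctions=sum(1 for j in junctions if j >= orf.t_end),
    )


def translate_cds(cds_seq: str) -> str:
    """Translate a CDS (standard genetic code), excluding the terminal stop.

    Requires length divisible by 3, an ATG start and a single terminal stop;
    an internal in-frame stop is a consistency error (it would violate ORF
    construction). Codons containing N translate to X.
    """
    cds_seq = cds_seq.upper()
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    if not cds_seq.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    if cds_seq[-3:] not in STOP_CODONS:
        raise ValueError("CDS does not end with a stop codon")
    protein = str(Seq(cds_seq[:-3]).translate())
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    return protein
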