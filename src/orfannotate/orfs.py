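"""AUG-initiated ORF enumeration, ranking, and upstream-ORF detection.

Only complete ORFs are called: an ATG paired with the first in-frame stop
codon downstream, stop included in the interval. ATGs with no in-frame stop
inside the sequence yield nothing (downstream logic — NMD, 3'UTR — needs a
stop). Codons containing N never match ATG or a stop, so unknown sequence
cannot fabricate a call.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from .scoring import CodingModel, FeatureVector, extract_features

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class OrfCandidate:
    """One AUG-initiated ORF in transcript coordinates, stop codon included."""

    t_start: int
    t_end: int
    orf_seq: str
    features: FeatureVector | None = None
    coding_prob: float | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if (self.t_end - self.t_start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if not self.orf_seq.startswith("ATG") or self.orf_seq[-3:] not in STOP_CODONS:
            raise ValueError("ORF must begin with ATG and end with a stop codon")

    @property
    def frame(self) -> int:
        return self.t_start % 3

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class UorfRecord:
    """An upstream ORF lying entirely 5' of the primary ORF."""

    t_start: int
    t_end: int
    coding_prob: float

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


def enumerate_orfs(seq: str) -> list[OrfCandidate]:
    """All complete AUG-initiated ORFs in the sense strand, sorted by start.

    Candidates sharing a stop but differing in start are distinct. Runs in
    O(L + #ATG log #stops) using per-frame stop indexes.
    """
    seq = seq.upper()
    stops_by_frame: list[list[int]] = [[], [], []]
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    out: list[OrfCandidate] = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        stops = stops_by_frame[i % 3]
        k = bisect_left(stops, i + 3)
        if k == len(stops):
            continue  # no in-frame stop: incomplete ORF, not called
        stop = stops[k]
        out.append(OrfCandidate(t_start=i, t_end=stop + 3, orf_seq=seq[i : stop + 3]))
    return out


def rank_and_select(
    candidates: list[OrfCandidate],
    scorer: CodingModel,
    n_top: int = 5,
    *,
    transcript_seq: str,
) -> tuple[OrfCandidate | None, list[OrfCandidate]]:
    """Score every candidate once and pick the primary ORF.

    Sorted by coding probability descending; ties broken by longer ORF, then
    smaller t_start. Returns (primary or None, top n_top candidates with
    ranks assigned).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    for cand in candidates:
        if cand.coding_prob is None:
            cand.features = extract_features(cand.orf_seq, transcript_seq, scorer.hexamer_table)
            cand.coding_prob = scorer.probability(cand.features)
    ordered = sorted(candidates, key=lambda c: (-c.coding_prob, -c.length, c.t_start))
    top = ordered[: min(n_top, len(ordered))]
    for rank, cand in enumerate(top, 1):
        cand.rank = rank
    return (top[0] if top else None), top


def detect_uorfs(
    seq: str,
    primary: OrfCandidate,
    scorer: CodingModel,
    min_prob: float,
    min_length: int = 9,
) -> list[UorfRecord]:
    """Non-overlapping upstream ORFs: entirely 5' of the primary start.

    Retained when coding probability exceeds ``min_prob`` (strict) and length
    (stop included) is at least ``min_length`` nt; the default 9 nt excludes
    degenerate ATG-stop dipeptides. ORFs overlapping the primary start
    (oORFs) are never reported. Sorted by t_start.
    """
    if primary is None:
        raise ValueError("detect_uorfs requires a primary ORF")
    out: list[UorfRecord] = []
    for cand in enumerate_orfs(seq):
        if cand.t_end > primary.t_start or cand.length < min_length:
            continue
        fv = extract_features(cand.orf_seq, seq, scorer.hexamer_table)
        prob = scorer.probability(fv)
        if prob > min_prob:
            out.append(UorfRecord(t_start=cand.t_start, t_end=cand.t_end, coding_prob=prob))
    return out
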