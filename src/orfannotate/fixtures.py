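"""Synthetic genome + annotation fixtures with fully known planted truth.

Each transcript is designed sequence-first: a 5'UTR, a planted primary ORF
(interior stop-free in frame), optional upstream ORFs, and a 3'UTR, with the
Kozak -3/+4 bases and the stop-to-last-junction distance chosen to force a
known strength class and NMD flag. The sequence is then split into exons and
embedded on a contig (reverse-complemented for minus-strand genes), so
reconstruction must return the designed sequence exactly.

Construction guarantees the planted ORFs are the only AUG-initiated ORFs:
UTRs, non-coding bodies and ORF interiors are drawn from a {C,G,T} alphabet
(no A, hence no ATG and no stop codon anywhere unplanted), planted elements
start with ATG and end with TAG, and the boundary analysis of those motifs
shows no ATG can straddle a planted/unplanted junction. Truth values are
therefore derivable by construction, never by running the pipeline.

The planted truth assumes the length-dominant diagnostic scorer
(``CodingModel.length_dominant()``): primary ORFs are >= 90 nt (probability
above its 0.35 cutoff), uORFs are 9-30 nt, and non-coding transcripts either
contain no ATG at all or only a 15-nt ORF scoring below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation_io import TranscriptModel, write_transcript_models
from .genome import InMemoryGenome
from .summary import write_fasta

_SAFE_BASES = np.array(list("CGT"))
_SAFE_PROBS = np.array([0.4, 0.4, 0.2])  # GC-leaning, coding-like interiors
_ACGT = np.array(list("ACGT"))

SCENARIOS = (
    "noncoding",
    "noncoding_short_orf",
    "coding_single",
    "coding_multi_nmd_false",
    "coding_multi_nmd_true",
    "coding_uorf",
)
_DEFAULT_MIX = {
    "noncoding": 0.15,
    "noncoding_short_orf": 0.05,
    "coding_single": 0.20,
    "coding_multi_nmd_false": 0.25,
    "coding_multi_nmd_true": 0.20,
    "coding_uorf": 0.15,
}
_KOZAK_PLAN = (("G", "G", "strong"), ("C", "G", "moderate"), ("G", "C", "moderate"), ("C", "C", "weak"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FixtureTruth:
    """Planted ground truth for one transcript, derived at construction time."""

    transcript_id: str
    scenario: str
    strand: str
    exon_count: int
    coding: bool
    transcript_seq: str
    junctions: list[int]
    orf_t_start: int | None = None
    orf_t_end: int | None = None
    uorfs: list[tuple[int, int]] = field(default_factory=list)
    kozak_strength: str | None = None
    nmd_flag: bool | None = None
    stop_to_last_junction: int | None = None
    utr5_length: int | None = None
    utr3_length: int | None = None
    utr5_junctions: int | None = None
    utr3_junctions: int | None = None


@dataclass
class Fixture:
    models: list[TranscriptModel]
    genome: InMemoryGenome
    truths: list[FixtureTruth]
    genome_path: Path | None = None
    gtf_path: Path | None = None
    truth_path: Path | None = None

    def truth_of(self, transcript_id: str) -> FixtureTruth:
        return next(t for t in self.truths if t.transcript_id == transcript_id)


def _safe_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence over {C,G,T}: contains no ATG and no stop codon."""
    if length == 0:
        return ""
    return "".join(rng.choice(_SAFE_BASES, size=length, p=_SAFE_PROBS))


def _orf_seq(rng: np.random.Generator, length: int, plus4: str | None = None) -> str:
    """Planted ORF of ``length`` nt: ATG + safe interior codons + TAG.

    ``plus4`` fixes the first base after ATG (the Kozak +4 position).
    """
    if length < 9 or length % 3:
        raise ValueError("planted ORF length must be a multiple of 3 and >= 9")
    interior = list(_safe_seq(rng, length - 6))
    if plus4 is not None:
        interior[0] = plus4
    return "ATG" + "".join(interior) + "TAG"


def _design_junctions(
    rng: np.random.Generator, length: int, exon_count: int, last_junction: int | None
) -> list[int]:
    """k-1 distinct junction positions in [1, length-1]; optionally pin the last."""
    needed = exon_count - 1
    if needed == 0:
        return []
    if last_junction is not None:
        pool = np.arange(1, last_junction)
        extra = rng.choice(pool, size=needed - 1, replace=False) if needed > 1 else np.array([], dtype=int)
        return sorted(extra.tolist() + [last_junction])
    pool = np.arange(1, length)
    return sorted(rng.choice(pool, size=needed, replace=False).tolist())


def _design_transcript(
    rng: np.random.Generator,
    scenario: str,
    exon_count_range: tuple[int, int],
    kozak_index: int,
) -> FixtureTruth:
    lo, hi = exon_count_range
    truth = FixtureTruth(
        transcript_id="", scenario=scenario, strand="+", exon_count=1, coding=False, transcript_seq="", junctions=[]
    )

    if scenario in ("noncoding", "noncoding_short_orf"):
        length = int(rng.integers(200, 600))
        seq = _safe_seq(rng, length)
        if scenario == "noncoding_short_orf":
            pos = int(rng.integers(20, length - 40))
            pos -= pos % 3  # keep construction tidy; frame is arbitrary for truth
            seq = seq[:pos] + _orf_seq(rng, 15) + seq[pos + 15 :]
        truth.exon_count = int(rng.integers(lo, hi + 1))
        truth.transcript_seq = seq
        truth.junctions = _design_junctions(rng, length, truth.exon_count, None)
        return truth

    # coding scenarios
    minus3, plus4, strength = _KOZAK_PLAN[kozak_index % len(_KOZAK_PLAN)]
    orf_len = int(rng.integers(30, 81)) * 3  # 90..240 nt
    utr5_len = int(rng.integers(10, 81))
    if scenario == "coding_multi_nmd_true":
        distance = int(rng.integers(51, 81))
        utr3_len = distance + int(rng.integers(10, 41))
    else:
        utr3_len = int(rng.integers(20, 101))

    utr5 = list(_safe_seq(rng, utr5_len))
    utr5[utr5_len - 3] = minus3  # Kozak -3; no A in UTR so this cannot create an ATG
    uorfs: list[tuple[int, int]] = []
    if scenario == "coding_uorf":
        n_uorfs = int(rng.integers(1, 3))
        cursor = 0
        for _ in range(n_uorfs):
            u_len = int(rng.integers(3, 11)) * 3  # 9..30 nt
            max_start = utr5_len - 10 - u_len  # keep clear of the Kozak window
            if max_start <= cursor:
                break
            u_start = int(rng.integers(cursor, max_start + 1))
            utr5[u_start : u_start + u_len] = list(_orf_seq(rng, u_len))
            uorfs.append((u_start, u_start + u_len))
            cursor = u_start + u_len
    utr5_seq = "".join(utr5)

    orf = _orf_seq(rng, orf_len, plus4=plus4)
    utr3_seq = _safe_seq(rng, utr3_len)
    seq = utr5_seq + orf + utr3_seq
    t_start, t_end = utr5_len, utr5_len + orf_len
    length = len(seq)

    if seq.count("ATG") != 1 + len(uorfs):  # construction guarantee, checked anyway
        raise AssertionError("fixture generation planted an unexpected ATG")

    if scenario == "coding_single":
        exon_count = 1
    elif scenario == "coding_uorf":
        exon_count = int(rng.integers(lo, hi + 1))
    else:
        if hi < 2:
            raise ValueError(f"scenario {scenario!r} needs >= 2 exons but exon_count_range={exon_count_range}")
        exon_count = int(rng.integers(max(2, lo), hi + 1))
    if exon_count == 1:
        junctions = []
    else:
        if scenario == "coding_multi_nmd_true":
            last = t_end + distance
        else:
            # last junction no more than 50 nt past the stop, no deeper than
            # 3 nt into the CDS interior; always leaves room for the others
            d_max = min(50, length - 1 - t_end)
            d_min = -(orf_len - 3)
            d = int(rng.integers(d_min, d_max + 1))
            last = t_end + d
        junctions = _design_junctions(rng, length, exon_count, last)

    truth.exon_count = exon_count
    truth.coding = True
    truth.transcript_seq = seq
    truth.junctions = junctions
    truth.orf_t_start = t_start
    truth.orf_t_end = t_end
    truth.uorfs = uorfs
    truth.kozak_strength = strength
    if junctions:
        truth.stop_to_last_junction = junctions[-1] - t_end
        truth.nmd_flag = truth.stop_to_last_junction > 50
    else:
        truth.nmd_flag = False
    truth.utr5_length = t_start
    truth.utr3_length = length - t_end
    truth.utr5_junctions = sum(1 for j in junctions if j <= t_start)
    truth.utr3_junctions = sum(1 for j in junctions if j >= t_end)
    return truth


def _place_on_genome(
    rng: np.random.Generator,
    truth: FixtureTruth,
    strand: str,
    chrom: str,
    contig_parts: list[str],
    offset: int,
) -> tuple[TranscriptModel, int]:
    """Append the gene's genomic sequence to the contig; return the model and new offset."""
    seq = truth.transcript_seq
    bounds = [0] + truth.junctions + [len(seq)]
    chunks = [seq[a:b] for a, b in zip(bounds, bounds[1:])]  # transcript order
    genomic_chunks = chunks if strand == "+" else [_revcomp(c) for c in reversed(chunks)]

    contig_parts.append("".join(rng.choice(_ACGT, size=int(rng.integers(30, 81)))))
    offset += len(contig_parts[-1])
    exons: list[tuple[int, int]] = []
    for i, chunk in enumerate(genomic_chunks):
        if i:
            intron = "".join(rng.choice(_ACGT, size=int(rng.integers(20, 121))))
            contig_parts.append(intron)
            offset += len(intron)
        exons.append((offset, offset + len(chunk)))
        contig_parts.append(chunk)
        offset += len(chunk)

    attrs = {}
    if int(truth.transcript_id.rsplit("_", 1)[-1]) % 2 == 0:
        attrs["transcript_biotype"] = "protein_coding" if truth.coding else "lncRNA"
    model = TranscriptModel(
        transcript_id=truth.transcript_id,
        gene_id=truth.transcript_id.replace("tx", "gene"),
        chrom=chrom,
        strand=strand,
        exons=exons,
        attributes=attrs,
        source="fixture",
    )
    return model, offset


def generate_fixture(
    n_transcripts: int,
    exon_count_range: tuple[int, int] = (1, 8),
    seed: int = 0,
    scenario_mix: dict[str, float] | None = None,
    out_dir: str | Path | None = None,
    transcripts_per_contig: int = 25,
) -> Fixture:
    """Generate a genome FASTA + GTF pair with a fully known truth table.

    Deterministic given ``seed``. ``scenario_mix`` maps scenario names to
    weights; infeasible scenarios under the exon range raise immediately when
    requested explicitly and are silently dropped from the default mix.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = exon_count_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid exon_count_range {exon_count_range}")

    explicit = scenario_mix is not None
    mix = dict(scenario_mix) if explicit else dict(_DEFAULT_MIX)
    for name in mix:
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
    multi_only = {"coding_multi_nmd_false", "coding_multi_nmd_true"}
    single_only = {"coding_single"}
    infeasible = (multi_only if hi < 2 else set()) | (single_only if lo > 1 else set())
    requested_infeasible = infeasible & {k for k, v in mix.items() if v > 0}
    if explicit and requested_infeasible:
        raise ValueError(f"scenarios {sorted(requested_infeasible)} infeasible with exon_count_range={exon_count_range}")
    mix = {k: v for k, v in mix.items() if v > 0 and k not in infeasible}
    if not mix:
        raise ValueError("no feasible scenarios in the mix")
    names = sorted(mix)
    probs = np.array([mix[n] for n in names], dtype=float)
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    models, truths = [], []
    contigs: dict[str, str] = {}
    contig_parts: list[str] = []
    offset = 0
    kozak_index = 0
    chrom = "chr1"
    for i in range(n_transcripts):
        if i and i % transcripts_per_contig == 0:
            contigs[chrom] = "".join(contig_parts)
            contig_parts, offset = [], 0
            chrom = f"chr{i // transcripts_per_contig + 1}"
        scenario = names[int(rng.choice(len(names), p=probs))]
        truth = _design_transcript(rng, scenario, exon_count_range, kozak_index)
        if truth.coding:
            kozak_index += 1
        truth.transcript_id = f"tx_{i + 1}"
        truth.strand = "+" if rng.random() < 0.5 else "-"
        model, offset = _place_on_genome(rng, truth, truth.strand, chrom, contig_parts, offset)
        models.append(model)
        truths.append(truth)
    contig_parts.append("".join(rng.choice(_ACGT, size=50)))
    contigs[chrom] = "".join(contig_parts)

    fixture = Fixture(models=models, genome=InMemoryGenome(contigs), truths=truths)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fixture.genome_path = out_dir / "genome.fa"
        fixture.gtf_path = out_dir / "transcripts.gtf"
        fixture.truth_path = out_dir / "truth.tsv"
        write_fasta(sorted(contigs.items()), fixture.genome_path)
        write_transcript_models(models, fixture.gtf_path, dialect="gtf")
        _write_truth(truths, fixture.truth_path)
    return fixture


_TRUTH_COLUMNS = [
    "transcript_id",
    "scenario",
    "strand",
    "exon_count",
    "coding",
    "orf_t_start",
    "orf_t_end",
    "uorfs",
    "kozak_strength",
    "nmd_flag",
    "stop_to_last_junction",
    "utr5_length",
    "utr3_length",
    "utr5_junctions",
    "utr3_junctions",
]


def _write_truth(truths: list[FixtureTruth], path: Path) -> None:
    def cell(value) -> str:
        return "NA" if value is None else str(value)

    with open(path, "w") as out:
        out.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truths:
            row = [
                t.transcript_id,
                t.scenario,
                t.strand,
                str(t.exon_count),
                str(t.coding),
                cell(t.orf_t_start),
                cell(t.orf_t_end),
                ";".join(f"{a}-{b}" for a, b in t.uorfs),
                cell(t.kozak_strength),
                cell(t.nmd_flag),
                cell(t.stop_to_last_junction),
                cell(t.utr5_length),
                cell(t.utr3_length),
                cell(t.utr5_junctions),
                cell(t.utr3_junctions),
            ]
            out.write("\t".join(row) + "\n")


def generate_training_sets(n_per_class: int = 150, seed: int = 0) -> tuple[list[str], list[str]]:
    """Separable coding/non-coding training sequences with a planted hexamer effect.

    Coding: in-frame CDS (ATG + GC-biased sense codons + stop), stop-free in
    frame 0, so the longest ORF spans the sequence. Non-coding: AT-rich
    random sequence whose incidental ORFs are short. The composition gap
    gives the hexamer feature a real signal to learn.
    """
    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    sense = [c for c in codons if c not in ("TAA", "TAG", "TGA")]
    gc_weight = np.array([1.0 + 2.0 * (c.count("G") + c.count("C")) for c in sense])
    gc_weight /= gc_weight.sum()

    coding = []
    for _ in range(n_per_class):
        n_codons = int(rng.integers(60, 161))
        body = "".join(rng.choice(sense, size=n_codons, p=gc_weight))
        coding.append("ATG" + body + "TAA")
    noncoding = []
    at_probs = np.array([0.35, 0.15, 0.15, 0.35])
    for _ in range(n_per_class):
        length = int(rng.integers(300, 801))
        noncoding.append("".join(rng.choice(_ACGT, size=length, p=at_probs)))
    return coding, noncoding
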