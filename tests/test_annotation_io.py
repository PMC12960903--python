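"""GTF/GFF3 parsing, CDS frame computation, and faithful re-emission."""

import pytest

from orfannotate.annotate import annotate_transcript
from orfannotate.annotation_io import (
    FeatureRecord,
    TranscriptModel,
    build_feature_records,
    parse_annotation,
    write_annotation,
)
from orfannotate.genome import InMemoryGenome, open_genome

GTF_TEXT = """\
chr1\ttest\ttranscript\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
"""

GFF3_TEXT = """\
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1
chr1\ttest\texon\t101\t200\t.\t+\t.\tID=exon:t1:1;Parent=t1
chr1\ttest\texon\t301\t400\t.\t+\t.\tID=exon:t1:2;Parent=t1
"""


@pytest.mark.parametrize("text,dialect", [(GTF_TEXT, "gtf"), (GFF3_TEXT, "gff3")])
def test_parse_coordinate_conversion_and_dialect_equivalence(tmp_path, text, dialect):
    path = tmp_path / f"in.{dialect}"
    path.write_text(text)
    models = parse_annotation(path, dialect=dialect).transcripts
    assert len(models) == 1
    model = models[0]
    assert model.transcript_id == "t1"
    assert model.exons == [(100, 200), (300, 400)]
    assert model.length == 200
    assert model.strand == "+"


def test_exon_only_gtf_matches_independent_parser(tmp_path):
    """Without a transcript-level line the exon span defines the transcript;
    cross-checked against gffutils parsing the same file."""
    import gffutils

    path = tmp_path / "noheader.gtf"
    path.write_text(
        'chr2\tx\texon\t51\t90\t.\t-\t.\tgene_id "g2"; transcript_id "t2";\n'
        'chr2\tx\texon\t121\t180\t.\t-\t.\tgene_id "g2"; transcript_id "t2";\n'
    )
    model = parse_annotation(path).transcripts[0]
    assert model.span == (50, 180)

    db = gffutils.create_db(str(path), ":memory:", disable_infer_genes=True, disable_infer_transcripts=True)
    oracle_exons = sorted((f.start - 1, f.end) for f in db.features_of_type("exon"))
    assert model.exons == oracle_exons


def test_parse_drops_bad_records_and_dedups(tmp_path, caplog):
    path = tmp_path / "messy.gtf"
    path.write_text(
        'chr1\tx\texon\t10\t5\t.\t+\t.\tgene_id "g"; transcript_id "bad_interval";\n'
        'chr1\tx\texon\t10\t50\t.\t.\t.\tgene_id "g"; transcript_id "bad_strand";\n'
        'chr1\tx\texon\t10\t50\t.\t+\t.\tgene_id "g"; transcript_id "dup";\n'
        'chr1\tx\texon\t10\t50\t.\t+\t.\tgene_id "g"; transcript_id "dup";\n'
    )
    result = parse_annotation(path)
    assert [m.transcript_id for m in result.transcripts] == ["dup"]
    assert result.transcripts[0].exons == [(9, 50)]  # 1-based 10..50 -> 0-based half-open
    assert result.n_dropped == 2
    assert any("dedup" in w for w in result.warnings)


def test_parse_missing_file_is_fatal(tmp_path):
    with pytest.raises(OSError):
        parse_annotation(tmp_path / "nope.gtf")


class _FakeAnnotation:
    def __init__(self, coding, cds, utr5=(), utr3=()):
        self.coding = coding
        self.cds_blocks = list(cds)
        self.utr5_blocks = list(utr5)
        self.utr3_blocks = list(utr3)


def _model(strand="+", exons=((100, 200), (300, 400))):
    return TranscriptModel("t1", "g1", "chr1", strand, list(exons))


@pytest.mark.parametrize(
    "cds_blocks,expected_frames",
    [
        ([(110, 122)], [0]),  # single block always frame 0
        ([(100, 200), (300, 320)], [0, 2]),  # first block 100 nt -> (3 - 100%3)%3 = 2
        ([(100, 200), (300, 301)], [0, 2]),
    ],
)
def test_cds_frame_accumulates_in_transcript_order(cds_blocks, expected_frames):
    ann = _FakeAnnotation(True, cds_blocks)
    records = build_feature_records(_model(), ann)
    assert [r.frame for r in records] == expected_frames
    assert all(r.feature_type == "CDS" for r in records)


def test_minus_strand_frames_start_at_high_coordinate_block(fixture50, ld_scorer):
    """On '-', frame accumulation follows transcript order: applying each
    block's frame shift and translating the concatenation must give a
    stop-free protein for every planted multi-block CDS."""
    from Bio.Seq import Seq, reverse_complement

    genome = open_genome(fixture50.genome_path)
    checked = 0
    for model in fixture50.models:
        if model.strand != "-" or not fixture50.truth_of(model.transcript_id).coding:
            continue
        ann = annotate_transcript(model, genome, ld_scorer)
        if not ann.coding or len(ann.cds_blocks) < 2:
            continue
        records = build_feature_records(model, ann)
        cds_records = [r for r in records if r.feature_type == "CDS"]
        spliced = "".join(
            reverse_complement(genome.fetch(r.chrom, r.start, r.end)) for r in cds_records
        )
        assert cds_records[0].start > cds_records[-1].start  # transcript order = descending genomic
        protein = str(Seq(spliced[: len(spliced) - 3]).translate())
        assert "*" not in protein
        checked += 1
    assert checked > 0


def test_noncoding_yields_no_records():
    assert build_feature_records(_model(), _FakeAnnotation(False, [])) == []


def test_unordered_blocks_raise():
    with pytest.raises(ValueError):
        build_feature_records(_model(strand="-"), _FakeAnnotation(True, [(100, 150), (300, 350)]))


def test_feature_record_frame_contract():
    with pytest.raises(ValueError):
        FeatureRecord("chr1", "x", "CDS", 0, 9, "+", ".")
    with pytest.raises(ValueError):
        FeatureRecord("chr1", "x", "exon", 0, 9, "+", 0)
    with pytest.raises(ValueError):
        FeatureRecord("chr1", "x", "exon", 9, 9, "+")


@pytest.mark.parametrize("dialect", ["gtf", "gff3"])
def test_round_trip_identity(tmp_path, fixture50, dialect):
    """parse(write(parse(X))) == parse(X): exon structures, strands, ids."""
    from orfannotate.annotation_io import write_transcript_models

    first_path = tmp_path / f"first.{dialect}"
    write_transcript_models(fixture50.models, first_path, dialect=dialect)
    first = parse_annotation(first_path)

    out_path = tmp_path / f"rt.{dialect}"
    write_annotation(first, {}, out_path)
    second = parse_annotation(out_path)

    assert len(first.transcripts) == len(second.transcripts) == len(fixture50.models)
    for a, b in zip(first.transcripts, second.transcripts):
        assert (a.transcript_id, a.gene_id, a.chrom, a.strand, a.exons) == (
            b.transcript_id,
            b.gene_id,
            b.chrom,
            b.strand,
            b.exons,
        )
    assert out_path.read_text() == first_path.read_text()


def test_annotated_output_retains_inputs_and_inserts_by_class(tmp_path, fixture50, ld_scorer):
    genome = open_genome(fixture50.genome_path)
    parsed = parse_annotation(fixture50.gtf_path)
    inserted = {}
    coding_ids, noncoding_ids = set(), set()
    for model in parsed:
        ann = annotate_transcript(model, genome, ld_scorer)
        if ann.coding:
            inserted[model.transcript_id] = build_feature_records(model, ann)
            coding_ids.add(model.transcript_id)
        else:
            noncoding_ids.add(model.transcript_id)
    out_path = tmp_path / "annotated.gtf"
    write_annotation(parsed, inserted, out_path)
    out_lines = out_path.read_text().splitlines()

    # every original line appears verbatim
    for line in parsed.lines:
        assert line in out_lines
    for tid in coding_ids:
        cds = [l for l in out_lines if f'transcript_id "{tid}"' in l and l.split("\t")[2] == "CDS"]
        assert cds, tid
    for tid in noncoding_ids:
        added = [
            l
            for l in out_lines
            if f'transcript_id "{tid}"' in l
            and l.split("\t")[2] in ("CDS", "five_prime_utr", "three_prime_utr")
        ]
        assert not added, tid

    # structural invariants of the inserted records
    by_id = {m.transcript_id: m for m in parsed}
    for tid, records in inserted.items():
        model = by_id[tid]
        assert sum(r.end - r.start for r in records if r.feature_type == "CDS") % 3 == 0
        for rec in records:
            assert any(e_start <= rec.start and rec.end <= e_end for e_start, e_end in model.exons)
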