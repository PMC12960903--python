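# orfannotate

GTF-native ORF prediction and exon-aware CDS/UTR annotation for transcript
models.

Transcriptome assemblers for long-read RNA-seq (Bambu, FLAIR, IsoQuant,
StringTie2, TALON) and reference annotations deliver transcript models as
GTF/GFF3, but most ORF predictors want transcript FASTA and leave it to the
user to map predicted coding regions back onto exon structures. `orfannotate`
works directly on the annotation: it reconstructs each spliced transcript
from the genome, predicts AUG-initiated open reading frames, scores them
with a CPAT-style coding-potential classifier, reinserts junction-aware CDS
and UTR features into the original GTF/GFF3 (with correct reading-frame
columns, ready for genome browsers and tools like ggtranscript), and
consolidates the translational context of every transcript into one summary
table. It is aimed at anyone annotating assembled transcriptomes — bulk or
single-cell, long- or short-read — who needs to know not just *whether* a
transcript codes, but *how* it is likely to be translated.

## What is computed

For each transcript, all complete ORFs (ATG through the first in-frame stop,
stop codon included) are enumerated on the sense strand. Each candidate ORF
*o* in transcript *t* gets four features

- ORF length `L(o)` (entering the model as `ln L`),
- ORF coverage `L(o) / L(t)`,
- Fickett TESTCODE score of the transcript sequence (positional base
  asymmetry + composition, via the published lookup tables),
- hexamer usage bias: the mean over in-frame hexamers of
  `ln f_coding(h) / f_noncoding(h)`,

combined by a logistic model `P(coding) = σ(β₀ + βᵀx)` that is trainable
from coding/non-coding FASTA sets and serializes to JSON. The
highest-probability ORF is the primary ORF; the transcript is classified
coding when its probability reaches the cutoff (recommended species cutoffs:
human 0.364, mouse 0.44, fly 0.39, zebrafish 0.38, from the CPAT
documentation; overridable).

For coding transcripts, `orfannotate` then annotates:

- **CDS / UTR features** — the primary ORF projected through the exon
  structure into genomic blocks, with GTF frame computed cumulatively in
  transcript order; 5′/3′ UTR blocks likewise.
- **Kozak context** — the −6…+4 window around the start codon, classified
  strong / moderate / weak by the purine-at-−3 and G-at-+4 determinants.
- **uORFs** — upstream ORFs lying entirely 5′ of the primary start, kept
  when their coding probability exceeds a minimum cutoff.
- **NMD susceptibility** — the 50-nt rule: a stop codon strictly more than
  50 nt upstream of the final exon–exon junction flags the transcript.
- **UTR structure** — 5′/3′ UTR lengths and exon–exon junction counts.

## Worked example

Generate a small synthetic genome + GTF (bundled generator), train a model
on synthetic coding/non-coding sets, and annotate:

```sh
python - <<'EOF'
from orfannotate import fixtures
from orfannotate.summary import write_fasta
fx = fixtures.generate_fixture(30, seed=3, out_dir=".")
c, n = fixtures.generate_training_sets(80, seed=3)
write_fasta([(f"c{i}", s) for i, s in enumerate(c)], "coding.fa")
write_fasta([(f"n{i}", s) for i, s in enumerate(n)], "noncoding.fa")
EOF
orfannotate train --coding coding.fa --noncoding noncoding.fa --out-model model.json --seed 3
orfannotate annotate --gtf transcripts.gtf --genome genome.fa \
    --model model.json --out out1 --uorf-min-prob 0.01
```

The run prints its counts (`"parsed": 30, "coding": 25, "noncoding": 5`) and
writes `out1/` with the annotated GTF, `summary.tsv`, `cds.fa`,
`protein.fa`, `utr5.fa`, `utr3.fa`, `orfs.fa` (top-N candidates per
transcript) and `run.log`. The first summary rows:

```
transcript_id  strand  transcript_length  orf_t_start  orf_t_end  coding_prob  coding_class  kozak_context  kozak_strength  nmd_flag  utr5_length  utr3_length  ...
tx_1           -       177                26           143        1.0000       coding        CTGGGCATGG     strong          False     26           34
tx_2           -       598                NA           NA         NA           noncoding     NA             NA              NA        NA           NA
```

`tx_1` codes (probability 1.0000): its ORF occupies transcript positions
26–143, the Kozak context `CTGGGC·ATG·G` is strong (G at −3, G at +4), and
the stop codon is not far enough upstream of the last junction to trigger
the NMD flag. The annotated GTF gains exon-aware records for it — note the
frame column accumulating along the minus strand from the
highest-coordinate CDS block:

```
chr1  orfannotate  CDS             521  548  .  -  0  gene_id "gene_1"; transcript_id "tx_1";
chr1  orfannotate  CDS             406  416  .  -  2  gene_id "gene_1"; transcript_id "tx_1";
chr1  orfannotate  CDS             331  362  .  -  0  gene_id "gene_1"; transcript_id "tx_1";
...
chr1  orfannotate  five_prime_utr  549  574  .  -  .  gene_id "gene_1"; transcript_id "tx_1";
chr1  orfannotate  three_prime_utr 156  161  .  -  .  gene_id "gene_1"; transcript_id "tx_1";
```

All original input lines are preserved byte-for-byte; non-coding
transcripts (`tx_2`) gain no CDS/UTR lines and appear in no sequence
export.

Library use mirrors the CLI:

```python
from orfannotate import open_genome, parse_annotation, annotate_transcript
from orfannotate.scoring import CodingModel

genome = open_genome("genome.fa")
model = CodingModel.from_json("model.json")
for tx in parse_annotation("transcripts.gtf"):
    ann = annotate_transcript(tx, genome, model)
    if ann.coding:
        print(tx.transcript_id, ann.primary.coding_prob, ann.kozak.strength, ann.nmd.flagged)
```

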