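# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF/GFF3 serialization is
1-based inclusive, converted only at the I/O boundary. Transcript space runs
5′→3′ along the spliced transcript. A `CoordinateMap` lists
(transcript-interval ↔ genomic-interval) block pairs in transcript order; on
the minus strand the first block maps to the highest-coordinate exon and a
transcript position `p` within a block `[ts,te) ↔ [gs,ge)` maps to genomic
base `ge − 1 − (p − ts)`. Projection splits a transcript interval at every
block boundary, so total genomic length always equals transcript length;
this is what makes the inserted CDS/UTR features exon-aware.

## ORF model

An ORF is an ATG followed by the first in-frame stop codon, both inside the
transcript; the interval includes the stop. Only complete ORFs are called —
3′-truncated ORFs are skipped, because the downstream annotations (NMD, 3′
UTR) are defined relative to the stop. Codons containing N never match ATG
or a stop, so unknown genomic sequence cannot create a call. Candidates
sharing a stop but differing in start are distinct; this is required for
uORF detection and the ranking tie-break (probability desc, then longer ORF,
then smaller start) naturally prefers the 5′-most of equally scoring
sharers.

**CDS convention.** The emitted CDS includes the stop codon; the 3′UTR
begins immediately after it, and no separate `start_codon`/`stop_codon`
features are written (TransDecoder-style output; one unambiguous
convention). The GTF frame of a CDS block is
`(3 − (cumulative CDS nt 5′ of the block mod 3)) mod 3`, accumulated in
transcript order — on the minus strand that means starting from the block
with the largest genomic coordinate.

## Coding-potential scorer

Four features per candidate feed a logistic model:

| feature | computed on | default weight source |
|---|---|---|
| ln ORF length (nt) | ORF | fitted |
| ORF coverage ∈ (0,1] | ORF / transcript | fitted |
| Fickett TESTCODE | full transcript sequence | fitted |
| hexamer log-ratio mean | ORF, in-frame step 3 | fitted |

The Fickett statistic uses the published position-asymmetry and composition
lookup tables; N bases are excluded from both counts. Hexamer tables are
built with frame-0, step-3 counting on coding CDS and all-offset, step-1
counting on non-coding sequences, with a pseudo-count of 1 per hexamer per
class before normalization (so all 4096 log-ratios are finite and each
class's frequencies sum to 1). Hexamers containing N are skipped; an ORF
shorter than 6 nt, or with every hexamer skipped, scores 0. Natural log is
used throughout.

Training (`train_model`) extracts each training sequence's longest complete
ORF, and fits the logistic layer by maximum likelihood (near-unpenalized,
lbfgs); it is deterministic for fixed inputs and seed. Models serialize to a
single JSON file (coefficients, cutoff, both hexamer frequency vectors) and
round-trip bit-exactly.

Classification is `coding ⇔ P ≥ cutoff`; the boundary counts as coding
(documented choice). Recommended species cutoffs (human 0.364, mouse 0.44,
fly 0.39, zebrafish 0.38) are adopted from the CPAT documentation and are
overridable per run; no species model files ship with the package — models
are trained from user-supplied FASTA sets (`orfannotate train`), and a
deterministic demonstration model trained on the synthetic sets is built on
demand for tests and examples. CPAT's own serialized models are not read.

`CodingModel.length_dominant()` is a degenerate diagnostic scorer whose
probability is `L/(L + 100)` (cutoff 0.35). It exists so structural tests
can verify coordinate and annotation logic with a scorer whose ranking is
fully predictable; it is not a realistic classifier.

## Translational context

- **Kozak**: context is the 10-mer covering positions −6…−1, the ATG, and
  +4, N-padded where the transcript ends. Strength uses only the canonical
  determinants: purine at −3 and G at +4 — both ⇒ strong, exactly one ⇒
  moderate, neither ⇒ weak. N satisfies neither condition, so a start codon
  at position < 3 can be at best moderate. The exact strong/moderate/weak
  rule at these two positions is a documented design choice.
- **NMD**: positional rule only. Distance = last junction position − ORF
  end (3′ end of the stop), in transcript coordinates; flagged iff
  distance > 50 nt, strict (the 50–55 nt range in the literature is resolved
  to the strict-50 form). Single-exon transcripts are never flagged. The
  threshold is configurable (`nmd_threshold_nt`).
- **UTR metrics**: `utr5 = orf_start`, `utr3 = length − orf_end`; a
  junction exactly at the ORF start counts as a 5′UTR junction, exactly at
  the ORF end as a 3′UTR junction, strictly inside the CDS as neither
  (boundary junctions assigned to the adjacent UTR; one documented
  convention — the conservation identity utr5 + ORF + utr3 = transcript
  length holds regardless).
- **uORFs**: entirely upstream (`end ≤ primary start`); overlapping
  upstream ORFs (oORFs) are not reported. Retained when probability
  strictly exceeds `uorf_min_prob` (default 0.5) and length ≥ 9 nt
  including the stop — one codon beyond ATG, excluding degenerate
  ATG-stop dipeptides (configurable).
- **Translation**: standard genetic code (table 1), terminal stop excluded
  from the protein, codons containing N emit X; an internal in-frame stop
  is an internal-consistency error.

## Pipeline behaviour and defaults

| parameter | default | meaning |
|---|---|---|
| `n_top` | 5 | candidates kept per transcript in the ORF FASTA |
| `coding_cutoff` | model's own | classification threshold override |
| `uorf_min_prob` | 0.5 | minimum uORF coding probability (strict) |
| `min_uorf_length_nt` | 9 | minimum uORF length incl. stop |
| `nmd_threshold_nt` | 50 | NMD distance rule |
| `dialect` | auto | GTF/GFF3 sniffed from suffix, then column-9 syntax |

CLI flags override `config.json` values, which override defaults. The run is
a single-process stream over transcripts; the seed affects model training
only, so annotation is bit-reproducible (two identical runs produce
byte-identical outputs). Transcripts on contigs absent from the genome, with
invalid exon intervals, or with unknown strand are dropped with a logged
warning and counted in the run report — never fatal. Duplicate exon lines
are deduplicated with a warning. Output files preserve every input line
verbatim and group inserted records immediately after their transcript's
original lines.

Degenerate inputs: an empty annotation yields header-only outputs and exit
0; an empty exon set, a 5′UTR shorter than 6 nt (padded Kozak), an ORF
spanning the whole transcript (both UTRs empty, omitted from the UTR
FASTAs) are all defined cases exercised by tests.

## Synthetic fixtures: what they emulate and what they do not

Fixtures are built transcript-first: 5′UTR + planted primary ORF + 3′UTR,
with the Kozak −3/+4 bases, uORF placement, and the stop-to-last-junction
distance chosen to force known truth values, then split into 1–8 exons and
embedded on contigs (reverse-complemented in reversed exon order on the
minus strand). Unplanted regions are drawn from a {C,G,T} alphabet and
planted elements end with TAG, which together guarantee — by a boundary
analysis of the ATG/TAG motifs, and re-checked at generation time — that the
planted ORFs are the *only* AUG-initiated ORFs in the transcript. Truth
tables are therefore derived from the construction, never from the pipeline.

The default scenario mix (15% ATG-free non-coding, 5% non-coding with a
short 15-nt ORF, 20% single-exon coding, 25% multi-exon NMD-negative, 20%
multi-exon NMD-positive with planted distance 51–80 nt, 15% coding with 1–2
uORFs of 9–30 nt) fixes primary ORFs at 90–240 nt, 5′UTRs at 10–80 nt and
3′UTRs at 20–100 nt — compact but structurally representative genes chosen
so every annotation path (both strands, 1–8 exons, all Kozak classes, both
NMD outcomes) is exercised. Truth recovery is asserted under the
length-dominant scorer, making it a test of coordinate, enumeration and
rule logic, not of the statistical classifier.

What the fixtures do **not** emulate: realistic exon length/number
distributions, splice-site motifs, genuine codon usage or hexamer
composition, non-AUG initiation, overlapping genes, or sequencing/assembly
noise. Passing the recovery tests shows the machinery is exact on known
structures; it says nothing about classifier accuracy on real organisms,
which depends entirely on the training sets supplied.

The classifier's own recovery test uses separate synthetic training sets
with a planted composition gap (GC-rich stop-free CDS vs AT-rich random
sequence, 120 + 120 training, 50 + 50 held-out); this verifies the
training/serialization path and that the features separate a separable
problem — not real-world performance.

## Problem sizes and numerical choices

Tests and the acceptance script run on 500-transcript fixtures, 1000
projection intervals and 200 oracle sequences (≤ 2 kb) — sizes chosen so the
whole suite completes in seconds while covering every scenario class
multiple times; the pipeline itself streams and has been exercised unchanged
on larger generated inputs. There is no floating-point tolerance anywhere in
the core: coordinates are exact integers, sequence checks are exact string
equality, and serialization round-trips are compared bit-exactly. The only
stochastic component, logistic training, fixes its seed and uses a large-C
(near-unpenalized) lbfgs fit.

## Known limitations

Non-AUG start codons, stop-codon readthrough and frameshifts are out of
scope. GFF3 multi-parent exons are resolved to their first parent with a
warning; phase semantics beyond the CDS frame column are not modelled. NMD
prediction is the positional rule only — no EJC composition, no long-3′UTR
sensing. Kozak scoring applies to the primary ORF only. Species cutoff
defaults are classifier-dependent recommendations, not measurements made by
this package.
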