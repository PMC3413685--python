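# Methods

This note records the models, parameter choices and numerical decisions
behind `btdpipe`, and what the synthetic experiments do and do not show.

## The synthetic study

The generator (`simdata`) emulates the statistical structure a short-read
transcriptome pipeline must handle, not any particular organism's gene
catalogue.

**Transcripts.** Each gene is a 5′ UTR (20–80 nt), an ATG-initiated CDS of
120–400 stop-free codons, a stop codon and a 3′ UTR. With probability
`isoform_probability` (default 0.2, up to three extras) a gene gains splice
isoforms by skipping one internal codon-aligned exon block (blocks ≥ 40
codons, so flanking shared sequence always exceeds the largest assembly k
of 41). This produces exactly the bubble structures the isotig builder must
resolve.

**Expression** is lognormal (σ = 1.2, median 1), giving the wide dynamic
range of real RNA-seq and driving the completeness–coverage relation below.

**Reads** are 90-bp pairs (insert 250 ± 25 nt), fragment counts multinomial
in expression × length. Per-base substitution errors default to 0.5 % —
a realistic figure for the Illumina GA era this kind of data comes from;
the error rate is a free parameter of the generator, not a literature
constant. Adapter contamination (1 % of fragments) is modelled as a
fragment shorter than the read, so the read runs into a configurable
adapter; `N` events (0.2 % of reads) mask one position. Qualities decay
from ~Q40 at the 5′ end to ~Q26 at the 3′ end with σ = 2 noise, matching
the 5′-window semantics of the read filter. Rates are read- or
fragment-level event probabilities; the calibration tests check observed
frequencies against them at 3 standard errors.

**Protein database.** One entry per gene: the longest-ORF translation with
uniform random substitutions bringing identity to a target (default 75 %).
Note the longest ORF may extend 5′ of the designed CDS when the UTR happens
to contain an in-frame ATG without an intervening stop; truth comparisons
therefore use the longest-ORF translation, not the designed CDS.

**What the generator does not model:** realistic Illumina error spectra
(position/context dependence), GC bias, intron retention, chimeric
fragments, or any real gene catalogue. Passing tests therefore demonstrate
algorithmic correctness under controlled conditions, not performance on
real libraries.

**Tiling reads.** `tile_reads` emits deterministic error-free reads whose
starts advance by `read_length // depth`. Random fragmentation at 30×
leaves transcript *ends* uncovered with high probability (a fragment must
start at position 0 for base 0 to be read), which makes exact end-to-end
reconstruction the wrong yardstick for multinomial reads; tiling preserves
the stated depth while making exact recovery a meaningful outcome. The
reconstruction experiment uses tiling reads for exactly this reason.

## Read filtering

A read passes iff ≥ 25 of its first 35 quality scores are strictly greater
than 30 (strict on 30, inclusive on 25), it contains no `N`, and no
configured adapter occurs as an exact substring (forward orientation).
Reads shorter than the 35-nt window are rejected — the rule is undefined
for them and the target data are uniform 90-mers. Input FASTQ is Phred+33
(+64 available for legacy data). Orphan mates whose partner fails are kept
as singles, matching assemblers that accept mixed paired/single input. The
rejection tally attributes each dropped read to its first failing rule
(quality, then N, then adapter).

## Assembly

K-mers are canonical (lexicographic minimum of k-mer and reverse
complement); k must be odd so no k-mer is its own reverse complement.
Contigs are maximal unbranched paths, each reported once in canonical
orientation; iteration over sorted k-mers makes the output independent of
read order and strand. `min_count` defaults to 1 in the library (the raw
graph); the pipeline sets 2, since with ≥ 10× simulated coverage a
singleton k-mer is almost surely a sequencing error, and error branches
otherwise fragment the path enumeration.

Isotigs: the contig graph doubles each contig into two oriented nodes with
(k−1)-overlap edges. An isogroup is a connected component; its isotigs are
source-to-sink simple paths, deduplicated up to reverse complement, ranked
by length-weighted mean k-mer coverage and capped at 16 per isogroup
(configurable; a warning reports truncation — chains of b bubbles yield 2^b
paths and bounded enumeration replaces transitive-reduction machinery).
Cyclic components fall back to emitting their contigs. Without read-pair
constraints, multi-bubble components legitimately enumerate recombined
paths that no true isoform follows; this is an accepted property of the
bounded enumeration, not a defect, and single-bubble components resolve
exactly.

N50 is the largest L such that sequences of length ≥ L contain at least
half of all assembled bases; the average length is an integer floor.

## Homology

Translated search aligns all six frames with exact Smith–Waterman under
BLOSUM62, gap open 11, extend 1 (a gap of length L costs 11 + L).
Significance uses the ungapped Karlin–Altschul parameters (λ = 0.318,
K = 0.13) applied to gapped scores as the conventional approximation, with
n the total residue count of the database, so the E < 10⁻⁵ threshold
behaves like a database-search E-value. A hit must exceed 60 aligned
columns (strict). Ties on E break by higher score, then lexicographic
subject id. A 5-mer word index skips subjects sharing no word with the
query — at ≥ 70 % identity over > 60 aa the expected number of shared
5-mers is far above zero, so the prefilter does not change results at the
identities the thresholds admit, while keeping the search near-linear.

The multi-k merge processes k values by ascending |k − base| (ties: lower
k first), which is declared, configurable, and only affects *which* isotig
represents a new subject, never the merged subject set (an invariant the
tests check against a set-union oracle).

Poly-N gap checking splits an isotig at N-runs and requires all segments'
best homologue to be one protein with subject starts monotone in segment
order (increasing for forward-frame hits, decreasing for reverse).

The target-site scan is translated query × translated reference (36 frame
pairs), reporting the best HSP per (reference, isotig) pair; identity is
per-HSP. Sub-threshold best identities are reported with a flag so near
misses stay visible.

## Annotation

Motif patterns: uppercase letters are fixed residues, `x` any single
residue, `x(m,n)` a flexible gap, `-` cosmetic. Matching is backtracking
over the parsed elements; wildcards and gaps never match `*`, so a match
cannot span a stop codon. All (overlapping) start positions are reported.
The matcher is deliberately independent of the regex engine; tests compare
it against a regex transcription of each pattern.

EC prediction takes the EC of the minimum-E enzymatic hit. Hits within a
10× E-value factor of the best (the declared "no clear ranking" criterion;
configurable) that disagree on EC invoke the motif step: if exactly one
competing EC's signature matches any six-frame translation, it wins
(`motif_confirmed`); zero or several matches leave the minimum-E choice
flagged unresolved with competitors listed.

Deduplication keeps, per (EC group, shared nearest homologue), the
highest-coverage isotig (ties: longer isotig, then id). Gene collapsing
groups predictions by nearest homologue; within a group, subject spans
with reciprocal overlap > 20 % are isoform candidates (one transcript
unit), mutually non-overlapping spans are fragments (several units, one
gene). The 20 % threshold stops near-zero accidental overlaps from
splitting genes while keeping genuinely disjoint fragments separate.
Family labels come from a user-supplied annotation of the enzyme database,
not from phylogenetics.

## Coverage and completeness

Mapping is exact-seed (20-mers at three offsets per orientation) plus
gap-free verification at ≥ 95 % identity over the fully contained read;
each read gets one best placement (fewest mismatches, ties broken by
strand, isotig id, position), contributing +1 to every covered base. Total
depth therefore equals mapped reads × read length exactly.

Completeness defaults to aligned subject-span length over subject protein
length (aa/aa, capped at 1) — unit-consistent and bounded; the
whole-isotig variant (isotig nt/3 over subject aa) is available via a
flag. Bins are left-closed, right-open, ten points wide, with 1.0 in the
top bin.

The completeness–coverage experiment (500 genes, 20 000 fragments,
k = 31) puts mean depth near 10× so that, under the lognormal expression
law, completeness actually spans its range: poorly expressed genes
fragment, well expressed ones assemble fully. The monotone rise of median
coverage with completeness bin is the qualitative claim the experiment
reproduces; at saturating depth nearly all genes complete and the low bins
are too sparse to order reliably.

## Pipeline

All thresholds live in one configuration object with their conventional
defaults (window 35 / ≥ 25 / Q30; > 60 aa; E < 10⁻⁵; mRNA identity 95 %
and coverage 80 %; target-site identity 90 %; k odd 21–41 with base 31)
and can be overridden from YAML. The synthetic study labels 40 % of genes
as enzymes (cycling through EC 1.14.14.1, 2.5.1.18, 3.1.1.1, 3.1.1.7) and
plants the matching signature motif in their CDS; target-site references
are 3 %-diverged copies of designated transcripts, standing in for genes
of a closely related species. The manifest records input hashes,
thresholds and per-stage counts and is byte-identical across reruns.

Problem sizes in the bundled experiments (15-gene pipeline run, 200
transcripts for reconstruction, 500 genes for the coverage relation) are
the package's own desk-scale choices: large enough for stable statistics,
small enough to run anywhere.

## Known limitations

- No quality trimming or adapter clipping — reads are filtered whole.
- The assembler has no expected-coverage estimation, scaffolding, or
  pair-aware path selection; tip clipping and bubble popping are off by
  default.
- E-values use ungapped Karlin–Altschul parameters on gapped scores; only
  threshold behaviour, not BLAST-exact E-values, is preserved.
- The read mapper requires full containment and gap-free placements; reads
  spanning indels or isotig ends go unmapped.
- Six-frame motif matching may fire on a frame other than the coding one;
  with short signatures this is rare but possible.
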