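"""Synthetic transcriptomes, reads and protein databases for pipeline testing.

The generator emulates the statistical structure a short-read
transcriptome pipeline has to cope with: a catalogue of genes with
optional splice isoforms (internal exon-block skipping), lognormal
expression, ~90-bp paired reads with position-dependent Phred qualities,
read-level adapter/N contamination, enzyme motifs planted in coding
regions, and a homologue protein database whose entries are diverged
copies of the true translations at a controlled identity.  Every record
carries its ground truth so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .annotate import MotifPattern, parse_motif
from .readqc import SequencedRead

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
NONSTOP_CODONS = [c for c in _CODONS if c not in STOP_CODONS]
# synonymous codons per residue, for back-translation
CODONS_FOR: dict[str, list[str]] = {}
for _c in NONSTOP_CODONS:
    CODONS_FOR.setdefault(str(Seq(_c).translate()), []).append(_c)

DEFAULT_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"


@dataclass(frozen=True)
class TranscriptModel:
    """One simulated transcript (splice isoform) with its ground truth."""

    gene_id: str
    isoform_id: str
    sequence: str
    expression: float
    cds_start: int
    cds_end: int  # half-open; includes the stop codon
    planted_motifs: tuple = ()  # (pattern_raw, protein_offset) pairs

    @property
    def protein(self) -> str:
        """Translation of the CDS, stop codon trimmed."""
        return str(Seq(self.sequence[self.cds_start : self.cds_end]).translate())[:-1]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    read1: SequencedRead
    read2: SequencedRead
    origin_isoform: str
    origin_start: int  # fragment start on the transcript (forward strand)
    origin_insert: int  # fragment length


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Expression follows a lognormal law (wide dynamic range, as in real
    RNA-seq); error/adapter/N rates are read- or base-level event
    probabilities.  ``read_length`` defaults to the 90-bp short reads the
    pipeline targets.
    """

    n_genes: int = 50
    isoform_probability: float = 0.2
    read_length: int = 90
    insert_size_mean: float = 250.0
    insert_size_sd: float = 25.0
    expression_mu: float = 0.0
    expression_sigma: float = 1.2
    error_rate: float = 0.005  # per base
    adapter_rate: float = 0.01  # per fragment
    n_rate: float = 0.002  # per read
    adapter: str = DEFAULT_ADAPTER
    n_fragments: int = 10_000
    cds_codons_min: int = 120
    cds_codons_max: int = 400
    utr_min: int = 20
    utr_max: int = 80
    min_orf_aa: int = 60
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        for name in ("isoform_probability", "error_rate", "adapter_rate", "n_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.insert_size_mean < self.read_length:
            raise ValueError("insert size mean below read length (overlapping mates)")


# ---------------------------------------------------------------------------
# Transcriptome generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n)
    return [NONSTOP_CODONS[i] for i in idx]


def generate_transcriptome(config: SimConfig) -> list[TranscriptModel]:
    """Generate ``n_genes`` genes, each with one isoform plus extras with
    probability ``isoform_probability`` (internal exon-block skipping).

    Deterministic for a fixed config (including seed).
    """
    config.validate()
    if config.n_genes <= 0:
        if config.n_genes == 0:
            return []
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptModel] = []
    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        n_codons = int(rng.integers(config.cds_codons_min, config.cds_codons_max + 1))
        body = _random_codons(rng, n_codons)  # codons between ATG and stop
        stop = STOP_CODONS[int(rng.integers(0, 3))]
        utr5 = _random_seq(rng, int(rng.integers(config.utr_min, config.utr_max + 1)))
        utr3 = _random_seq(rng, int(rng.integers(config.utr_min, config.utr_max + 1)))
        # codon-aligned exon blocks >= 20 codons each, so flanks exceed any k
        n_blocks = max(1, min(5, n_codons // 40))
        bounds = np.linspace(0, n_codons, n_blocks + 1).astype(int)
        blocks = [body[bounds[i] : bounds[i + 1]] for i in range(n_blocks)]

        def assemble(kept_blocks: list[list[str]]) -> tuple[str, int, int]:
            cds = "ATG" + "".join("".join(b) for b in kept_blocks) + stop
            seq = utr5 + cds + utr3
            return seq, len(utr5), len(utr5) + len(cds)

        seq, cs, ce = assemble(blocks)
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                isoform_id=f"{gene_id}.1",
                sequence=seq,
                expression=float(rng.lognormal(config.expression_mu, config.expression_sigma)),
                cds_start=cs,
                cds_end=ce,
            )
        )
        iso = 2
        while n_blocks >= 3 and rng.random() < config.isoform_probability and iso <= 4:
            skip = int(rng.integers(1, n_blocks - 1))  # internal block only
            kept = [b for i, b in enumerate(blocks) if i != skip]
            seq, cs, ce = assemble(kept)
            transcripts.append(
                TranscriptModel(
                    gene_id=gene_id,
                    isoform_id=f"{gene_id}.{iso}",
                    sequence=seq,
                    expression=float(rng.lognormal(config.expression_mu, config.expression_sigma)),
                    cds_start=cs,
                    cds_end=ce,
                )
            )
            iso += 1
    return transcripts


# ---------------------------------------------------------------------------
# Read simulation


def _quality_profile(rng: np.random.Generator, length: int) -> list[int]:
    # high 5' scores decaying toward the 3' end, with mild noise
    pos = np.arange(length)
    base = 40.0 - 14.0 * pos / max(1, length - 1)
    q = np.clip(np.rint(base + rng.normal(0.0, 2.0, size=length)), 2, 40)
    return [int(x) for x in q]


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        alternatives = [b for b in NUCLEOTIDES if b != arr[i]]
        arr[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_reads(
    transcripts: list[TranscriptModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """Draw paired 90-bp reads, fragments multinomial in expression x length.

    Each pair records its true origin (isoform, fragment start, insert
    size).  Adapter-bearing pairs come from fragments shorter than the
    read length (the read runs into the adapter); N-bearing reads get one
    position masked.  Sequencing errors are uniform substitutions.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    weights = np.array([t.expression * len(t) for t in transcripts], dtype=float)
    counts = rng.multinomial(config.n_fragments, weights / weights.sum())
    pairs: list[ReadPair] = []
    idx = 0
    for t, n in zip(transcripts, counts):
        L = len(t)
        for _ in range(int(n)):
            with_adapter = rng.random() < config.adapter_rate
            if with_adapter:
                insert = int(rng.integers(rl // 2, rl))
            else:
                insert = int(np.clip(round(rng.normal(config.insert_size_mean, config.insert_size_sd)), rl, L))
            start = int(rng.integers(0, L - insert + 1))
            frag = t.sequence[start : start + insert]
            if with_adapter:
                tail = (config.adapter * math.ceil(rl / max(1, len(config.adapter))))
                b1 = frag + tail[: rl - insert]
                b2 = str(Seq(frag).reverse_complement()) + tail[: rl - insert]
            else:
                b1 = frag[:rl]
                b2 = str(Seq(frag[-rl:]).reverse_complement())
            b1 = _mutate(rng, b1, config.error_rate)
            b2 = _mutate(rng, b2, config.error_rate)
            reads = []
            for mate, bases in ((1, b1), (2, b2)):
                if config.n_rate > 0 and rng.random() < config.n_rate:
                    p = int(rng.integers(0, len(bases)))
                    bases = bases[:p] + "N" + bases[p + 1 :]
                reads.append(
                    SequencedRead(
                        read_id=f"frag{idx:07d}/{mate}",
                        mate=mate,
                        bases=bases,
                        qualities=_quality_profile(rng, len(bases)),
                    )
                )
            pairs.append(ReadPair(reads[0], reads[1], t.isoform_id, start, insert))
            idx += 1
    return pairs


def tile_reads(
    transcripts: list[TranscriptModel], read_length: int = 90, depth: int = 30
) -> list[SequencedRead]:
    """Deterministic error-free single-end reads tiling each transcript.

    Read starts advance by ``read_length // depth`` so every base —
    including the transcript ends — is covered at approximately ``depth``.
    Used for assembly-correctness experiments where exact end-to-end
    reconstruction is the measured outcome.
    """
    stride = max(1, read_length // depth)
    reads: list[SequencedRead] = []
    for t in transcripts:
        last = len(t) - read_length
        if last < 0:
            continue
        starts = list(range(0, last + 1, stride))
        if starts[-1] != last:
            starts.append(last)
        for j, s in enumerate(starts):
            reads.append(
                SequencedRead(
                    read_id=f"{t.isoform_id}_tile{j}",
                    mate=1,
                    bases=t.sequence[s : s + read_length],
                    qualities=[40] * read_length,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Protein database


def find_longest_orf(seq: str) -> tuple[int, int] | None:
    """Longest ATG..stop open reading frame on the forward strand.

    Returns half-open nucleotide coordinates including the stop codon,
    or None when no complete ORF exists.
    """
    best: tuple[int, int] | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                if best is None or (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    return best


def build_protein_db(
    transcripts: list[TranscriptModel],
    target_identity: float = 0.7,
    seed: int = 0,
    min_orf_aa: int = 60,
) -> dict[str, str]:
    """One diverged protein per gene, from the longest-ORF translation.

    Random substitutions bring each protein to ``target_identity`` with
    its true translation (+- rounding).  Record ids are ``prot_<gene_id>``
    so truth can be recovered.  Genes without an ORF of >= ``min_orf_aa``
    residues are skipped.
    """
    if not 0.3 <= target_identity <= 1.0:
        raise ValueError("target_identity must be in [0.3, 1.0]")
    rng = np.random.default_rng(seed)
    db: dict[str, str] = {}
    seen_genes: set[str] = set()
    for t in transcripts:
        if t.gene_id in seen_genes:
            continue
        orf = find_longest_orf(t.sequence)
        if orf is None:
            continue
        pep = str(Seq(t.sequence[orf[0] : orf[1]]).translate())[:-1]
        if len(pep) < min_orf_aa:
            continue
        seen_genes.add(t.gene_id)
        n_sub = round((1.0 - target_identity) * len(pep))
        arr = list(pep)
        if n_sub > 0:
            positions = rng.choice(len(arr), size=n_sub, replace=False)
            for p in positions:
                alternatives = [a for a in AMINO_ACIDS if a != arr[p]]
                arr[p] = alternatives[int(rng.integers(0, len(alternatives)))]
        db[f"prot_{t.gene_id}"] = "".join(arr)
    return db


# ---------------------------------------------------------------------------
# Motif planting


def sample_motif_instance(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """One peptide drawn uniformly from the pattern's language."""
    out: list[str] = []
    for el in pattern.elements:
        if el[0] == "res":
            out.append(el[1])
        elif el[0] == "any":
            out.append(AMINO_ACIDS[int(rng.integers(0, 20))])
        else:  # gap
            n = int(rng.integers(el[1], el[2] + 1))
            out.extend(AMINO_ACIDS[int(rng.integers(0, 20))] for _ in range(n))
    return "".join(out)


def back_translate(pep: str, rng: np.random.Generator) -> str:
    return "".join(
        CODONS_FOR[aa][int(rng.integers(0, len(CODONS_FOR[aa])))] for aa in pep
    )


def plant_motif(
    transcript: TranscriptModel,
    pattern: MotifPattern | str,
    seed: int = 0,
    protein_offset: int | None = None,
) -> TranscriptModel:
    """Splice a back-translated motif instance in-frame into the CDS.

    The planted protein-coordinate offset is recorded on the returned
    transcript.  Offsets are relative to the translated CDS (0 = the
    initial Met, which is never overwritten).
    """
    if isinstance(pattern, str):
        pattern = parse_motif(pattern)
    rng = np.random.default_rng(seed)
    instance = sample_motif_instance(pattern, rng)
    n_codons = (transcript.cds_end - transcript.cds_start) // 3 - 1  # sans stop
    if len(instance) + 1 > n_codons:
        raise ValueError(
            f"transcript {transcript.isoform_id} too short to host a "
            f"{len(instance)}-residue motif instance"
        )
    if protein_offset is None:
        protein_offset = int(rng.integers(1, n_codons - len(instance) + 1))
    elif not 1 <= protein_offset <= n_codons - len(instance):
        raise ValueError("protein_offset out of range")
    nt = back_translate(instance, rng)
    p = transcript.cds_start + 3 * protein_offset
    seq = transcript.sequence[:p] + nt + transcript.sequence[p + len(nt) :]
    return replace(
        transcript,
        sequence=seq,
        planted_motifs=transcript.planted_motifs + ((pattern.raw, protein_offset),),
    )


# ---------------------------------------------------------------------------
# Serialisation helpers


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_transcripts_fasta(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.isoform_id} gene={t.gene_id} expression={t.expression:.4f}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")


def write_truth_tables(transcripts: list[TranscriptModel], pairs: list[ReadPair], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "truth_expression.tsv", "w") as fh:
        fh.write("isoform_id\tgene_id\tlength\texpression\n")
        for t in transcripts:
            fh.write(f"{t.isoform_id}\t{t.gene_id}\t{len(t)}\t{t.expression:.6f}\n")
    with open(out / "truth_motifs.tsv", "w") as fh:
        fh.write("isoform_id\tpattern\tprotein_offset\n")
        for t in transcripts:
            for raw, off in t.planted_motifs:
                fh.write(f"{t.isoform_id}\t{raw}\t{off}\n")
    with open(out / "truth_read_origins.tsv", "w") as fh:
        fh.write("pair_id\tisoform_id\tstart\tinsert\n")
        for p in pairs:
            pid = p.read1.read_id.rsplit("/", 1)[0]
            fh.write(f"{pid}\t{p.origin_isoform}\t{p.origin_start}\t{p.origin_insert}\n")
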