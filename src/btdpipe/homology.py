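"""Translated homology search and multi-k assembly merging.

Queries are translated in all six reading frames and aligned locally
(Smith-Waterman, BLOSUM62, affine gaps 11/1) against a protein database.
Significance uses the Karlin-Altschul formula E = K*m*n*exp(-lambda*S)
with the matrix's ungapped parameters applied to gapped scores, the
database length entering through n, so the conventional E < 1e-5 cut
behaves comparably to a BLAST run.  A hit must additionally span more
than 60 aligned amino-acid columns.

A word-index prefilter (shared 4-mers) skips subject proteins that
cannot reach the thresholds; the alignment itself is always the exact
dynamic program, never a heuristic extension.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# Karlin-Altschul ungapped parameters for BLOSUM62
KA_LAMBDA = 0.318
KA_K = 0.13

MIN_ALIGNED_AA = 60  # strict: hits must exceed this
MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a (translated) query and a subject."""

    query_id: str
    subject_id: str
    frame: int  # query frame, +-1..3; 0 for untranslated queries
    subject_frame: int | None
    score: float
    evalue: float
    identity: float  # matches / aligned columns
    aligned_len: int  # aligned columns, gaps included
    query_span: tuple[int, int]  # half-open, residue (or nt) coords
    subject_span: tuple[int, int]


@dataclass(frozen=True)
class HomologueAssignment:
    isotig_id: str
    subject_id: str
    hit: AlignmentHit


# ---------------------------------------------------------------------------
# Translation


def translate_six_frames(nt: str) -> dict[int, str]:
    """Standard-table translations of frames +1..+3 and -1..-3.

    Stops are rendered '*'.  Frames with fewer than one full codon are
    empty strings.
    """
    nt = nt.upper()
    if len(nt) < 3:
        return {f: "" for f in (1, 2, 3, -1, -2, -3)}
    rc = str(Seq(nt).reverse_complement())
    frames: dict[int, str] = {}
    for off in range(3):
        for sign, s in ((1, nt), (-1, rc)):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            frames[sign * (off + 1)] = str(Seq(sub).translate()) if sub else ""
    return frames


# ---------------------------------------------------------------------------
# Local protein alignment


@lru_cache(maxsize=None)
def _aligner(gap_open: int, gap_extend: int, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST convention: a gap of length L costs gap_open + L*gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


_NON_MATRIX = re.compile(r"[^ARNDCQEGHILKMFPSTWYVBZX*]")


def _sanitise(pep: str) -> str:
    # unknown residue symbols fall to the matrix's wildcard row
    return _NON_MATRIX.sub("X", pep.upper())


def local_align_protein(
    query_pep: str,
    subject_pep: str,
    query_id: str = "query",
    subject_id: str = "subject",
    frame: int = 0,
    subject_frame: int | None = None,
    db_size: int | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    matrix: str = "BLOSUM62",
) -> AlignmentHit | None:
    """Optimal local alignment of two peptides, or None if no positive score.

    ``db_size`` (total residues in the search database) replaces the
    subject length as n in the E-value when given, matching database
    search semantics.
    """
    if not query_pep or not subject_pep:
        return None
    q, s = _sanitise(query_pep), _sanitise(subject_pep)
    aligner = _aligner(gap_open, gap_extend, matrix)
    alignments = aligner.align(q, s)
    if alignments.score <= 0:
        return None
    score = alignments.score
    aln = alignments[0]
    qblocks, sblocks = aln.aligned
    matches = 0
    columns = 0
    prev_q = prev_s = None
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        if prev_q is not None:
            columns += (qa - prev_q) + (sa - prev_s)  # gap columns
        for i in range(qb - qa):
            columns += 1
            if q[qa + i] == s[sa + i]:
                matches += 1
        prev_q, prev_s = qb, sb
    n = db_size if db_size is not None else len(s)
    evalue = karlin_altschul_evalue(score, len(q), n)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        frame=frame,
        subject_frame=subject_frame,
        score=float(score),
        evalue=evalue,
        identity=matches / columns if columns else 0.0,
        aligned_len=columns,
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        subject_span=(int(sblocks[0][0]), int(sblocks[-1][1])),
    )


class ProteinIndex:
    """Inverted word index over a protein database (BLAST-style seeding,
    used only to skip subjects sharing no word with the query)."""

    def __init__(self, db: dict[str, str], word: int = 5):
        self.db = db
        self.word = word
        self.total_residues = sum(len(s) for s in db.values())
        self._index: dict[str, set[str]] = {}
        for sid, seq in db.items():
            for i in range(len(seq) - word + 1):
                self._index.setdefault(seq[i : i + word], set()).add(sid)

    def candidates(self, pep: str) -> set[str]:
        out: set[str] = set()
        for i in range(len(pep) - self.word + 1):
            hit = self._index.get(pep[i : i + self.word])
            if hit:
                out |= hit
        return out


def assign_best_homologue(
    isotig_id: str,
    nt_seq: str,
    protein_db: dict[str, str] | ProteinIndex,
    min_aa: int = MIN_ALIGNED_AA,
    max_e: float = MAX_EVALUE,
    prefilter: bool = True,
) -> HomologueAssignment | None:
    """Best subject over all six frames by smallest E-value.

    Ties break by higher score, then lexicographic subject id.  Returns
    None when no alignment exceeds ``min_aa`` columns at E < ``max_e``.
    """
    index = protein_db if isinstance(protein_db, ProteinIndex) else ProteinIndex(protein_db)
    db = index.db
    best: AlignmentHit | None = None
    for frame, pep in sorted(translate_six_frames(nt_seq).items()):
        if len(pep) <= min_aa:
            continue
        subjects = index.candidates(pep) if prefilter else set(db)
        for sid in sorted(subjects):
            hit = local_align_protein(
                pep, db[sid], isotig_id, sid, frame=frame, db_size=index.total_residues
            )
            if hit is None or hit.aligned_len <= min_aa or hit.evalue >= max_e:
                continue
            if best is None or (hit.evalue, -hit.score, hit.subject_id) < (
                best.evalue,
                -best.score,
                best.subject_id,
            ):
                best = hit
    if best is None:
        return None
    return HomologueAssignment(isotig_id, best.subject_id, best)


# ---------------------------------------------------------------------------
# Multi-k merging


def merge_multi_k(
    per_k_isotigs: dict[int, list],
    assignments: dict[str, str | None],
    base_k: int = 31,
) -> tuple[list, dict[int, int]]:
    """Merge isotig sets from several k values around a base assembly.

    The base-k isotigs are all kept, homologue or not.  An isotig from
    another k joins only when its assigned subject is new: absent from
    the base set's subjects and from subjects contributed by previously
    processed k values.  k values are processed by ascending distance to
    ``base_k`` (ties: lower k first).  Returns the merged isotig list and
    the per-k tally of additional subjects contributed.

    ``per_k_isotigs`` values are sequences of objects with an
    ``isotig_id`` attribute (or plain ids); ``assignments`` maps isotig
    id -> subject id or None.
    """
    if base_k not in per_k_isotigs:
        raise ValueError(f"base k={base_k} missing from the per-k map")

    def ident(it):
        return it.isotig_id if hasattr(it, "isotig_id") else it

    merged = list(per_k_isotigs[base_k])
    seen_subjects = {
        s for s in (assignments.get(ident(it)) for it in merged) if s is not None
    }
    tally: dict[int, int] = {}
    order = sorted((k for k in per_k_isotigs if k != base_k), key=lambda k: (abs(k - base_k), k))
    for k in order:
        added = 0
        for it in per_k_isotigs[k]:
            subject = assignments.get(ident(it))
            if subject is None or subject in seen_subjects:
                continue
            merged.append(it)
            seen_subjects.add(subject)
            added += 1
        tally[k] = added
    return merged, tally


# ---------------------------------------------------------------------------
# Known-mRNA validation (nucleotide mode)


@lru_cache(maxsize=1)
def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # megablast-like scoring
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def validate_against_known(
    isotigs: dict[str, str],
    known_mrnas: dict[str, str],
    min_identity: float = 0.95,
    min_cov: float = 0.80,
) -> list[dict]:
    """Nucleotide validation against known full mRNAs.

    A pair passes when alignment identity > ``min_identity`` and aligned
    length / isotig length > ``min_cov``.  Rows are grouped per mRNA.
    """
    aligner = _nt_aligner()
    rows: list[dict] = []
    for mid, mseq in sorted(known_mrnas.items()):
        for iid, iseq in sorted(isotigs.items()):
            best = None
            for strand, q in (("+", iseq), ("-", str(Seq(iseq).reverse_complement()))):
                if aligner.score(q, mseq) <= 0:
                    continue
                aln = aligner.align(q, mseq)[0]
                qb, sb = aln.aligned
                matches = sum(
                    1
                    for (qa, qe), (sa, _) in zip(qb, sb)
                    for i in range(qe - qa)
                    if q[qa + i] == mseq[sa + i]
                )
                columns = 0
                prev = None
                for (qa, qe), (sa, se) in zip(qb, sb):
                    if prev is not None:
                        columns += (qa - prev[0]) + (sa - prev[1])
                    columns += qe - qa
                    prev = (qe, se)
                rec = (matches / columns if columns else 0.0, columns, strand)
                if best is None or rec > best:
                    best = rec
            if best is None:
                continue
            identity, columns, strand = best
            coverage = columns / len(iseq)
            if identity > min_identity and coverage > min_cov:
                rows.append(
                    {
                        "mrna_id": mid,
                        "isotig_id": iid,
                        "identity": identity,
                        "coverage_ratio": coverage,
                        "aligned_len": columns,
                        "strand": strand,
                    }
                )
    return rows


# ---------------------------------------------------------------------------
# Poly-N gap consistency


@dataclass(frozen=True)
class GapConsistency:
    isotig_id: str
    consistent: bool
    reason: str
    subject_id: str | None = None


def check_gap_consistency(
    isotig_id: str,
    seq: str,
    protein_db: dict[str, str] | ProteinIndex,
    min_segment: int = 90,
    min_aa: int = 20,
    max_e: float = MAX_EVALUE,
) -> GapConsistency:
    """Check that segments flanking poly-N runs tell one coherent story.

    The isotig is split at runs of N; each segment's best homologue must
    be the same protein, with subject coordinates in the same order as
    the segments appear along the isotig.
    """
    segments = [s for s in re.split("N+", seq.upper()) if len(s) >= min_segment]
    if "N" not in seq.upper():
        return GapConsistency(isotig_id, True, "no N-run: nothing to check")
    if len(segments) < 2:
        return GapConsistency(isotig_id, False, "fewer than two alignable segments")
    assignments = []
    for i, seg in enumerate(segments):
        a = assign_best_homologue(f"{isotig_id}/seg{i}", seg, protein_db, min_aa=min_aa, max_e=max_e)
        if a is None:
            return GapConsistency(isotig_id, False, f"segment {i} has no homologue")
        assignments.append(a)
    subjects = {a.subject_id for a in assignments}
    if len(subjects) > 1:
        return GapConsistency(
            isotig_id, False, f"segments hit different proteins: {sorted(subjects)}"
        )
    starts = [a.hit.subject_span[0] for a in assignments]
    forward = all(a.hit.frame > 0 for a in assignments)
    ordered = starts == sorted(starts) if forward else starts == sorted(starts, reverse=True)
    if not ordered:
        return GapConsistency(
            isotig_id, False, "subject coordinates out of order across the gap",
            subject_id=assignments[0].subject_id,
        )
    return GapConsistency(isotig_id, True, "segments collinear on one protein",
                          subject_id=assignments[0].subject_id)


# ---------------------------------------------------------------------------
# Target-site discovery (translated query vs translated reference)


def translated_scan(
    isotigs: dict[str, str],
    reference_genes: dict[str, str],
    min_identity: float = 0.90,
    min_aa: int = 20,
    max_e: float = MAX_EVALUE,
) -> list[dict]:
    """Six-frame x six-frame scan of isotigs against nucleotide references.

    For each (reference, isotig) pair the best HSP over all 36 frame
    combinations is reported when its identity exceeds ``min_identity``;
    the best sub-threshold identity is reported too (flagged), so near
    misses stay visible in the table.
    """
    word = 4
    rows: list[dict] = []
    for rid, rseq in sorted(reference_genes.items()):
        ref_frames = translate_six_frames(rseq)
        ref_words = {
            sf: {spep[i : i + word] for i in range(len(spep) - word + 1)}
            for sf, spep in ref_frames.items()
        }
        for iid, iseq in sorted(isotigs.items()):
            best: AlignmentHit | None = None
            for qf, qpep in sorted(translate_six_frames(iseq).items()):
                if len(qpep) < min_aa:
                    continue
                qwords = {qpep[i : i + word] for i in range(len(qpep) - word + 1)}
                for sf, spep in sorted(ref_frames.items()):
                    if len(spep) < min_aa or not (qwords & ref_words[sf]):
                        continue
                    hit = local_align_protein(
                        qpep, spep, iid, rid, frame=qf, subject_frame=sf
                    )
                    if hit is None or hit.aligned_len < min_aa:
                        continue
                    if best is None or (hit.evalue, -hit.score) < (best.evalue, -best.score):
                        best = hit
            if best is None or best.evalue >= max_e:
                continue
            rows.append(
                {
                    "reference": rid,
                    "isotig_id": iid,
                    "evalue": best.evalue,
                    "identity": best.identity,
                    "aligned_len": best.aligned_len,
                    "isotig_length": len(iseq),
                    "above_threshold": best.identity > min_identity,
                }
            )
    return rows


# ---------------------------------------------------------------------------
# Tabular rendering (12-column blast-like dialect)

TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def hit_to_tabular(hit: AlignmentHit) -> str:
    """Render a hit in the familiar 12-column tab-separated layout
    (1-based closed coordinates, as rendered reports use)."""
    mismatches = hit.aligned_len - round(hit.identity * hit.aligned_len)
    fields = [
        hit.query_id,
        hit.subject_id,
        f"{100 * hit.identity:.2f}",
        str(hit.aligned_len),
        str(mismatches),
        "0",
        str(hit.query_span[0] + 1),
        str(hit.query_span[1]),
        str(hit.subject_span[0] + 1),
        str(hit.subject_span[1]),
        f"{hit.evalue:.2e}",
        f"{hit.score:.1f}",
    ]
    return "\t".join(fields)
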