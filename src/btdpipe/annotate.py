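"""Enzyme annotation: EC-group prediction, flexible-gap motif matching,
coverage-based deduplication and gene collapsing.

Motif patterns follow the catalytic-signature grammar used for enzyme
sequence signatures: an uppercase letter is a fixed residue, ``x`` is
any single residue, ``x(m,n)`` is a flexible gap of m..n arbitrary
residues, and ``-`` is a cosmetic separator.  Matches never cross a stop
codon ('*'): wildcards and gaps match the 20 amino acids only.

An isotig is assigned to the EC group of its closest enzymatic
homologue (smallest E-value).  When the best hits' E-values are within
one ambiguity factor of each other but disagree on EC, the group whose
signature motif matches one of the isotig's six-frame translations is
chosen; otherwise the minimum-E choice is kept and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import homology
from .homology import AlignmentHit, ProteinIndex, translate_six_frames

# ---------------------------------------------------------------------------
# Motif grammar

Element = tuple  # ("res", ch) | ("any",) | ("gap", m, n)


@dataclass(frozen=True)
class MotifPattern:
    raw: str
    elements: tuple[Element, ...]

    def render(self) -> str:
        return self.raw

    @property
    def min_len(self) -> int:
        return sum(1 if e[0] != "gap" else e[1] for e in self.elements)

    @property
    def max_len(self) -> int:
        return sum(1 if e[0] != "gap" else e[2] for e in self.elements)


class MotifParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def parse_motif(raw: str) -> MotifPattern:
    """Parse a flexible-gap pattern; round-trips via ``render``."""
    if not raw:
        raise MotifParseError("empty pattern", 0)
    elements: list[Element] = []
    i = 0
    n_fixed = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "-":
            i += 1
        elif ch == "x":
            if i + 1 < len(raw) and raw[i + 1] == "(":
                j = raw.find(")", i + 2)
                if j < 0:
                    raise MotifParseError("unterminated gap", i)
                body = raw[i + 2 : j]
                parts = body.split(",")
                if len(parts) != 2 or not all(p.strip().isdigit() for p in parts):
                    raise MotifParseError(f"malformed gap 'x({body})'", i)
                m, n = int(parts[0]), int(parts[1])
                if m > n:
                    raise MotifParseError(f"gap bounds reversed in 'x({body})'", i)
                elements.append(("gap", m, n))
                i = j + 1
            else:
                elements.append(("any",))
                i += 1
        elif ch.isalpha() and ch.isupper():
            elements.append(("res", ch))
            n_fixed += 1
            i += 1
        else:
            raise MotifParseError(f"unexpected character {ch!r}", i)
    if n_fixed == 0:
        raise MotifParseError("pattern has no fixed residue", 0)
    return MotifPattern(raw=raw, elements=tuple(elements))


def _match_here(elements: tuple[Element, ...], pep: str, pos: int, ei: int) -> bool:
    # backtracking matcher; '*' never matched by wildcards or gaps
    if ei == len(elements):
        return True
    el = elements[ei]
    if el[0] == "res":
        if pos < len(pep) and pep[pos] == el[1]:
            return _match_here(elements, pep, pos + 1, ei + 1)
        return False
    if el[0] == "any":
        if pos < len(pep) and pep[pos] != "*":
            return _match_here(elements, pep, pos + 1, ei + 1)
        return False
    m, n = el[1], el[2]
    for width in range(m, n + 1):
        if pos + width > len(pep) or "*" in pep[pos : pos + width]:
            break
        if _match_here(elements, pep, pos + width, ei + 1):
            return True
    return False


def match_motif(pattern: MotifPattern, peptide: str) -> list[int]:
    """All distinct start positions where the pattern matches (overlaps
    reported; matches cannot span '*')."""
    last_start = len(peptide) - pattern.min_len
    return [
        i for i in range(last_start + 1) if _match_here(pattern.elements, peptide, i, 0)
    ]


# ---------------------------------------------------------------------------
# Motif library

# signature motifs of the insecticide-relevant EC groups: the heme-binding
# decapeptide of cytochrome P450s, GST G-site signatures (incl. one
# two-component flexible-gap signature), the esterase catalytic elbow,
# and an acetylcholinesterase-specific pentapeptide.
DEFAULT_MOTIFS: dict[str, tuple[str, ...]] = {
    "1.14.14.1": ("FxxGxRxCxG",),
    "2.5.1.18": ("SxAI", "TxAI", "PxLxD-x(7,10)-SxAIxxYLxxK"),
    "3.1.1.1": ("GxSxG",),
    "3.1.1.7": ("SEDCL",),
}


def default_motif_library() -> dict[str, list[MotifPattern]]:
    return {ec: [parse_motif(p) for p in pats] for ec, pats in DEFAULT_MOTIFS.items()}


def load_motif_library(path) -> dict[str, list[MotifPattern]]:
    """Plain-text library: one ``EC<whitespace>pattern`` per line, '#' comments."""
    lib: dict[str, list[MotifPattern]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            ec, pattern = line.split(None, 1)
            lib.setdefault(ec, []).append(parse_motif(pattern.strip()))
    return lib


# ---------------------------------------------------------------------------
# Enzyme database

def parse_enzyme_fasta(path) -> dict[str, tuple[str, str]]:
    """Read an enzyme FASTA whose headers carry ``EC=`` tags.

    Returns id -> (sequence, ec_number).
    """
    db: dict[str, tuple[str, str]] = {}
    name, ec, chunks = None, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    db[name] = ("".join(chunks), ec)
                header = line[1:].split()
                name = header[0]
                ec = next(
                    (f.split("=", 1)[1] for f in header[1:] if f.startswith("EC=")), ""
                )
                chunks = []
            else:
                chunks.append(line.strip())
    if name is not None:
        db[name] = ("".join(chunks), ec)
    return db


# ---------------------------------------------------------------------------
# EC prediction


@dataclass
class ECPrediction:
    isotig_id: str
    ec_number: str
    source_hit: AlignmentHit
    motif_confirmed: bool = False
    resolved: bool = True
    competing_ecs: list[str] = field(default_factory=list)


def _any_frame_motif_match(nt_seq: str, patterns: list[MotifPattern]) -> bool:
    for _, pep in translate_six_frames(nt_seq).items():
        for pat in patterns:
            if match_motif(pat, pep):
                return True
    return False


def predict_ec(
    isotig_id: str,
    nt_seq: str,
    enzyme_db: dict[str, tuple[str, str]],
    motif_library: dict[str, list[MotifPattern]] | None = None,
    ambiguity_factor: float = 10.0,
    min_aa: int = homology.MIN_ALIGNED_AA,
    max_e: float = homology.MAX_EVALUE,
    index: ProteinIndex | None = None,
) -> ECPrediction | None:
    """EC of the minimum-E-value enzymatic homologue, motif-arbitrated
    when the ranking is not clear.

    ``enzyme_db`` maps id -> (sequence, ec).  Hits within
    ``ambiguity_factor`` of the best E-value that disagree on EC trigger
    the motif step; when exactly one competing EC's motif matches some
    six-frame translation the prediction switches to it
    (motif_confirmed).  Zero or several matching motifs leave the
    minimum-E choice flagged unresolved with the competitors listed.
    """
    if motif_library is None:
        motif_library = default_motif_library()
    seqs = {sid: s for sid, (s, _) in enzyme_db.items()}
    if index is None:
        index = ProteinIndex(seqs)
    hits: list[AlignmentHit] = []
    for frame, pep in sorted(translate_six_frames(nt_seq).items()):
        if len(pep) <= min_aa:
            continue
        for sid in sorted(index.candidates(pep)):
            hit = homology.local_align_protein(
                pep, seqs[sid], isotig_id, sid, frame=frame,
                db_size=index.total_residues,
            )
            if hit and hit.aligned_len > min_aa and hit.evalue < max_e:
                hits.append(hit)
    if not hits:
        return None
    # best hit per subject, then rank subjects
    by_subject: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = by_subject.get(h.subject_id)
        if cur is None or (h.evalue, -h.score) < (cur.evalue, -cur.score):
            by_subject[h.subject_id] = h
    ranked = sorted(by_subject.values(), key=lambda h: (h.evalue, -h.score, h.subject_id))
    best = ranked[0]
    best_ec = enzyme_db[best.subject_id][1]
    near = [h for h in ranked if h.evalue <= best.evalue * ambiguity_factor]
    competing = sorted({enzyme_db[h.subject_id][1] for h in near} - {best_ec})
    if not competing:
        pred = ECPrediction(isotig_id, best_ec, best)
        pred.motif_confirmed = _any_frame_motif_match(
            nt_seq, motif_library.get(best_ec, [])
        )
        return pred
    # ambiguous ranking: let the signature motifs arbitrate
    matching = [
        ec
        for ec in [best_ec] + competing
        if _any_frame_motif_match(nt_seq, motif_library.get(ec, []))
    ]
    if len(matching) == 1:
        winner_ec = matching[0]
        winner_hit = best if winner_ec == best_ec else next(
            h for h in near if enzyme_db[h.subject_id][1] == winner_ec
        )
        return ECPrediction(
            isotig_id, winner_ec, winner_hit, motif_confirmed=True,
            competing_ecs=[ec for ec in [best_ec] + competing if ec != winner_ec],
        )
    return ECPrediction(
        isotig_id, best_ec, best,
        motif_confirmed=best_ec in matching,
        resolved=False,
        competing_ecs=competing,
    )


# ---------------------------------------------------------------------------
# Deduplication and gene collapsing


def dedupe_by_coverage(
    predictions: list[ECPrediction],
    coverages: dict[str, float],
    lengths: dict[str, int] | None = None,
) -> list[ECPrediction]:
    """Within each (EC group, shared nearest homologue) set keep only the
    highest-coverage isotig; ties go to the longer isotig, then the id."""
    lengths = lengths or {}

    def sort_key(p: ECPrediction):
        return (
            -coverages[p.isotig_id],
            -lengths.get(p.isotig_id, 0),
            p.isotig_id,
        )

    groups: dict[tuple[str, str], list[ECPrediction]] = {}
    for p in predictions:
        groups.setdefault((p.ec_number, p.source_hit.subject_id), []).append(p)
    survivors = [min(members, key=sort_key) for members in groups.values()]
    survivors.sort(key=lambda p: p.isotig_id)
    return survivors


@dataclass
class GeneCluster:
    gene_key: str  # subject id of the shared nearest homologue
    member_isotigs: list[str]
    representative: str
    n_transcript_units: int
    family_label: str | None = None


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def collapse_genes(
    predictions: list[ECPrediction],
    coverages: dict[str, float] | None = None,
    family_labels: dict[str, str] | None = None,
    overlap_threshold: float = 0.2,
) -> tuple[list[GeneCluster], list[dict]]:
    """Collapse isotigs sharing a nearest homologue into putative genes.

    Isotigs whose subject spans overlap reciprocally by more than the
    threshold are isoform candidates (one transcript unit); mutually
    non-overlapping isotigs are fragments of the same gene (several
    transcript units, still one gene).  Returns the clusters and a
    per-family tally table (family, n_isotigs, n_genes).
    """
    coverages = coverages or {}
    family_labels = family_labels or {}
    by_key: dict[str, list[ECPrediction]] = {}
    for p in predictions:
        by_key.setdefault(p.source_hit.subject_id, []).append(p)
    clusters: list[GeneCluster] = []
    for key in sorted(by_key):
        members = sorted(by_key[key], key=lambda p: p.isotig_id)
        spans = [p.source_hit.subject_span for p in members]
        # connected components under the reciprocal-overlap relation
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _reciprocal_overlap(spans[i], spans[j]) > overlap_threshold:
                    parent[find(i)] = find(j)
        units = len({find(i) for i in range(len(members))})
        rep = max(members, key=lambda p: (coverages.get(p.isotig_id, 0.0), p.isotig_id))
        clusters.append(
            GeneCluster(
                gene_key=key,
                member_isotigs=[p.isotig_id for p in members],
                representative=rep.isotig_id,
                n_transcript_units=units,
                family_label=family_labels.get(key),
            )
        )
    tally: dict[str, dict[str, int]] = {}
    for c in clusters:
        fam = c.family_label or "unclassified"
        row = tally.setdefault(fam, {"n_isotigs": 0, "n_genes": 0})
        row["n_isotigs"] += len(c.member_isotigs)
        row["n_genes"] += 1
    table = [
        {"family": fam, **counts} for fam, counts in sorted(tally.items())
    ]
    return clusters, table
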