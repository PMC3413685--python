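"""Quality filtering of paired-end short reads.

Reads are filtered whole (no trimming): a read survives only if its 5'
window is of high quality and it is free of uncertain bases and adapter
contamination.  The quality rule keeps a read iff at least ``min_good``
of the first ``window`` base calls have a Phred score strictly above
``min_q`` (defaults 25 / 35 / Q30).  Pairs where both mates survive stay
paired; a lone surviving mate is kept as a single (orphan) read, the way
short-read assemblers accept a mixed paired/single input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_WINDOW = 35
DEFAULT_MIN_GOOD = 25
DEFAULT_MIN_Q = 30


@dataclass
class SequencedRead:
    """One short read: bases plus per-base Phred quality scores."""

    read_id: str
    mate: int  # 1 or 2
    bases: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QCReport:
    """Accounting of a filtering run, in the layout of an assembly-stats table."""

    n_input: int = 0
    n_retained: int = 0
    n_paired_retained: int = 0
    n_single_retained: int = 0
    rejection_tally: dict = field(default_factory=dict)
    total_retained_length: int = 0

    def validate(self) -> None:
        assert self.n_retained == self.n_paired_retained + self.n_single_retained
        assert self.n_retained <= self.n_input
        assert sum(self.rejection_tally.values()) == self.n_input - self.n_retained


def passes_quality_window(
    read: SequencedRead,
    window: int = DEFAULT_WINDOW,
    min_good: int = DEFAULT_MIN_GOOD,
    min_q: int = DEFAULT_MIN_Q,
) -> bool:
    """True iff >= ``min_good`` of the first ``window`` scores are > ``min_q``.

    Reads shorter than the window are rejected: the rule is undefined for
    them and the target data are uniform-length reads.
    """
    if len(read) < window:
        return False
    good = sum(1 for q in read.qualities[:window] if q > min_q)
    return good >= min_good


def passes_content(read: SequencedRead, adapters: Sequence[str] = ()) -> bool:
    """False iff the read contains an 'N' or any adapter as an exact substring."""
    if "N" in read.bases:
        return False
    for adapter in adapters:
        if adapter and adapter in read.bases:
            return False
    return True


def _passes(read: SequencedRead, adapters: Sequence[str], quality_kw: dict) -> tuple[bool, str | None]:
    if not passes_quality_window(read, **quality_kw):
        return False, "quality"
    if "N" in read.bases:
        return False, "N"
    for adapter in adapters:
        if adapter and adapter in read.bases:
            return False, "adapter"
    return True, None


def filter_pairs(
    pairs: Iterable[tuple[SequencedRead, SequencedRead]],
    adapters: Sequence[str] = (),
    window: int = DEFAULT_WINDOW,
    min_good: int = DEFAULT_MIN_GOOD,
    min_q: int = DEFAULT_MIN_Q,
) -> tuple[list[tuple[SequencedRead, SequencedRead]], list[SequencedRead], QCReport]:
    """Apply both predicates to synchronized mate pairs.

    Both mates pass -> retained pair; exactly one -> retained single;
    neither -> dropped.  Returns (pairs, singles, report).
    """
    quality_kw = dict(window=window, min_good=min_good, min_q=min_q)
    kept_pairs: list[tuple[SequencedRead, SequencedRead]] = []
    kept_singles: list[SequencedRead] = []
    report = QCReport()
    for r1, r2 in pairs:
        if _strip_mate_suffix(r1.read_id) != _strip_mate_suffix(r2.read_id):
            raise ValueError(
                f"desynchronized mate files at read id {r1.read_id!r} vs {r2.read_id!r}"
            )
        report.n_input += 2
        ok1, why1 = _passes(r1, adapters, quality_kw)
        ok2, why2 = _passes(r2, adapters, quality_kw)
        if ok1 and ok2:
            kept_pairs.append((r1, r2))
            report.n_paired_retained += 2
            report.total_retained_length += len(r1) + len(r2)
        elif ok1 or ok2:
            keeper = r1 if ok1 else r2
            kept_singles.append(keeper)
            report.n_single_retained += 1
            report.total_retained_length += len(keeper)
            why = why2 if ok1 else why1
            report.rejection_tally[why] = report.rejection_tally.get(why, 0) + 1
        else:
            for why in (why1, why2):
                report.rejection_tally[why] = report.rejection_tally.get(why, 0) + 1
    report.n_retained = report.n_paired_retained + report.n_single_retained
    report.validate()
    return kept_pairs, kept_singles, report


def _strip_mate_suffix(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33 by default, +64 available for legacy data)


def read_fastq(path, phred_offset: int = 33, mate: int = 1) -> Iterator[SequencedRead]:
    offset_shift = phred_offset - 33
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if offset_shift:
            quals = [q - offset_shift for q in quals]
        yield SequencedRead(rec.id, mate, str(rec.seq).upper(), quals)


def read_paired_fastq(path1, path2, phred_offset: int = 33) -> Iterator[tuple[SequencedRead, SequencedRead]]:
    it1 = read_fastq(path1, phred_offset, mate=1)
    it2 = read_fastq(path2, phred_offset, mate=2)
    for r1, r2 in zip(it1, it2, strict=True):
        yield r1, r2


def _to_record(read: SequencedRead) -> SeqRecord:
    rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
    rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def write_fastq(reads: Iterable[SequencedRead], path) -> int:
    return SeqIO.write((_to_record(r) for r in reads), str(path), "fastq")


def write_filtered(pairs, singles, out_dir) -> dict:
    """Write retained_1.fq / retained_2.fq / retained_single.fq under out_dir."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n1 = write_fastq((p[0] for p in pairs), out / "retained_1.fq")
    n2 = write_fastq((p[1] for p in pairs), out / "retained_2.fq")
    ns = write_fastq(singles, out / "retained_single.fq")
    return {"retained_1": n1, "retained_2": n2, "retained_single": ns}
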