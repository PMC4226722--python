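"""IsomiR calling from small-RNA alignments.

Reads are filtered by the mapping criteria (length >= 16 nt, unique mapping,
no indels, mismatch rate <= 4% of read length), assigned to the unique arm
window that wholly contains them, and collapsed by exact genomic endpoints
into isomiRs.  Endpoint offsets are expressed in the 5'->3' orientation of
the mature strand relative to the reference mature entry; the printable
notation is ``[5´end±k][3´end±k]``.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .annotation import ArmCatalog, ArmWindow, interval_to_offsets

MIN_READ_LENGTH = 16
MAX_MISMATCH_RATE = 0.04

# rejection reasons
TOO_SHORT = "too_short"
MULTIMAPPED = "multimapped"
INDEL = "indel"
MISMATCH_RATE = "mismatch_rate"


@dataclass(frozen=True)
class AlignedRead:
    """A mapped small-RNA read, in genomic 0-based half-open coordinates."""

    chrom: str
    strand: str
    start: int
    end: int
    read_length: int
    mismatches: int = 0
    has_indel: bool = False
    is_unique: Optional[bool] = None  # None = no uniqueness evidence
    sample_id: str = ""


@dataclass(frozen=True)
class IsomiR:
    """An arm plus signed (5', 3') endpoint offsets vs the miRBase reference."""

    arm_id: str
    off5: int
    off3: int
    sequence: str = ""

    @property
    def notation(self) -> str:
        return format_notation(self.off5, self.off3)

    @property
    def is_reference(self) -> bool:
        return self.off5 == 0 and self.off3 == 0


@dataclass
class ReadTally:
    """Pipeline-wide read accounting for one sample."""

    total: int = 0
    kept: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    rejected: Counter = field(default_factory=Counter)

    @property
    def rejected_total(self) -> int:
        return sum(self.rejected.values())

    def check_conservation(self) -> bool:
        return (
            self.assigned + self.unassigned + self.ambiguous
            + self.rejected_total + self.unmapped == self.total
        )


def mismatch_budget(read_length: int, rate: float = MAX_MISMATCH_RATE) -> int:
    """Largest mismatch count compatible with 'no more than rate per length'."""
    return math.floor(rate * read_length)


def filter_read(
    read: AlignedRead,
    min_length: int = MIN_READ_LENGTH,
    max_mismatch_rate: float = MAX_MISMATCH_RATE,
    unique_mode: str = "strict",
) -> tuple[bool, Optional[str]]:
    """Apply the mapping filters; returns (keep, rejection_reason).

    ``unique_mode`` controls reads with no uniqueness evidence: "strict"
    rejects them as multimapped, "lenient" treats primary-only records as
    unique.
    """
    if read.read_length < min_length:
        return False, TOO_SHORT
    unique = read.is_unique
    if unique is None:
        unique = unique_mode == "lenient"
    if not unique:
        return False, MULTIMAPPED
    if read.has_indel:
        return False, INDEL
    if read.mismatches > mismatch_budget(read.read_length, max_mismatch_rate):
        return False, MISMATCH_RATE
    return True, None


ASSIGNED = "assigned"
UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"


def assign_read(
    read: AlignedRead, catalog: ArmCatalog
) -> tuple[Optional[str], str]:
    """Assign a kept read to the unique window wholly containing it.

    Returns (arm_id, status) with status in {assigned, unassigned,
    ambiguous}; reads contained in more than one window are dropped as
    ambiguous (counted, never fractionally assigned).
    """
    hits = catalog.windows_containing(read.chrom, read.strand, read.start, read.end)
    if not hits:
        return None, UNASSIGNED
    if len(hits) > 1:
        return None, AMBIGUOUS
    return hits[0].arm.arm_id, ASSIGNED


def group_endpoints(
    assigned: Iterable[tuple[AlignedRead, str]], catalog: ArmCatalog
) -> dict[str, Counter]:
    """Collapse assigned reads of one sample by exact endpoints per arm.

    Reads sharing genomic (start, end) within an arm merge into one endpoint
    group regardless of internal mismatches.  Keys are (off5, off3) in
    mature-strand orientation.
    """
    groups: dict[str, Counter] = {}
    for read, arm_id in assigned:
        arm = catalog[arm_id].arm
        key = interval_to_offsets(arm, read.start, read.end)
        groups.setdefault(arm_id, Counter())[key] += 1
    return groups


def isomir_sequence(window: ArmWindow, off5: int, off3: int) -> str:
    """Genome-templated sequence of the isomiR, 5'->3' of the mature strand."""
    if not window.window_sequence:
        return ""
    i = window.flank + off5
    j = len(window.window_sequence) - window.flank + off3
    return window.window_sequence[i:j]


# --------------------------------------------------------------- notation

_NOTATION_RE = re.compile(
    r"^\[5´end(?P<s5>[+\-−–])(?P<k5>\d+)\]\[3´end(?P<s3>[+\-−–])(?P<k3>\d+)\]$"
)


def format_notation(off5: int, off3: int) -> str:
    """Canonical printable isomiR name; zero offsets rendered '+0'."""
    return f"[5´end{off5:+d}][3´end{off3:+d}]"


def parse_notation(text: str, flank: Optional[int] = None) -> tuple[int, int]:
    """Invert :func:`format_notation`; accepts '-', minus and en-dash signs.

    If ``flank`` is given, offsets outside ``[-flank, flank]`` are rejected.
    """
    m = _NOTATION_RE.match(text)
    if m is None:
        for pos, (a, b) in enumerate(zip(text, "[5´end")):
            if a != b:
                raise ValueError(f"malformed isomiR notation at position {pos}: {text!r}")
        raise ValueError(f"malformed isomiR notation at position {min(len(text), 6)}: {text!r}")
    sign5 = 1 if m["s5"] == "+" else -1
    sign3 = 1 if m["s3"] == "+" else -1
    off5, off3 = sign5 * int(m["k5"]), sign3 * int(m["k3"])
    if flank is not None and (abs(off5) > flank or abs(off3) > flank):
        raise ValueError(
            f"offsets ({off5},{off3}) outside the ±{flank} nt window: {text!r}"
        )
    return off5, off3


# --------------------------------------------------------------- SAM input


def _read_from_alignment(rec, chrom: str, unique: Optional[bool]) -> AlignedRead:
    has_indel = any(op in (1, 2, 3) for op, _ in (rec.cigartuples or ()))
    try:
        nm = rec.get_tag("NM")
    except KeyError:
        nm = 0
    return AlignedRead(
        chrom=chrom,
        strand="-" if rec.is_reverse else "+",
        start=rec.reference_start,
        end=rec.reference_end,
        read_length=rec.query_length or rec.infer_query_length() or 0,
        mismatches=nm,
        has_indel=has_indel,
        is_unique=unique,
    )


def _uniqueness(rec) -> Optional[bool]:
    if rec.is_secondary or rec.is_supplementary:
        return False
    try:
        return rec.get_tag("NH") == 1
    except KeyError:
        return None


def count_sam(
    path: str | Path,
    catalog: ArmCatalog,
    min_length: int = MIN_READ_LENGTH,
    max_mismatch_rate: float = MAX_MISMATCH_RATE,
    unique_mode: str = "strict",
    max_mismatches: Optional[int] = None,
) -> tuple[dict[str, Counter], ReadTally]:
    """Filter, assign and endpoint-group all reads of one SAM/BAM file.

    Returns (counts, tally): ``counts[arm_id][(off5, off3)]`` is the number
    of reads in that endpoint group.  ``max_mismatches`` optionally imposes
    an absolute mismatch cap (0 for the exact-match PAR-CLIP regime) on top
    of the rate-based budget.

    Alignment records are memoised on (position, span, flag, length, NM)
    since small-RNA data is massively duplicated.
    """
    counts: dict[str, Counter] = {}
    tally = ReadTally()
    cache: dict[tuple, tuple[str, Optional[str], Optional[tuple[int, int]]]] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        refs = af.references
        for rec in af.fetch(until_eof=True) if af.has_index() else af:
            tally.total += 1
            if rec.is_unmapped:
                tally.unmapped += 1
                continue
            try:
                nm = rec.get_tag("NM")
            except KeyError:
                nm = 0
            unique = _uniqueness(rec)
            key = (rec.reference_id, rec.flag, rec.reference_start,
                   rec.reference_end, rec.query_length, nm, unique)
            hit = cache.get(key)
            if hit is None:
                read = _read_from_alignment(rec, refs[rec.reference_id], unique)
                keep, reason = filter_read(read, min_length, max_mismatch_rate, unique_mode)
                if keep and max_mismatches is not None and read.mismatches > max_mismatches:
                    keep, reason = False, MISMATCH_RATE
                if not keep:
                    hit = ("rejected", reason, None)
                else:
                    arm_id, status = assign_read(read, catalog)
                    if status == ASSIGNED:
                        arm = catalog[arm_id].arm
                        hit = (ASSIGNED, arm_id,
                               interval_to_offsets(arm, read.start, read.end))
                    else:
                        hit = (status, None, None)
                cache[key] = hit
            status, payload, offs = hit  # payload: reason or arm_id
            if status == "rejected":
                tally.rejected[payload] += 1
            elif status == ASSIGNED:
                tally.kept += 1
                tally.assigned += 1
                counts.setdefault(payload, Counter())[offs] += 1
            elif status == UNASSIGNED:
                tally.unassigned += 1
            else:
                tally.ambiguous += 1
    return counts, tally


def write_counts_tsv(
    counts: dict[str, Counter], sample_id: str, path: str | Path
) -> None:
    """Per-sample isomiR count table (one row per endpoint group)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tarm_id\tnotation\toff5\toff3\tcount\n")
        for arm_id in sorted(counts):
            for (o5, o3), n in sorted(counts[arm_id].items()):
                fh.write(
                    f"{sample_id}\t{arm_id}\t{format_notation(o5, o3)}\t{o5}\t{o3}\t{n}\n"
                )


def read_counts_tsv(path: str | Path) -> tuple[str, dict[str, Counter]]:
    """Read back a per-sample count table written by :func:`write_counts_tsv`."""
    counts: dict[str, Counter] = {}
    sample_id = ""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sample_id = f[idx["sample_id"]]
            counts.setdefault(f[idx["arm_id"]], Counter())[
                (int(f[idx["off5"]]), int(f[idx["off3"]]))
            ] += int(f[idx["count"]])
    return sample_id, counts
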