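"""miRBase-style annotation handling.

Loads precursor-arm (mature miRNA) coordinates from a miRBase-dialect GFF3
plus a genome (or hairpin) FASTA and builds, for every arm, the flanked
search window inside which reads are considered to belong to that arm.

Coordinate conventions
----------------------
Internally everything is 0-based half-open ``[start, end)``.  GFF3 I/O uses
the standard 1-based inclusive convention.  Mature sequences are stored
5'->3' of the mature strand, i.e. minus-strand entries are stored as the
reverse complement of the genomic slice.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

DEFAULT_FLANK = 6

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T's partner A)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceMature:
    """One miRBase reference mature entry (the offset origin for its arm)."""

    arm_id: str
    precursor_id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.arm_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.arm_id}: strand must be '+' or '-'")
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.arm_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmWindow:
    """A mature entry flanked on both sides; reads must fall wholly inside."""

    arm: ReferenceMature
    flank: int
    window_sequence: str = ""  # mature-strand orientation, len = mature + 2*flank

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def win_start(self) -> int:
        return self.arm.start - self.flank

    @property
    def win_end(self) -> int:
        return self.arm.end + self.flank

    def contains(self, chrom: str, strand: str, start: int, end: int) -> bool:
        return (
            chrom == self.arm.chrom
            and strand == self.arm.strand
            and start >= self.win_start
            and end <= self.win_end
        )


def offsets_to_interval(arm: ReferenceMature, off5: int, off3: int) -> tuple[int, int]:
    """Genomic interval of the isomiR with the given endpoint offsets.

    Offsets are signed in the 5'->3' direction of the mature strand:
    negative = upstream of the reference terminus.
    """
    if arm.strand == "+":
        return arm.start + off5, arm.end + off3
    return arm.start - off3, arm.end - off5


def interval_to_offsets(arm: ReferenceMature, start: int, end: int) -> tuple[int, int]:
    """Inverse of :func:`offsets_to_interval`."""
    if arm.strand == "+":
        return start - arm.start, end - arm.end
    return arm.end - end, arm.start - start


class ArmCatalog:
    """Collection of arm windows with containment lookup.

    Arms whose mature coordinates coincide exactly but carry different names
    (rare miRBase duplicates) are all kept; their ids are listed in
    :attr:`coordinate_duplicates` so downstream users can decide.
    """

    def __init__(self, windows: Iterable[ArmWindow], genome_id: str = "") -> None:
        self.genome_id = genome_id
        self._windows: dict[str, ArmWindow] = {}
        by_coord: dict[tuple, list[str]] = {}
        for w in windows:
            if w.arm.arm_id in self._windows:
                raise ValueError(f"duplicate arm_id: {w.arm.arm_id}")
            self._windows[w.arm.arm_id] = w
            by_coord.setdefault(
                (w.arm.chrom, w.arm.strand, w.arm.start, w.arm.end), []
            ).append(w.arm.arm_id)
        self.coordinate_duplicates: list[tuple[str, ...]] = [
            tuple(v) for v in by_coord.values() if len(v) > 1
        ]
        # per (chrom, strand) lists for containment lookup
        self._by_loc: dict[tuple[str, str], list[ArmWindow]] = {}
        for w in self._windows.values():
            self._by_loc.setdefault((w.arm.chrom, w.arm.strand), []).append(w)

    def __len__(self) -> int:
        return len(self._windows)

    def __iter__(self) -> Iterator[ArmWindow]:
        return iter(self._windows.values())

    def __contains__(self, arm_id: str) -> bool:
        return arm_id in self._windows

    def __getitem__(self, arm_id: str) -> ArmWindow:
        return self._windows[arm_id]

    @property
    def arm_ids(self) -> list[str]:
        return list(self._windows)

    def windows_containing(
        self, chrom: str, strand: str, start: int, end: int
    ) -> list[ArmWindow]:
        """All windows fully containing ``[start, end)`` on (chrom, strand)."""
        cand = self._by_loc.get((chrom, strand), ())
        return [w for w in cand if start >= w.win_start and end <= w.win_end]

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            out = csv.writer(fh, delimiter="\t", lineterminator="\n")
            out.writerow(
                ["arm_id", "precursor_id", "chrom", "strand", "mature_start",
                 "mature_end", "win_start", "win_end", "flank", "sequence"]
            )
            for w in self:
                a = w.arm
                out.writerow(
                    [a.arm_id, a.precursor_id, a.chrom, a.strand, a.start,
                     a.end, w.win_start, w.win_end, w.flank, a.sequence]
                )

    def to_gff3(self, path: str | Path) -> None:
        """Write mature entries back out as miRBase-dialect GFF3 (1-based)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for w in self:
                a = w.arm
                attrs = f"ID={a.arm_id};Name={a.arm_id}"
                if a.precursor_id:
                    attrs += f";Derives_from={a.precursor_id}"
                fh.write(
                    f"{a.chrom}\t.\tmiRNA\t{a.start + 1}\t{a.end}\t.\t"
                    f"{a.strand}\t.\t{attrs}\n"
                )


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def _read_gff3(path: str | Path):
    """Yield (type, chrom, start0, end, strand, attrs) for every feature."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            yield f[2], f[0], int(f[3]) - 1, int(f[4]), f[6], _parse_gff3_attributes(f[8])


def load_catalog(
    gff3_path: str | Path,
    fasta_path: str | Path,
    flank: int = DEFAULT_FLANK,
) -> ArmCatalog:
    """Build the arm-window catalog from a miRBase-style GFF3 and a FASTA.

    The FASTA may be a genome (records named after the GFF3 seqids; mature
    and window sequences are sliced out, minus-strand entries reverse
    complemented) or a per-arm FASTA keyed by the feature ``Name`` (then no
    window sequence is available and it is left empty).
    """
    seqs: dict[str, str] = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    precursor_names: dict[str, str] = {}
    matures = []
    for ftype, chrom, start, end, strand, attrs in _read_gff3(gff3_path):
        if ftype == "miRNA_primary_transcript":
            if "ID" in attrs:
                precursor_names[attrs["ID"]] = attrs.get("Name", attrs["ID"])
        elif ftype == "miRNA":
            matures.append((chrom, start, end, strand, attrs))

    windows = []
    for chrom, start, end, strand, attrs in matures:
        arm_id = attrs.get("Name") or attrs.get("ID")
        if not arm_id:
            raise ValueError(f"mature feature at {chrom}:{start}-{end} has no Name/ID")
        precursor = precursor_names.get(attrs.get("Derives_from", ""), "")
        win_seq = ""
        if chrom in seqs:
            genome = seqs[chrom]
            ws, we = start - flank, end + flank
            if ws < 0 or we > len(genome):
                raise ValueError(
                    f"{arm_id}: flanked window [{ws},{we}) outside {chrom} "
                    f"(length {len(genome)})"
                )
            mature_seq = genome[start:end]
            win_seq = genome[ws:we]
            if strand == "-":
                mature_seq = reverse_complement(mature_seq)
                win_seq = reverse_complement(win_seq)
        elif arm_id in seqs:
            mature_seq = seqs[arm_id]
        else:
            raise ValueError(f"no sequence resolvable for mature feature {arm_id}")
        arm = ReferenceMature(arm_id, precursor, chrom, start, end, strand, mature_seq)
        windows.append(ArmWindow(arm, flank, win_seq))
    return ArmCatalog(windows)
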