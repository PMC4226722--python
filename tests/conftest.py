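import numpy as np
import pytest

from isomirpipe.annotation import load_catalog


def make_genome(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def write_toy_annotation(tmp_path, genome: str, arms, flank: int = 6):
    """Write a GFF3 + FASTA for the given (name, start, end, strand) arms."""
    gff = tmp_path / "toy.gff3"
    fa = tmp_path / "toy.fa"
    lines = ["##gff-version 3"]
    for name, start, end, strand in arms:
        lines.append(
            f"chrT\t.\tmiRNA\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f"ID={name};Name={name}"
        )
    gff.write_text("\n".join(lines) + "\n")
    fa.write_text(">chrT\n" + genome + "\n")
    return gff, fa


@pytest.fixture
def toy_genome():
    return make_genome(400, seed=42)


# three arms: two overlapping plus-strand windows (for the ambiguity case)
# and one minus-strand arm
TOY_ARMS = [
    ("toy-mir-1-5p", 100, 122, "+"),
    ("toy-mir-1-3p", 112, 134, "+"),
    ("toy-mir-2-3p", 200, 222, "-"),
]


@pytest.fixture
def toy_catalog(tmp_path, toy_genome):
    gff, fa = write_toy_annotation(tmp_path, toy_genome, TOY_ARMS, flank=6)
    return load_catalog(gff, fa, flank=6)


def sam_line(qname, flag, pos0, cigar, seq, nm=0, nh=1, chrom="chrT"):
    return (f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t255\t{cigar}\t*\t0\t0"
            f"\t{seq}\t*\tNM:i:{nm}\tNH:i:{nh}\n")


@pytest.fixture
def hand_built_sam(tmp_path, toy_genome):
    """Twelve reads over the toy catalog with a hand-enumerable outcome.

    Expected: 6 assigned reads forming groups
      toy-mir-1-5p: {(0,0): 1, (-1,+2): 2}
      toy-mir-1-3p: {(0,0): 1}
      toy-mir-2-3p: {(0,0): 1, (-1,+1): 1}
    1 rejected per reason (too_short, multimapped, indel, mismatch_rate),
    1 unassigned (outside every window), 1 ambiguous (inside both
    overlapping plus-strand windows).
    """
    g = toy_genome
    header = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chrT\tLN:400\n"
    reads = [
        sam_line("r1", 0, 100, "22M", g[100:122]),                  # arm1 (0,0)
        sam_line("r2", 0, 99, "25M", g[99:124]),                    # arm1 (-1,+2)
        sam_line("r3", 0, 99, "25M", g[99:124], nm=1),              # same group, 1 mm (budget 1)
        sam_line("r4", 16, 200, "22M", g[200:222]),                 # arm3 (0,0), minus
        sam_line("r5", 16, 199, "24M", g[199:223]),                 # arm3 (-1,+1), minus
        sam_line("r6", 0, 100, "15M", g[100:115]),                  # too_short
        sam_line("r7", 0, 100, "22M", g[100:122], nh=2),            # multimapped
        sam_line("r8", 0, 100, "10M1D12M", g[100:110] + g[111:123], nm=1),  # indel
        sam_line("r9", 0, 100, "22M", g[100:122], nm=1),            # mismatch_rate (budget 0)
        sam_line("r10", 0, 50, "22M", g[50:72]),                    # unassigned
        sam_line("r11", 0, 112, "16M", g[112:128]),                 # ambiguous (both windows)
        sam_line("r12", 0, 112, "22M", g[112:134]),                 # arm2 (0,0)
    ]
    path = tmp_path / "hand.sam"
    path.write_text(header + "".join(reads))
    return path


EXPECTED_HAND_GROUPS = {
    "toy-mir-1-5p": {(0, 0): 1, (-1, 2): 2},
    "toy-mir-1-3p": {(0, 0): 1},
    "toy-mir-2-3p": {(0, 0): 1, (-1, 1): 1},
}
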