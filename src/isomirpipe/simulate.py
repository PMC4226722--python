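"""Synthetic small-RNA study generator with known ground truth.

Emulates the statistical structure of a multi-population LCL small-RNA
study: a toy genome with miRNA precursors on both strands, several isomiRs
per arm with fixed endpoint offsets and stable compositions (drawn once per
arm from a Dirichlet, with built-in margins so downstream classifications
are unambiguous at realistic depth), per-sample sequencing depths spanning a
wide log-uniform range, designated group-specific fold changes on chosen
arms, technical replicate runs that share their parent sample's composition
and expression, decoy reads that exercise every mapping filter, and
heavy-tailed PAR-CLIP distinct-species count backgrounds with spiked
Ago-loaded isomiRs.

All outputs are deterministic functions of the master seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import (
    ArmCatalog, load_catalog, offsets_to_interval, reverse_complement,
)
from .calling import format_notation, parse_notation
from .parclip import ParClipDataset, ZTNBModel, critical_count

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Spike:
    """A designated differential arm: fold change applies to one population,
    optionally restricted to one gender."""

    arm_index: int
    population: str
    gender: Optional[str]
    log2fc: float


@dataclass
class ParClipSimConfig:
    n_datasets: int = 3
    r: float = 2.0
    p: float = 0.1
    depth_multipliers: tuple[float, ...] = (1.0, 3.0, 10.0)
    n_background: int = 2000
    loaded_fraction: float = 0.45
    presence_prob: float = 0.8   # chance a non-loaded isomiR appears at background level
    spike_factor: float = 3.0    # loaded count = spike_factor x critical count


@dataclass
class SimConfig:
    """Study conditions for the generator (defaults = the 'desk' preset)."""

    n_arms: int = 30
    flank: int = 6
    populations: tuple[str, ...] = ("CEU", "FIN", "GBR", "TSI", "YRI")
    genders: tuple[str, ...] = ("F", "M")
    n_per_cell: int = 6
    depth_range: tuple[int, int] = (200_000, 2_000_000)
    dirichlet_conc: float = 12.0
    arm_lognorm_sigma: float = 1.0
    sample_noise_sigma: float = 0.0  # composition/expression shared within a group
    decoy_frac: float = 0.05
    replicate_runs: int = 6  # extra runs of one sample per population (septets)
    spikes: Optional[tuple[Spike, ...]] = None  # None -> default two-arm pattern
    parclip: ParClipSimConfig = field(default_factory=ParClipSimConfig)
    chrom: str = "chrSim"
    mature_len: int = 22
    seed: int = 0

    def resolved_spikes(self) -> tuple[Spike, ...]:
        """Two differential arms by default: one population-wide (both
        genders), one restricted to females of another population — so the
        gender-stratified comparisons are exercised."""
        if self.spikes is not None:
            return self.spikes
        return (
            Spike(self.n_arms // 3, self.populations[-1], None, 2.2),
            Spike((2 * self.n_arms) // 3, self.populations[0], "F", 1.75),
        )


def desk_preset(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def paper_shaped_preset(seed: int = 0) -> SimConfig:
    """Mirrors the real study's group sizes (87/93/94/89/89 individuals per
    population) at reduced depth; heavy — minutes to hours of I/O."""
    cfg = SimConfig(seed=seed)
    cfg.group_sizes = {"CEU": 87, "FIN": 93, "GBR": 94, "TSI": 89, "YRI": 89}  # type: ignore[attr-defined]
    return cfg


@dataclass
class TruthTable:
    """Ground truth of one simulated study."""

    compositions: dict[str, dict[tuple[int, int], float]]
    arm_weights: dict[str, float]
    spikes: list[dict]
    loaded_isomirs: set = field(default_factory=set)

    def expected_top(self, arm_id: str) -> tuple[int, int]:
        comp = self.compositions[arm_id]
        return max(comp, key=lambda k: (comp[k], -abs(k[0]), -abs(k[1])))

    def expected_retained(self, arm_id: str, cum_share: float = 0.95) -> list[tuple[int, int]]:
        """IsomiRs the cumulative-share filter should keep, from true shares."""
        comp = self.compositions[arm_id]
        order = sorted(comp, key=lambda k: (-comp[k], k[0], k[1]))
        kept, acc = [], 0.0
        for k in order:
            kept.append(k)
            acc += comp[k]
            if acc >= cum_share - 1e-12:
                break
        return kept

    def to_json(self, path: str | Path) -> None:
        payload = {
            "compositions": {
                arm: {format_notation(*k): v for k, v in comp.items()}
                for arm, comp in self.compositions.items()
            },
            "arm_weights": self.arm_weights,
            "spikes": self.spikes,
            "loaded_isomirs": sorted(
                [arm, o5, o3] for (arm, o5, o3) in self.loaded_isomirs
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ------------------------------------------------------------- annotation


def generate_annotation(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path]:
    """Write a toy genome FASTA and miRBase-style GFF3; returns their paths.

    Precursors are non-overlapping, mixed-strand, each carrying a 5p and a
    3p mature entry of ``mature_len`` nt; deterministic under the seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_prec = (config.n_arms + 1) // 2
    prec_len, spacing, margin = 80, 60, 40
    genome_len = 2 * margin + n_prec * (prec_len + spacing)
    if genome_len < n_prec * prec_len:
        raise ValueError("insufficient genome length for the requested arms")
    genome = "".join(rng.choice(_BASES, size=genome_len))

    gff_lines = ["##gff-version 3"]
    arm_count = 0
    L = config.mature_len
    for i in range(n_prec):
        p_start = margin + i * (prec_len + spacing)
        p_end = p_start + prec_len
        strand = "+" if rng.random() < 0.5 else "-"
        prec_id = f"SIMPREC{i + 1}"
        prec_name = f"sim-mir-{i + 1}"
        gff_lines.append(
            f"{config.chrom}\t.\tmiRNA_primary_transcript\t{p_start + 1}\t{p_end}"
            f"\t.\t{strand}\t.\tID={prec_id};Name={prec_name}"
        )
        left = (p_start + 4, p_start + 4 + L)
        right = (p_end - 4 - L, p_end - 4)
        # 5p arm = 5' of the precursor transcript (genomic left on +, right on -)
        arms = [("5p", left), ("3p", right)] if strand == "+" else \
               [("5p", right), ("3p", left)]
        for suffix, (s, e) in arms:
            if arm_count >= config.n_arms:
                break
            arm_count += 1
            name = f"{prec_name}-{suffix}"
            gff_lines.append(
                f"{config.chrom}\t.\tmiRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f"ID=SIMMAT{arm_count};Name={name};Derives_from={prec_id}"
            )

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{config.chrom}\n")
        for i in range(0, genome_len, 70):
            fh.write(genome[i:i + 70] + "\n")
    gff3_path = outdir / "annotation.gff3"
    gff3_path.write_text("\n".join(gff_lines) + "\n")
    return fasta_path, gff3_path


# ------------------------------------------------------------ compositions

_OFF5_CHOICES = np.array([-1, 0, 1])
_OFF5_PROBS = np.array([0.12, 0.72, 0.16])
_OFF3_CHOICES = np.array([-2, -1, 0, 1, 2])
_OFF3_PROBS = np.array([0.10, 0.24, 0.32, 0.24, 0.10])


def _draw_offsets(rng: np.random.Generator, k: int) -> list[tuple[int, int]]:
    """k distinct endpoint offset pairs, 3'-biased, always including (0,0)."""
    offsets = {(0, 0)}
    guard = 0
    while len(offsets) < k:
        o5 = int(rng.choice(_OFF5_CHOICES, p=_OFF5_PROBS))
        o3 = int(rng.choice(_OFF3_CHOICES, p=_OFF3_PROBS))
        if o5 == 0 and o3 == 0 and rng.random() < 0.8:
            continue  # keep a 3'-biased non-reference pool
        offsets.add((o5, o3))
        guard += 1
        if guard > 10_000:
            raise RuntimeError("offset pool exhausted")
    return sorted(offsets)


def _composition_ok(
    w: np.ndarray, ref_idx: int, ref_low: bool, cum_share: float = 0.95
) -> bool:
    """Margins so binomial noise cannot flip downstream classifications:
    clear top-vs-runner-up gap, prefix sums away from the cumulative-share
    boundary, top-vs-reference ratio away from the conservative 0.585 log2
    threshold, and the reference unambiguously inside (or, for ``ref_low``
    arms, outside) the retained prefix."""
    order = np.argsort(-w, kind="mergesort")
    ws = w[order]
    if ws.size > 1 and ws[0] < 1.3 * ws[1]:
        return False
    cums = np.cumsum(ws)
    if np.any(np.abs(cums[:-1] - cum_share) < 0.04):
        return False
    ref_rank = int(np.where(order == ref_idx)[0][0])
    prefix_before_ref = float(cums[ref_rank - 1]) if ref_rank else 0.0
    if ref_low:
        # reference must sit strictly past the cumulative-share cutoff
        if prefix_before_ref < cum_share + 0.02:
            return False
    else:
        if prefix_before_ref > cum_share - 0.04:
            return False
        if order[0] != ref_idx and abs(
                math.log2(ws[0] / max(w[ref_idx], 1e-9)) - 0.585) < 0.15:
            return False
    return True


def _arm_composition(
    rng: np.random.Generator, offsets: list[tuple[int, int]], conc: float,
    ref_low: bool,
) -> dict[tuple[int, int], float]:
    """Draw one margin-respecting composition; ``ref_low`` arms emulate loci
    where the miRBase reference is expressed but falls outside the retained
    95%-share prefix (about a third of arms in LCL data)."""
    k = len(offsets)
    ref_idx = offsets.index((0, 0))
    for _ in range(5000):
        if ref_low and k >= 2:
            eps = rng.uniform(0.002, 0.01)
            w_rest = rng.dirichlet(np.full(k - 1, conc / k)) * (1.0 - eps)
            w = np.insert(w_rest, ref_idx, eps)
        else:
            w = rng.dirichlet(np.full(k, conc / k))
        if w.min() < 1e-4:
            continue
        if _composition_ok(w, ref_idx, ref_low):
            return {off: float(p) for off, p in zip(offsets, w)}
    raise RuntimeError("could not draw a margin-respecting composition")


def build_truth(config: SimConfig, catalog: ArmCatalog) -> TruthTable:
    """Draw per-arm isomiR compositions and arm expression weights."""
    rng = np.random.default_rng([config.seed, 2])
    compositions: dict[str, dict[tuple[int, int], float]] = {}
    arm_weights: dict[str, float] = {}
    for arm_id in catalog.arm_ids:
        k = int(rng.integers(2, 6))
        offsets = _draw_offsets(rng, k)
        ref_low = k >= 3 and rng.random() < 0.3
        compositions[arm_id] = _arm_composition(
            rng, offsets, config.dirichlet_conc, ref_low)
        arm_weights[arm_id] = float(rng.lognormal(0.0, config.arm_lognorm_sigma))
    spikes = [
        {"arm_id": catalog.arm_ids[s.arm_index], "population": s.population,
         "gender": s.gender, "log2fc": s.log2fc}
        for s in config.resolved_spikes()
    ]
    return TruthTable(compositions=compositions, arm_weights=arm_weights, spikes=spikes)


# ----------------------------------------------------------------- samples


def _sample_plan(config: SimConfig) -> list[dict]:
    """Sample sheet: unique samples per (population x gender) cell plus
    technical replicate runs of the first female sample of each population."""
    sizes = getattr(config, "group_sizes", None)
    plan = []
    for pop in config.populations:
        if sizes:
            total = sizes[pop]
            per_gender = [total - total // 2, total // 2]
        else:
            per_gender = [config.n_per_cell] * len(config.genders)
        for gender, n in zip(config.genders, per_gender):
            for i in range(n):
                plan.append({"sample_id": f"{pop}_{gender}{i + 1}",
                             "population": pop, "gender": gender, "replicate_of": ""})
    for pop in config.populations:
        parent = f"{pop}_{config.genders[0]}1"
        for k in range(config.replicate_runs):
            plan.append({"sample_id": f"{parent}_r{k + 1}", "population": pop,
                         "gender": config.genders[0], "replicate_of": parent})
    return plan


def _sam_header(config: SimConfig, genome_len: int) -> str:
    return f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{config.chrom}\tLN:{genome_len}\n"


def _category_templates(
    config: SimConfig, catalog: ArmCatalog, truth: TruthTable, genome: str
) -> tuple[list[tuple[str, tuple[int, int]]], list[str]]:
    """One prebuilt SAM line per (arm, isomiR) category."""
    keys: list[tuple[str, tuple[int, int]]] = []
    lines: list[str] = []
    cat_i = 0
    for arm_id in catalog.arm_ids:
        arm = catalog[arm_id].arm
        for (o5, o3) in truth.compositions[arm_id]:
            s, e = offsets_to_interval(arm, o5, o3)
            seq = genome[s:e]
            flag = 0
            if arm.strand == "-":
                seq = reverse_complement(seq)
                flag = 16
            lines.append(
                f"c{cat_i}\t{flag}\t{config.chrom}\t{s + 1}\t255\t{e - s}M\t*\t0\t0"
                f"\t{seq}\t*\tNM:i:0\tNH:i:1\n"
            )
            keys.append((arm_id, (o5, o3)))
            cat_i += 1
    return keys, lines


def _decoy_templates(config: SimConfig, catalog: ArmCatalog, genome: str) -> list[str]:
    """One template per decoy class: too-short, multimapped (two records),
    indel-bearing, out-of-window, over-the-mismatch-budget."""
    arm0 = catalog[catalog.arm_ids[0]].arm
    w0 = catalog[catalog.arm_ids[0]]
    chrom = config.chrom
    intergenic = w0.win_end + 10  # in the spacer, outside every window
    s = arm0.start

    def line(qname, flag, pos, cigar, seq, nm, nh):
        return (f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0"
                f"\t{seq}\t*\tNM:i:{nm}\tNH:i:{nh}\n")

    too_short = line("d_short", 0, s, "14M", genome[s:s + 14], 0, 1)
    multi = (line("d_multi", 0, s, "22M", genome[s:s + 22], 0, 2)
             + line("d_multi", 256, intergenic, "22M",
                    genome[intergenic:intergenic + 22], 0, 2))
    indel = line("d_indel", 0, s, "10M1D12M", genome[s:s + 10] + genome[s + 11:s + 23], 1, 1)
    outside = line("d_out", 0, intergenic, "22M",
                   genome[intergenic:intergenic + 22], 0, 1)
    mism = line("d_mm", 0, s, "20M", genome[s:s + 20], 1, 1)  # budget floor(0.8)=0
    return [too_short, multi, indel, outside, mism]


def _write_sam(path: Path, header: str, lines: Sequence[str], counts: np.ndarray,
               chunk: int = 4096) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        for line, k in zip(lines, counts):
            k = int(k)
            while k > 0:
                b = min(k, chunk)
                fh.write(line * b)
                k -= b


def simulate_samples(
    config: SimConfig,
    catalog: ArmCatalog,
    truth: TruthTable,
    outdir: str | Path,
    genome: str,
) -> tuple[list[Path], Path]:
    """Write per-sample SAM files and the metadata TSV.

    Per sample: depth ~ log-uniform over ``depth_range``; reads multinomial
    over (arm, isomiR) categories with probabilities proportional to
    arm weight x group fold change x per-sample jitter x composition;
    replicate runs reuse their parent's probabilities and redraw only the
    depth and the multinomial noise.  ``decoy_frac`` of each sample's reads
    are decoys exercising the mapping filters.
    """
    rng = np.random.default_rng([config.seed, 3])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_len = len(genome)
    header = _sam_header(config, genome_len)
    cat_keys, cat_lines = _category_templates(config, catalog, truth, genome)
    decoy_lines = _decoy_templates(config, catalog, genome)

    base_w = np.array([
        truth.arm_weights[arm] * truth.compositions[arm][off]
        for arm, off in cat_keys
    ])
    arm_of_cat = np.array([catalog.arm_ids.index(arm) for arm, _ in cat_keys])

    plan = _sample_plan(config)
    lo, hi = config.depth_range
    parent_probs: dict[str, np.ndarray] = {}
    sam_paths = []
    for row in plan:
        sid, pop, gender = row["sample_id"], row["population"], row["gender"]
        if row["replicate_of"]:
            probs = parent_probs[row["replicate_of"]]
        else:
            mult = np.ones(len(catalog.arm_ids))
            for sp in truth.spikes:
                if sp["population"] == pop and (sp["gender"] in (None, "", gender)):
                    mult[catalog.arm_ids.index(sp["arm_id"])] *= 2.0 ** sp["log2fc"]
            if config.sample_noise_sigma > 0:
                mult = mult * rng.lognormal(0.0, config.sample_noise_sigma,
                                            size=len(catalog.arm_ids))
            w = base_w * mult[arm_of_cat]
            probs = w / w.sum()
            parent_probs[sid] = probs
        depth = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        n_decoy = int(round(config.decoy_frac * depth))
        n_main = depth - n_decoy
        counts = rng.multinomial(n_main, probs)
        path = outdir / f"{sid}.sam"
        _write_sam(path, header, cat_lines, counts)
        if n_decoy:
            dcounts = rng.multinomial(n_decoy, np.full(len(decoy_lines),
                                                       1.0 / len(decoy_lines)))
            with open(path, "a") as fh:
                for line, k in zip(decoy_lines, dcounts):
                    fh.write(line * int(k))
        sam_paths.append(path)

    meta_path = outdir / "metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tpopulation\tgender\treplicate_of\n")
        for row in plan:
            fh.write(f"{row['sample_id']}\t{row['population']}\t{row['gender']}"
                     f"\t{row['replicate_of']}\n")
    return sam_paths, meta_path


# ----------------------------------------------------------------- PAR-CLIP


def _scaled_p(p: float, mult: float) -> float:
    """NB success probability whose mean is ``mult`` times the original."""
    mean_ratio = mult * (1 - p) / p
    return 1.0 / (1.0 + mean_ratio)


def _ztnb_draws(rng: np.random.Generator, r: float, p: float, n: int,
                floor: int = 1) -> np.ndarray:
    lo = stats.nbinom.cdf(floor - 1, r, p)
    u = rng.uniform(lo, 1.0, size=n)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


def simulate_parclip(
    config: SimConfig,
    catalog: ArmCatalog,
    truth: TruthTable,
    outdir: Optional[str | Path] = None,
) -> tuple[list[ParClipDataset], dict[str, tuple[Hashable, bool]]]:
    """Simulate PAR-CLIP distinct-species count tables with spiked loading.

    Background species counts follow a ZTNB whose mean scales with each
    dataset's depth multiplier.  A ``loaded_fraction`` of isomiRs is
    designated truly Ago-loaded (recorded in ``truth.loaded_isomirs``): each
    receives, in at least one dataset, a count ``spike_factor`` times that
    dataset's 0.05 critical count.  Non-loaded isomiRs appear at background
    level with probability ``presence_prob``.

    Returns the datasets and the isomiR key map (id -> (endpoint key,
    is_reference)) used by the support caller.
    """
    pc = config.parclip
    rng = np.random.default_rng([config.seed, 4])
    iso_keys: dict[str, tuple[Hashable, bool]] = {}
    iso_list: list[tuple[str, Hashable]] = []
    for arm_id in catalog.arm_ids:
        arm = catalog[arm_id].arm
        for (o5, o3) in truth.compositions[arm_id]:
            s, e = offsets_to_interval(arm, o5, o3)
            key = (arm.chrom, arm.strand, s, e)
            iso_id = f"{arm_id}|{format_notation(o5, o3)}"
            iso_keys[iso_id] = (key, o5 == 0 and o3 == 0)
            iso_list.append((iso_id, key))

    n_iso = len(iso_list)
    loaded_idx = rng.choice(n_iso, size=int(round(pc.loaded_fraction * n_iso)),
                            replace=False)
    loaded = set(int(i) for i in loaded_idx)
    # every loaded isomiR gets its spike in at least this one dataset
    designated = {i: int(rng.integers(0, pc.n_datasets)) for i in sorted(loaded)}
    for i in sorted(loaded):
        iso_id = iso_list[i][0]
        arm_id, notation = iso_id.split("|")
        o5, o3 = parse_notation(notation)
        truth.loaded_isomirs.add((arm_id, o5, o3))

    datasets = []
    for d in range(pc.n_datasets):
        mult = pc.depth_multipliers[d % len(pc.depth_multipliers)]
        p_d = _scaled_p(pc.p, mult)
        model = ZTNBModel(r=pc.r, p=p_d, dataset_id=f"parclip{d + 1}")
        c_star = critical_count(model)
        counts: dict[Hashable, int] = {}
        # background (non-isomiR) species in intergenic space
        bg = _ztnb_draws(rng, pc.r, p_d, pc.n_background)
        for j, c in enumerate(bg):
            counts[("bg", "+", 10_000_000 + 30 * j, 10_000_000 + 30 * j + 22)] = int(c)
        # isomiR species
        in_this = rng.random(n_iso)
        for i, (iso_id, key) in enumerate(iso_list):
            if i in loaded:
                if d == designated[i] or in_this[i] < 0.7:
                    counts[key] = int(math.ceil(pc.spike_factor * c_star)
                                      + rng.integers(0, max(2, c_star // 4)))
                elif in_this[i] < 0.9:
                    counts[key] = int(_ztnb_draws(rng, pc.r, p_d, 1)[0])
            else:
                if in_this[i] < pc.presence_prob:
                    counts[key] = int(_ztnb_draws(rng, pc.r, p_d, 1)[0])
        ds = ParClipDataset(f"parclip{d + 1}", counts)
        datasets.append(ds)
        if outdir is not None:
            out = Path(outdir) / f"{ds.dataset_id}.tsv"
            with open(out, "w") as fh:
                fh.write("chrom\tstrand\tstart\tend\tcount\n")
                for (chrom, strand, s, e), c in counts.items():
                    fh.write(f"{chrom}\t{strand}\t{s}\t{e}\t{c}\n")
    return datasets, iso_keys


# ------------------------------------------------------------- one-stop API


def simulate_all(config: SimConfig, outdir: str | Path) -> dict:
    """Generate annotation, samples, PAR-CLIP data and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path, gff3_path = generate_annotation(config, outdir)
    catalog = load_catalog(gff3_path, fasta_path, flank=config.flank)
    truth = build_truth(config, catalog)
    genome = _read_single_fasta(fasta_path)
    sam_paths, meta_path = simulate_samples(config, catalog, truth,
                                            outdir / "samples", genome)
    parclip_dir = outdir / "parclip"
    parclip_dir.mkdir(exist_ok=True)
    datasets, iso_keys = simulate_parclip(config, catalog, truth, parclip_dir)
    truth.to_json(outdir / "truth.json")
    return {
        "fasta": fasta_path, "gff3": gff3_path, "catalog": catalog,
        "truth": truth, "sam_paths": sam_paths, "metadata": meta_path,
        "parclip_datasets": datasets, "parclip_keys": iso_keys,
        "parclip_dir": parclip_dir,
    }


def _read_single_fasta(path: str | Path) -> str:
    seq_lines = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(">"):
                seq_lines.append(line.strip())
    return "".join(seq_lines)
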