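"""End-to-end orchestration: calling -> quantification -> filters ->
summaries -> differential expression -> termini grids -> PAR-CLIP support,
with a manifest recording parameters, package version and input digests, and
replicate-concordance diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .annotation import ArmCatalog, load_catalog, offsets_to_interval
from .calling import count_sam
from .de import enumerate_contrasts, estimate_size_factors, nb_test
from .parclip import read_parclip_tsv, support_table
from .quantify import (
    CONSERVATIVE_LOG2, build_matrix, filter_isomirs, isomir_ttests,
    read_metadata, summarize_arms, write_matrix_tsv,
)
from .termini import termini_grid, termini_points

log = logging.getLogger("isomirpipe")


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    gff3: str
    fasta: str
    alignments: dict[str, str]          # sample_id -> SAM/BAM path
    metadata: str
    outdir: str
    parclip: dict[str, str] = field(default_factory=dict)  # id -> count TSV
    flank: int = 6
    min_top_mean: float = 25.0
    cum_share: float = 0.95
    alpha: float = 0.05
    conservative_log2: float = CONSERVATIVE_LOG2  # log2(1.5), printed as 0.585
    unique_mode: str = "strict"
    contrasts: Optional[list[tuple[str, str, Optional[str]]]] = None
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.cum_share <= 1 and 0 < self.alpha < 1
                and self.flank >= 0 and self.min_top_mean >= 0):
            raise ValueError("pipeline thresholds out of range")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the in-memory results and writes TSVs plus a
    manifest to ``config.outdir``.  A stage failure aborts with the stage
    name and the offending input in the exception message."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - reraised with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    catalog: ArmCatalog = _stage("annotation", load_catalog,
                                 config.gff3, config.fasta, config.flank)
    metadata = _stage("metadata", read_metadata, config.metadata)
    missing = set(config.alignments) - set(metadata.index)
    if missing:
        raise RuntimeError(
            f"pipeline stage 'metadata' failed: samples without metadata: {sorted(missing)}")

    sample_counts, tallies = {}, {}
    for sid, path in config.alignments.items():
        counts, tally = _stage(f"calling:{sid}", count_sam, path, catalog,
                               unique_mode=config.unique_mode)
        sample_counts[sid] = counts
        tallies[sid] = tally
        log.info("calling %s: total=%d assigned=%d ambiguous=%d rejected=%d",
                 sid, tally.total, tally.assigned, tally.ambiguous,
                 tally.rejected_total)

    matrix = _stage("matrix", build_matrix, sample_counts, metadata)
    matrix.normalize()
    uniq = matrix.unique_samples()
    filtered = _stage("filter", filter_isomirs, matrix.normalized, uniq,
                      config.min_top_mean, config.cum_share)
    per_arm, aggregate = _stage("summaries", summarize_arms, filtered,
                                matrix.normalized, uniq,
                                config.conservative_log2)
    ttests = _stage("ttests", isomir_ttests, filtered, uniq)

    size_factors = _stage("size_factors", estimate_size_factors,
                          matrix.raw[uniq]) if len(uniq) >= 2 else None
    contrasts = config.contrasts
    if contrasts is None:
        contrasts = enumerate_contrasts(metadata.loc[uniq])
    de_results = {}
    raw_filtered = matrix.raw.loc[filtered.index]
    for pop_a, pop_b, gender in contrasts:
        ga = matrix.group_samples(population=pop_a, gender=gender)
        gb = matrix.group_samples(population=pop_b, gender=gender)
        if len(ga) < 2 or len(gb) < 2:
            warnings.warn(f"skipping contrast {pop_a} vs {pop_b} (gender={gender}): "
                          "fewer than 2 samples per group")
            continue
        label = f"{pop_a}_vs_{pop_b}" + (f"_{gender}" if gender else "")
        de_results[label] = _stage(f"de:{label}", nb_test, raw_filtered,
                                   size_factors, ga, gb)

    all_points = []
    groups = metadata.loc[uniq].groupby(["population", "gender"]).groups
    for (pop, gender), _ in sorted(groups.items()):
        cols = matrix.group_samples(population=pop, gender=gender)
        pts = termini_points(filtered, cols, group=f"{pop}_{gender}")
        all_points.append(pts)
    points = pd.concat(all_points, ignore_index=True) if all_points else pd.DataFrame()
    grid, marginals = _stage("termini", termini_grid, points, config.flank)

    concordance = replicate_concordance(matrix.normalized, metadata)

    parclip_out = None
    if config.parclip:
        datasets = [read_parclip_tsv(p, d) for d, p in config.parclip.items()]
        iso_keys = {}
        for (arm_id, o5, o3) in filtered.index:
            arm = catalog[arm_id].arm
            s, e = offsets_to_interval(arm, o5, o3)
            iso_keys[f"{arm_id}|{o5}|{o3}"] = (
                (arm.chrom, arm.strand, s, e), o5 == 0 and o3 == 0)
        parclip_out = _stage("parclip", support_table, iso_keys, datasets,
                             config.alpha)

    # ------------------------------------------------------------- outputs
    write_matrix_tsv(matrix.raw, outdir / "counts_raw.tsv")
    write_matrix_tsv(matrix.normalized, outdir / "counts_normalized.tsv")
    write_matrix_tsv(filtered, outdir / "counts_filtered.tsv")
    per_arm.to_csv(outdir / "arm_summary.tsv", sep="\t")
    ttests.to_csv(outdir / "isomir_ttests.tsv", sep="\t")
    aggregate.to_csv(outdir / "arm_summary_aggregate.tsv", sep="\t", index=False)
    grid.to_csv(outdir / "termini_grid.tsv", sep="\t", index=False)
    marginals.to_csv(outdir / "termini_marginals.tsv", sep="\t", index=False)
    concordance.to_csv(outdir / "replicate_concordance.tsv", sep="\t", index=False)
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    sig_long = []
    for label, table in de_results.items():
        table.to_csv(de_dir / f"{label}.tsv", sep="\t")
        sig = table[table["FDR"] <= config.alpha]
        for key, row in sig.iterrows():
            sig_long.append({"contrast": label, "arm_id": key[0], "off5": key[1],
                             "off3": key[2], "log2FoldChange": row["log2FoldChange"],
                             "FDR": row["FDR"]})
    pd.DataFrame(sig_long, columns=["contrast", "arm_id", "off5", "off3",
                                    "log2FoldChange", "FDR"]
                 ).to_csv(outdir / "de_significant_long.tsv", sep="\t", index=False)
    if parclip_out is not None:
        parclip_out[0].to_csv(outdir / "parclip_support.tsv", sep="\t")
        parclip_out[1].to_csv(outdir / "parclip_summary.tsv", sep="\t", index=False)

    tally_rows = [{"sample_id": sid, "total": t.total, "assigned": t.assigned,
                   "unassigned": t.unassigned, "ambiguous": t.ambiguous,
                   "unmapped": t.unmapped, **{f"rejected_{k}": v
                                              for k, v in t.rejected.items()}}
                  for sid, t in tallies.items()]
    pd.DataFrame(tally_rows).to_csv(outdir / "read_tallies.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("alignments", "parclip", "outdir")},
        "inputs": {
            "gff3": _digest(config.gff3),
            "fasta": _digest(config.fasta),
            "metadata": _digest(config.metadata),
            "alignments": {sid: _digest(p) for sid, p in config.alignments.items()},
            "parclip": {d: _digest(p) for d, p in config.parclip.items()},
        },
    }
    manifest["digest"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    results.update(dict(
        catalog=catalog, matrix=matrix, filtered=filtered, per_arm=per_arm,
        aggregate=aggregate, ttests=ttests, de=de_results, termini_grid=grid,
        termini_marginals=marginals, concordance=concordance,
        parclip=parclip_out, tallies=tallies, manifest=manifest,
    ))
    return results


def replicate_concordance(
    normalized: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Spearman and Pearson correlations over the normalized isomiR vector
    for every pair within each technical-replicate group (parent + reruns).
    """
    md = metadata.loc[[s for s in normalized.columns]]
    rep = md["replicate_of"].fillna("").astype(str).str.strip()
    groups: dict[str, list[str]] = {}
    for sid in normalized.columns:
        parent = rep.loc[sid] or sid
        groups.setdefault(parent, []).append(sid)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if not groups:
        warnings.warn("no replicate groups with >= 2 members")
    rows = []
    for parent, members in groups.items():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                x, y = normalized[a].to_numpy(), normalized[b].to_numpy()
                rows.append({
                    "group": parent, "sample_a": a, "sample_b": b,
                    "spearman": float(sps.spearmanr(x, y).statistic),
                    "pearson": float(sps.pearsonr(x, y).statistic),
                })
    return pd.DataFrame(rows, columns=["group", "sample_a", "sample_b",
                                       "spearman", "pearson"])
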