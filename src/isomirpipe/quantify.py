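"""IsomiR quantification: count matrix, quantile normalization, abundance
filters, and per-arm top-isomiR summaries.

The matrix holds isomiRs as rows (MultiIndex ``(arm_id, off5, off3)``) and
samples as columns.  Normalization is the classic rank-mean quantile
procedure; the abundance filters are (a) drop an arm unless its top isomiR
averages >= 25 normalized reads per sample, and (b) within a kept arm retain
the smallest abundance-ranked prefix of isomiRs covering >= 95% of the arm's
reads, iterated to a fixed point so the filter is idempotent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Counter as CounterT, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import format_notation

MIN_TOP_MEAN = 25.0
CUM_SHARE = 0.95
# the conventional "0.585 log2 units" is the rounded value of log2(1.5);
# using the exact constant makes an exactly 1.5-fold ratio qualify
CONSERVATIVE_LOG2 = math.log2(1.5)

ROW_LEVELS = ("arm_id", "off5", "off3")


@dataclass
class CountMatrix:
    """isomiR x sample counts with raw and normalized layers plus metadata."""

    raw: pd.DataFrame
    metadata: pd.DataFrame
    normalized: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = set(self.raw.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def unique_samples(self) -> list[str]:
        """Samples that are not technical replicate re-runs."""
        md = self.metadata.loc[self.samples]
        rep = md["replicate_of"].fillna("") if "replicate_of" in md else ""
        return [s for s in self.samples if not str(rep.loc[s]).strip()]

    def group_samples(
        self, population: Optional[str] = None, gender: Optional[str] = None,
        include_replicates: bool = False,
    ) -> list[str]:
        md = self.metadata.loc[self.samples]
        keep = pd.Series(True, index=md.index)
        if population is not None:
            keep &= md["population"] == population
        if gender is not None:
            keep &= md["gender"] == gender
        if not include_replicates and "replicate_of" in md:
            keep &= md["replicate_of"].fillna("").astype(str).str.strip() == ""
        return [s for s in self.samples if keep.loc[s]]

    def normalize(self) -> pd.DataFrame:
        self.normalized = quantile_normalize(self.raw)
        return self.normalized


def build_matrix(
    sample_counts: Mapping[str, Mapping[str, CounterT]],
    metadata: pd.DataFrame,
) -> CountMatrix:
    """Assemble the isomiR x sample raw count matrix (missing isomiRs = 0)."""
    rows: dict[tuple, dict[str, int]] = {}
    for sample, per_arm in sample_counts.items():
        for arm_id, groups in per_arm.items():
            for (o5, o3), n in groups.items():
                rows.setdefault((arm_id, o5, o3), {})[sample] = n
    index = pd.MultiIndex.from_tuples(sorted(rows), names=ROW_LEVELS)
    df = pd.DataFrame(
        [[rows[key].get(s, 0) for s in sample_counts] for key in index],
        index=index, columns=list(sample_counts), dtype=np.int64,
    )
    return CountMatrix(raw=df, metadata=metadata)


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_id", "population", "gender"):
        if col not in md.columns:
            raise ValueError(f"metadata is missing required column '{col}'")
    if "replicate_of" not in md.columns:
        md["replicate_of"] = ""
    return md.set_index("sample_id")


# ------------------------------------------------------------ normalization


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization across columns.

    Each column's sorted values are replaced by the across-column mean at
    every rank; within a column, tied values receive the mean of their tied
    rank-means, so the transform is well defined and order independent.
    """
    if df.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return df.astype(float).copy()
    X = df.to_numpy(dtype=float)
    n = X.shape[0]
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        by_rank = np.empty(n)
        by_rank[order] = rank_means
        # average rank-means over ties
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=by_rank)
        cnts = np.bincount(inv)
        out[:, j] = (sums / cnts)[inv]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ------------------------------------------------------------------ filters


def _arm_order(sub_means: pd.Series) -> list[tuple]:
    """Abundance-descending row order, ties broken by (off5, off3)."""
    return sorted(sub_means.index, key=lambda k: (-sub_means[k], k[1], k[2]))


def _prefix_keep(values: np.ndarray, cum_share: float) -> int:
    """Length of the minimal prefix whose cumulative share >= cum_share."""
    total = values.sum()
    if total <= 0:
        return 0
    cum = np.cumsum(values)
    return int(np.searchsorted(cum, cum_share * total - 1e-12) + 1)


def filter_isomirs(
    normalized: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    min_top_mean: float = MIN_TOP_MEAN,
    cum_share: float = CUM_SHARE,
) -> pd.DataFrame:
    """Apply the abundance filters over the analysis group ``samples``.

    Per arm: the arm is dropped unless its most abundant isomiR has mean
    normalized count >= ``min_top_mean``; within a kept arm, isomiRs are
    ranked by mean abundance and the smallest prefix covering
    >= ``cum_share`` of the arm's reads is retained.  The prefix rule is
    iterated until stable, which makes the whole filter idempotent.
    """
    if normalized.empty:
        return normalized.copy()
    cols = list(samples) if samples is not None else list(normalized.columns)
    means = normalized[cols].mean(axis=1)
    kept_rows: list[tuple] = []
    for arm_id, sub in means.groupby(level="arm_id", sort=False):
        order = _arm_order(sub)
        if sub[order[0]] < min_top_mean:
            continue
        vals = np.array([sub[k] for k in order], dtype=float)
        k = len(order)
        while True:
            k_new = _prefix_keep(vals[:k], cum_share)
            if k_new == k or k_new == 0:
                k = k_new
                break
            k = k_new
        kept_rows.extend(order[:k])
    if not kept_rows:
        return normalized.iloc[0:0]
    return normalized.loc[pd.MultiIndex.from_tuples(kept_rows, names=ROW_LEVELS)]


# ------------------------------------------------------------------- t-test


def one_sample_ttest(
    values: Sequence[float],
    null_value: float = 0.0,
    transform: str = "log2p1",
) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test; returns (t, p, degenerate).

    ``transform`` is applied to the values first: "log2p1" -> log2(x + 1)
    (the default for normalized counts tested against 0), or "identity".
    Zero sample variance is degenerate: p = 1 when the common value equals
    the null, else p = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one_sample_ttest requires at least 2 samples")
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "identity":
        raise ValueError(f"unknown transform: {transform}")
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0.0:
        if mean == null_value:
            return 0.0, 1.0, True
        return math.copysign(math.inf, mean - null_value), 0.0, True
    t = (mean - null_value) / (sd / math.sqrt(x.size))
    p = 2.0 * stats.t.sf(abs(t), df=x.size - 1)
    return float(t), float(p), False


def isomir_ttests(
    normalized: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    null_value: float = 0.0,
    transform: str = "log2p1",
) -> pd.DataFrame:
    cols = list(samples) if samples is not None else list(normalized.columns)
    rows = [
        one_sample_ttest(normalized.loc[key, cols], null_value, transform)
        for key in normalized.index
    ]
    return pd.DataFrame(rows, index=normalized.index, columns=["t", "p", "degenerate"])


# ----------------------------------------------------------- arm summaries

DISAGREE_NONE = "none"
DISAGREE_5P = "5p_only"
DISAGREE_3P = "3p_only"
DISAGREE_BOTH = "both"


def _category(off5: int, off3: int) -> str:
    if off5 == 0 and off3 == 0:
        return DISAGREE_NONE
    if off5 != 0 and off3 != 0:
        return DISAGREE_BOTH
    return DISAGREE_5P if off5 != 0 else DISAGREE_3P


def summarize_arms(
    filtered: pd.DataFrame,
    normalized_full: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    conservative_log2: float = CONSERVATIVE_LOG2,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-arm top-isomiR classification and aggregate counts.

    For every retained arm: the most abundant isomiR, whether it matches the
    reference (0,0) entry, how it disagrees (5' only / 3' only / both /
    none), a conservative flag (top exceeds reference by >= 0.585 log2
    units, pseudocounted), and whether the reference survived the
    cumulative-share filter.  The aggregate table mirrors the count +
    percentage structure of the per-population statistics.
    """
    cols = list(samples) if samples is not None else list(filtered.columns)
    records = []
    for arm_id, sub in filtered[cols].mean(axis=1).groupby(level="arm_id", sort=False):
        order = _arm_order(sub)
        top = order[0]
        _, o5, o3 = top
        ref_key = (arm_id, 0, 0)
        ref_in_95th = ref_key in sub.index
        if ref_key in normalized_full.index:
            ref_mean = float(normalized_full.loc[ref_key, cols].mean())
        else:
            ref_mean = 0.0  # reference never observed: pseudocount floor applies
        top_mean = float(sub[top])
        lfc = math.log2(top_mean + pseudocount) - math.log2(ref_mean + pseudocount)
        records.append({
            "arm_id": arm_id,
            "top_off5": o5,
            "top_off3": o3,
            "top_notation": format_notation(o5, o3),
            "top_mean": top_mean,
            "reference_mean": ref_mean,
            "top_matches_reference": o5 == 0 and o3 == 0,
            "category": _category(o5, o3),
            "conservative_flag": (not (o5 == 0 and o3 == 0))
            and lfc >= conservative_log2 - 1e-12,
            "reference_in_95th": ref_in_95th,
            "n_isomirs": len(order),
        })
    per_arm = pd.DataFrame.from_records(records).set_index("arm_id") if records \
        else pd.DataFrame(columns=["category"])
    n = len(per_arm)

    def _row(label: str, count: int) -> dict:
        return {"statistic": label, "count": count,
                "percentage": round(100.0 * count / n) if n else 0.0}

    cat = per_arm["category"] if n else pd.Series(dtype=object)
    agg = pd.DataFrame([
        _row("arms_considered", n),
        _row("reference_not_in_95th", int((~per_arm["reference_in_95th"]).sum()) if n else 0),
        _row("top_disagrees", int((~per_arm["top_matches_reference"]).sum()) if n else 0),
        _row("top_disagrees_conservative", int(per_arm["conservative_flag"].sum()) if n else 0),
        _row("disagrees_5p", int(cat.isin([DISAGREE_5P, DISAGREE_BOTH]).sum())),
        _row("disagrees_5p_only", int((cat == DISAGREE_5P).sum())),
        _row("disagrees_3p", int(cat.isin([DISAGREE_3P, DISAGREE_BOTH]).sum())),
        _row("disagrees_3p_only", int((cat == DISAGREE_3P).sum())),
        _row("disagrees_both", int((cat == DISAGREE_BOTH).sum())),
    ])
    return per_arm, agg


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=[0, 1, 2])
    df.index.names = ROW_LEVELS
    return df
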