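"""Argonaute-loading support from PAR-CLIP read counts.

Each PAR-CLIP dataset is a table of distinct sequence species and their read
counts.  A zero-truncated negative binomial (ZTNB) is fitted per dataset to
the distinct-species count background (observed species have at least one
read, hence the truncation), and an isomiR is called Ago-loaded when its
exact-endpoint read count is in the upper tail (P(X >= c) <= alpha) of its
own dataset's fitted background in at least one dataset.  Fitting per
dataset matters because the count needed for significance grows with
sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

ALPHA = 0.05


@dataclass
class ParClipDataset:
    """One PAR-CLIP dataset: distinct species (any hashable key) -> count."""

    dataset_id: str
    counts: dict[Hashable, int]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.counts.items() if v < 1]
        if bad:
            raise ValueError(f"{self.dataset_id}: counts must be >= 1 (observed species)")

    @property
    def depth(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ZTNBModel:
    """Fitted zero-truncated negative binomial background."""

    r: float          # size (inverse dispersion)
    p: float          # NB success probability; mean = r (1-p)/p
    dataset_id: str = ""
    loglik: float = float("nan")
    floor: int = 1    # counts < floor are unobservable

    def logpmf(self, k) -> np.ndarray:
        k = np.asarray(k)
        lp = stats.nbinom.logpmf(k, self.r, self.p)
        norm = stats.nbinom.logsf(self.floor - 1, self.r, self.p)
        return np.where(k >= self.floor, lp - norm, -np.inf)

    def pmf(self, k) -> np.ndarray:
        return np.exp(self.logpmf(k))

    def sf_inclusive(self, c: int) -> float:
        """P(X >= c) under the truncated law."""
        if c <= self.floor:
            return 1.0
        num = stats.nbinom.sf(c - 1, self.r, self.p)
        den = stats.nbinom.sf(self.floor - 1, self.r, self.p)
        return float(num / den)


def _ztnb_negloglik(params: np.ndarray, ks: np.ndarray, ws: np.ndarray, floor: int) -> float:
    log_r, logit_p = params
    r = np.exp(log_r)
    p = 1.0 / (1.0 + np.exp(-logit_p))
    if not (np.isfinite(r) and 0.0 < p < 1.0):
        return np.inf
    lp = stats.nbinom.logpmf(ks, r, p) - stats.nbinom.logsf(floor - 1, r, p)
    val = -(ws * lp).sum()
    return val if np.isfinite(val) else np.inf


def _mom_start(counts: np.ndarray) -> tuple[float, float]:
    m, v = counts.mean(), counts.var(ddof=1)
    if v <= m:
        v = m * 1.5 + 1e-6
    r = m * m / (v - m)
    p = m / v
    return max(r, 1e-3), min(max(p, 1e-6), 1 - 1e-6)


def fit_ztnb(
    counts: Sequence[int], dataset_id: str = "", floor: int = 1
) -> ZTNBModel:
    """Maximum-likelihood ZTNB fit to observed species counts (all >= floor).

    Starts from the untruncated method-of-moments estimate and optimizes
    (log r, logit p) with Nelder-Mead.  Degenerate data (all counts equal)
    and non-convergence raise informative errors.
    """
    ks = np.asarray(counts, dtype=np.int64)
    if ks.size < 50:
        raise ValueError(f"need >= 50 counts to fit a background, got {ks.size}")
    if (ks < floor).any():
        raise ValueError(f"all counts must be >= truncation floor {floor}")
    if np.ptp(ks) == 0:
        raise ValueError(
            "degenerate data: all counts equal; a Poisson-like model (or a "
            "different floor) is needed instead of a ZTNB fit"
        )
    uniq, ws = np.unique(ks, return_counts=True)
    r0, p0 = _mom_start(ks.astype(float))
    x0 = np.array([np.log(r0), np.log(p0 / (1 - p0))])
    res = optimize.minimize(
        _ztnb_negloglik, x0, args=(uniq, ws.astype(float), floor),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError(f"ZTNB fit did not converge for {dataset_id!r}: {res.message}")
    r = float(np.exp(res.x[0]))
    p = float(1.0 / (1.0 + np.exp(-res.x[1])))
    return ZTNBModel(r=r, p=p, dataset_id=dataset_id, loglik=-float(res.fun), floor=floor)


def loading_pvalue(count: int, model: ZTNBModel) -> float:
    """Upper-tail P(X >= count) under the fitted truncated background."""
    if count < model.floor:
        raise ValueError(f"count {count} below truncation floor {model.floor}")
    return model.sf_inclusive(int(count))


def critical_count(model: ZTNBModel, alpha: float = ALPHA) -> int:
    """Smallest count whose upper-tail p-value is <= alpha."""
    den = stats.nbinom.sf(model.floor - 1, model.r, model.p)
    c = int(stats.nbinom.isf(alpha * den, model.r, model.p))
    c = max(c - 2, model.floor)
    while loading_pvalue(c, model) > alpha:
        c += 1
    while c > model.floor and loading_pvalue(c - 1, model) <= alpha:
        c -= 1
    return c


def support_table(
    isomirs: Mapping[str, tuple[Hashable, bool]],
    datasets: Sequence[ParClipDataset],
    alpha: float = ALPHA,
    models: Optional[Mapping[str, ZTNBModel]] = None,
    background: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call Ago-loading support per isomiR across PAR-CLIP datasets.

    ``isomirs`` maps an isomiR id to (species key, is_reference flag); the
    key space must match the datasets' (e.g. exact genomic endpoint tuples).
    The background is fitted per dataset on all distinct-species counts
    (``background='all'``) or only on isomiR-matching species
    (``background='matched'``).  An isomiR is supported when its count
    reaches p <= alpha in at least one dataset; absent isomiRs get count 0
    and are unsupported.

    Returns (per-isomiR table, supported-fraction summary split by
    reference vs non-reference isomiRs).
    """
    if background not in ("all", "matched"):
        raise ValueError("background must be 'all' or 'matched'")
    fitted: dict[str, ZTNBModel] = dict(models or {})
    for ds in datasets:
        if ds.dataset_id in fitted:
            continue
        if background == "all":
            train = list(ds.counts.values())
        else:
            keys = {key for key, _ in isomirs.values()}
            train = [v for k, v in ds.counts.items() if k in keys]
        fitted[ds.dataset_id] = fit_ztnb(train, dataset_id=ds.dataset_id)

    records = []
    for iso_id, (key, is_ref) in isomirs.items():
        rec: dict = {"isomir": iso_id, "is_reference": bool(is_ref)}
        supported = False
        for ds in datasets:
            c = int(ds.counts.get(key, 0))
            rec[f"count_{ds.dataset_id}"] = c
            if c >= fitted[ds.dataset_id].floor:
                pv = loading_pvalue(c, fitted[ds.dataset_id])
            else:
                pv = 1.0
            rec[f"p_{ds.dataset_id}"] = pv
            supported = supported or pv <= alpha
        rec["supported"] = supported
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index("isomir")

    rows = []
    for label, mask in (
        ("reference", table["is_reference"]),
        ("non_reference", ~table["is_reference"]),
        ("all", pd.Series(True, index=table.index)),
    ):
        n = int(mask.sum())
        s = int((table["supported"] & mask).sum())
        rows.append({"class": label, "n": n, "supported": s,
                     "fraction": s / n if n else float("nan")})
    return table, pd.DataFrame(rows)


def read_parclip_tsv(path: str | Path, dataset_id: Optional[str] = None) -> ParClipDataset:
    """Read a PAR-CLIP count TSV keyed either by sequence or by
    chrom/strand/start/end endpoint columns."""
    df = pd.read_csv(path, sep="\t")
    if "count" not in df.columns:
        raise ValueError("PAR-CLIP table needs a 'count' column")
    if {"chrom", "strand", "start", "end"} <= set(df.columns):
        keys = list(zip(df["chrom"], df["strand"], df["start"].astype(int),
                        df["end"].astype(int)))
    elif "sequence" in df.columns:
        keys = list(df["sequence"])
    else:
        raise ValueError("PAR-CLIP table needs endpoint columns or a 'sequence' column")
    counts: dict[Hashable, int] = {}
    for k, c in zip(keys, df["count"].astype(int)):
        counts[k] = counts.get(k, 0) + c
    return ParClipDataset(dataset_id or Path(path).stem, counts)
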