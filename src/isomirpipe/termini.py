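"""Termini-variability profiles.

Every retained isomiR maps to a point (X, Y) = (off5, off3) with a height
Z in [0, 1]: the isomiR's share of its arm's reads within the analysis
group.  Points are aggregated onto a (2*flank+1)^2 grid per group, and the
marginals report what fraction of unique isomiRs change their 3' end, their
5' end, or both relative to the reference.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .annotation import DEFAULT_FLANK


def termini_points(
    filtered: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    group: str = "all",
) -> pd.DataFrame:
    """Per-isomiR (X, Y, Z) points for one analysis group.

    Z = isomiR group-mean normalized count / arm group-mean total; arms with
    zero total are skipped.  Within an arm the retained isomiRs' Z values
    sum to 1.
    """
    cols = list(samples) if samples is not None else list(filtered.columns)
    means = filtered[cols].mean(axis=1)
    records = []
    for arm_id, sub in means.groupby(level="arm_id", sort=False):
        total = sub.sum()
        if total <= 0:
            continue
        for (a, o5, o3), v in sub.items():
            records.append({"group": group, "arm_id": arm_id,
                            "X": o5, "Y": o3, "Z": v / total})
    return pd.DataFrame.from_records(
        records, columns=["group", "arm_id", "X", "Y", "Z"]
    )


def termini_grid(
    points: pd.DataFrame, flank: int = DEFAULT_FLANK
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate points into the (X, Y) grid plus marginal fractions.

    The grid holds, per group and cell, the summed Z across arms and the
    number of contributing isomiRs.  Marginals count unique isomiRs whose
    3' end (Y != 0), 5' end (X != 0) or both ends differ from the reference.
    """
    cells = []
    marginals = []
    for group, sub in points.groupby("group", sort=False):
        agg = sub.groupby(["X", "Y"]).agg(Z=("Z", "sum"), n_isomirs=("Z", "size"))
        for x in range(-flank, flank + 1):
            for y in range(-flank, flank + 1):
                z, n = (agg.loc[(x, y)] if (x, y) in agg.index else (0.0, 0))
                cells.append({"group": group, "X": x, "Y": y,
                              "Z": float(z), "n_isomirs": int(n)})
        n = len(sub)
        marginals.append({
            "group": group,
            "n_isomirs": n,
            "frac_3p_change": float((sub["Y"] != 0).sum() / n) if n else 0.0,
            "frac_5p_change": float((sub["X"] != 0).sum() / n) if n else 0.0,
            "frac_both_change": float(((sub["X"] != 0) & (sub["Y"] != 0)).sum() / n)
            if n else 0.0,
        })
    return pd.DataFrame(cells), pd.DataFrame(marginals)
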