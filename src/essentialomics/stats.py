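"""Shared statistical utilities.

Pairwise group comparison uses a two-sided Mann-Whitney U test with
Bonferroni adjustment over the number of tested pairs; alteration and
dependency counts are skewed, so a rank test is the robust default.
Percentages in human-readable reports are rounded half away from zero,
matching the convention of the summaries this package reproduces
(e.g. 65/73 -> 89%).
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "round_half_away",
    "percentage",
    "bonferroni_pairwise",
    "bh_adjust",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (5 rounds up in magnitude).

    Python's built-in ``round`` is banker's rounding; report tables here
    need the arithmetic convention (e.g. 15.668 -> 16, 12.5 -> 13, -12.5 -> -13).
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** decimals
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * math.copysign(1.0, scaled)
    out = rounded / factor
    return out if decimals > 0 else float(int(out))


def percentage(count: float, total: float, decimals: int | None = 0) -> float:
    """100 * count / total, optionally rounded half away from zero."""
    if total == 0:
        raise ZeroDivisionError("percentage undefined for total == 0")
    pct = 100.0 * count / total
    return pct if decimals is None else round_half_away(pct, decimals)


def bonferroni_pairwise(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All unordered pairwise two-sided Mann-Whitney U tests, Bonferroni-adjusted.

    Adjusted p = min(1, m * p) where m is the number of tested pairs.
    Pairs where either group has fewer than two values are reported as
    skipped rows (NaN p-values, note set) and do not count toward m.

    Returns a DataFrame with columns group_a, group_b, n_a, n_b, statistic,
    p_raw, p_adj, significant, note.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    rows = []
    for a, b in itertools.combinations(sorted(arrays), 2):
        xa, xb = arrays[a], arrays[b]
        row = {"group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb)}
        if len(xa) < 2 or len(xb) < 2:
            row.update(statistic=np.nan, p_raw=np.nan, note="skipped: group with <2 values")
        else:
            if np.array_equal(xa, xb):
                # identical samples carry no evidence of a location shift
                row.update(statistic=np.nan, p_raw=1.0, note="")
            else:
                res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
                row.update(statistic=float(res.statistic), p_raw=float(res.pvalue), note="")
        rows.append(row)
    out = pd.DataFrame(rows)
    m = int(out["p_raw"].notna().sum())
    out["m"] = m
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * m)
    out["significant"] = out["p_adj"] < alpha
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
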