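"""Approach 4: loss-of-function dependency screens and xenograft confirmation.

Scores are on the calibrated dependency scale (0 = not essential, -1 =
median of known common-essential genes). A substantial dependency is a
(gene, cell line) score <= -1 (inclusive). Genes are classified as:

* common essential — ranked among the top ``top_fraction`` most depleting
  genes in at least ``line_fraction`` (default 90%) of pan-cancer lines;
* strongly selective — the per-gene score vector is at least
  ``lr_threshold`` (default 100) times more likely under a skew-normal
  than under a normal maximum-likelihood fit. This is a skew-normal
  simplification of the skewed-vs-normal likelihood-ratio convention used
  by dependency portals (which fit a skew-t); family and threshold are
  exposed here as parameters of the fit.

Candidates from either class are then confirmed by patient-derived
xenograft protein expression: kept only with at least one model at
|Z| >= 2. Evidence must be positive — candidates never measured in the PDX
resource are excluded (logged distinctly from "measured but not
significant").
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, skewnorm

from . import stats
from .exceptions import ValidationError
from .types import GeneSet

logger = logging.getLogger(__name__)

DEPENDENCY_CUTOFF = -1.0


def substantial_dependencies(
    matrix: pd.DataFrame, cutoff: float = DEPENDENCY_CUTOFF
) -> tuple[pd.Series, GeneSet, int, float]:
    """Count scores <= cutoff per gene.

    Returns (per-gene dependency counts, qualifying genes — count >= 1,
    total dependencies, qualifying fraction of genes screened).
    """
    if matrix.empty:
        raise ValidationError("dependency matrix is empty")
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValidationError("dependency matrix contains non-finite scores")
    counts = (matrix <= cutoff).sum(axis=1).rename("n_dependencies")
    qualifying = frozenset(counts.index[counts >= 1])
    total = int(counts.sum())
    fraction = len(qualifying) / len(matrix)
    return counts, GeneSet("substantial_dependencies", qualifying), total, fraction


def subtype_dependency_ratio(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    cutoff: float = DEPENDENCY_CUTOFF,
    breast_only: bool = True,
) -> pd.DataFrame:
    """Dependencies per molecular subtype, normalized by cell-line count.

    Columns: subtype, n_dependencies, n_lines, ratio (exact), ratio_1dp
    (rounded half away from zero, the presentation convention), pct_share
    (share of all dependencies among the included lines, integer-rounded).
    Subtypes with zero lines are omitted.
    """
    unannotated = set(matrix.columns) - set(annotation["cell_line"])
    if unannotated:
        raise ValidationError(f"unannotated cell lines: {sorted(unannotated)[:10]}")
    ann = annotation.set_index("cell_line").loc[list(matrix.columns)]
    if breast_only:
        keep = ann.index[ann["is_breast"]]
    else:
        keep = ann.index
    sub_matrix = matrix[list(keep)]
    hits = sub_matrix <= cutoff
    total = int(hits.to_numpy().sum())
    rows = []
    for subtype, lines in ann.loc[list(keep)].groupby("subtype").groups.items():
        n_lines = len(lines)
        if n_lines == 0:
            continue
        n_dep = int(hits[list(lines)].to_numpy().sum())
        ratio = n_dep / n_lines
        rows.append(
            {
                "subtype": subtype,
                "n_dependencies": n_dep,
                "n_lines": n_lines,
                "ratio": ratio,
                "ratio_1dp": stats.round_half_away(ratio, 1),
                "pct_share": stats.percentage(n_dep, total) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values("subtype", kind="stable").reset_index(drop=True)


def classify_common_essential(
    matrix: pd.DataFrame,
    top_fraction: float = 0.25,
    line_fraction: float = 0.90,
) -> GeneSet:
    """Genes in the top most-depleting fraction in >= line_fraction of lines.

    Per line, genes are ranked by ascending score (most depleting first,
    ties by minimum rank); a gene qualifies in a line when its rank is
    within ``top_fraction`` of the genes screened.
    """
    if len(matrix) < 2:
        raise ValidationError("need at least two genes to rank")
    if matrix.shape[1] < 10:
        raise ValidationError("common-essential classification needs >= 10 cell lines")
    ranks = matrix.rank(axis=0, method="min", ascending=True)
    rank_cut = top_fraction * len(matrix)
    qualifies_per_line = ranks <= rank_cut
    frac_lines = qualifies_per_line.mean(axis=1)
    return GeneSet("common_essential", frozenset(frac_lines.index[frac_lines >= line_fraction]))


def _skewnorm_negll(params: np.ndarray, x: np.ndarray) -> float:
    a, loc, log_scale = params
    ll = skewnorm.logpdf(x, a, loc=loc, scale=np.exp(log_scale)).sum()
    return -ll if np.isfinite(ll) else 1e12


def _fit_skewnorm(x: np.ndarray) -> tuple[float, tuple[float, float, float]] | None:
    """Skew-normal ML fit via moment-initialized L-BFGS; None on failure."""
    mean, sd = x.mean(), x.std()
    g1 = float(np.clip(((x - mean) ** 3).mean() / sd**3, -0.99, 0.99))
    # method-of-moments start for the shape parameter
    c = (2.0 * abs(g1) / (4.0 - np.pi)) ** (2.0 / 3.0)
    delta = np.sign(g1) * np.sqrt((np.pi / 2.0) * c / (1.0 + c))
    delta = float(np.clip(delta, -0.95, 0.95))
    a0 = delta / np.sqrt(1.0 - delta**2)
    scale0 = sd / np.sqrt(max(1e-8, 1.0 - 2.0 * delta**2 / np.pi))
    loc0 = mean - scale0 * delta * np.sqrt(2.0 / np.pi)
    best = None
    for start in ((a0, loc0, np.log(scale0)), (0.0, mean, np.log(sd))):
        res = optimize.minimize(
            _skewnorm_negll, np.asarray(start), args=(x,), method="L-BFGS-B",
            options={"maxiter": 200},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return None
    a, loc, log_scale = best.x
    return -float(best.fun), (float(a), float(loc), float(np.exp(log_scale)))


def classify_strongly_selective(
    matrix: pd.DataFrame,
    lr_threshold: float = 100.0,
) -> tuple[GeneSet, pd.DataFrame]:
    """Genes whose scores favor a skewed over a normal distribution.

    Per gene, both families are fit by maximum likelihood; the gene
    qualifies iff the likelihood ratio (skew-normal / normal) is at least
    ``lr_threshold``. Degenerate vectors or failed fits are flagged
    ``unclassified``, never silently dropped. Returns the selection and a
    per-gene report (log_lr, fitted shape/loc/scale, status).
    """
    if matrix.shape[1] < 20:
        raise ValidationError("strongly-selective classification needs >= 20 cell lines")
    rows = []
    for gene, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        sd = x.std()
        if not np.isfinite(x).all() or sd == 0:
            rows.append({"gene": gene, "log_lr": np.nan, "a": np.nan, "loc": np.nan,
                         "scale": np.nan, "status": "unclassified"})
            continue
        ll_norm = float(norm.logpdf(x, loc=x.mean(), scale=sd).sum())
        fit = _fit_skewnorm(x)
        if fit is None:
            rows.append({"gene": gene, "log_lr": np.nan, "a": np.nan, "loc": np.nan,
                         "scale": np.nan, "status": "unclassified"})
            continue
        ll_skew, (a, loc, scale) = fit
        log_lr = max(0.0, ll_skew - ll_norm)  # normal is nested in skew-normal
        rows.append({"gene": gene, "log_lr": log_lr, "a": a, "loc": loc,
                     "scale": scale, "status": "classified"})
    report = pd.DataFrame(rows)
    selected = frozenset(
        report.loc[
            (report["status"] == "classified") & (report["log_lr"] >= np.log(lr_threshold)),
            "gene",
        ]
    )
    return GeneSet("strongly_selective", selected), report


def pdx_filter(
    candidates: Iterable[str],
    pdx: pd.DataFrame,
    threshold: float = 2.0,
) -> tuple[GeneSet, pd.DataFrame]:
    """Approach-4 essential set: candidates with PDX |Z| >= threshold.

    A candidate is kept when at least one xenograft model shows
    |z_score| >= threshold (inclusive). Candidates absent from the PDX
    table are excluded with status ``not_measured``; measured candidates
    below threshold get ``not_significant``. Per-gene direction and the
    qualifying model identifiers are retained.
    """
    if not np.isfinite(pdx["z_score"]).all():
        raise ValidationError("PDX table contains non-finite z-scores")
    by_protein = dict(tuple(pdx.groupby("protein")))
    rows = []
    kept = set()
    for gene in sorted(set(candidates)):
        sub = by_protein.get(gene)
        if sub is None:
            rows.append({"gene": gene, "status": "not_measured", "direction": "",
                         "models": ""})
            continue
        sig = sub.loc[sub["z_score"].abs() >= threshold]
        if sig.empty:
            rows.append({"gene": gene, "status": "not_significant", "direction": "",
                         "models": ""})
            continue
        has_high = bool((sig["z_score"] >= threshold).any())
        has_low = bool((sig["z_score"] <= -threshold).any())
        direction = "both" if (has_high and has_low) else ("high" if has_high else "low")
        kept.add(gene)
        rows.append({"gene": gene, "status": "kept", "direction": direction,
                     "models": ",".join(sorted(sig["model_id"].astype(str)))})
    n_unmeasured = sum(1 for r in rows if r["status"] == "not_measured")
    if n_unmeasured:
        logger.info("excluded %d candidates never measured in PDX models", n_unmeasured)
    return GeneSet("dependency_pdx", frozenset(kept)), pd.DataFrame(rows)
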