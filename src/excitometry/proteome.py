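"""Differential abundance for TMT-style protein/peptide tables.

Two-condition design (WT vs cKO, three replicates each in the study's
layout).  Rows are proteins or peptides, columns per-replicate abundances
named ``GROUP_rep`` (``WT_1`` … ``cKO_3``).  Welch's t-test (Satterthwaite
degrees of freedom) runs on log2 abundances; fold change is the ratio of
group means on the linear scale.  Differential calls default to the p-only
filter (p < 0.05) with an optional two-sided fold-change gate (> 1.5 or
< 1/1.5) for volcano highlighting.  The pre-ranked enrichment metric is the
signed log2 fold change multiplied by the inverse p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VolcanoThresholds",
    "group_columns",
    "welch_table",
    "dep_filter",
    "psea_rank_metric",
    "rank_table",
    "overlap_fold",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class VolcanoThresholds:
    p_max: float = 0.05
    fc_min: float = 1.5  # two-sided: ratio > fc_min or < 1/fc_min

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")
        if not self.fc_min > 1:
            raise ValueError("fc_min must exceed 1")


def group_columns(table: pd.DataFrame, group: str) -> list[str]:
    """Replicate columns of one group (``GROUP_rep`` naming)."""
    cols = [c for c in table.columns if c.startswith(group + "_")]
    if not cols:
        raise ValueError(f"no replicate columns found for group {group!r}")
    return cols


def welch_table(
    table: pd.DataFrame,
    group_a: str = "WT",
    group_b: str = "cKO",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Attach Welch's-t statistics and fold changes to an abundance table.

    Adds columns ``fold_change`` (group_b mean / group_a mean, linear scale),
    ``log2_fc`` and ``p_welch`` (two-sided Welch's t on log2 abundances).
    Rows with zero variance in both groups get ``p_welch`` = NaN with a
    warning.  ``bh_correct`` adds a Benjamini–Hochberg ``q_welch`` column.
    """
    cols_a = group_columns(table, group_a)
    cols_b = group_columns(table, group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least two replicates per group")
    a = table[cols_a].to_numpy(dtype=float)
    b = table[cols_b].to_numpy(dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("abundances must be positive before log transform")

    out = table.copy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    out["fold_change"] = mean_b / mean_a
    out["log2_fc"] = np.log2(out["fold_change"])

    la, lb = np.log2(a), np.log2(b)
    degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} row(s) with zero variance in both groups; p set to NaN")
        p[degenerate] = np.nan
    out["p_welch"] = p
    if bh_correct:
        out["q_welch"] = benjamini_hochberg(p)
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def dep_filter(
    table: pd.DataFrame,
    p_max: float = 0.05,
    require_fc: bool = False,
    fc_min: float = 1.5,
    id_col: Optional[str] = None,
) -> tuple[list, list, dict[str, int]]:
    """Differentially expressed rows, split by direction.

    DEP = ``p_welch`` < ``p_max``; when ``require_fc`` is set the fold change
    must additionally exceed ``fc_min`` (up) or fall below 1/``fc_min``
    (down).  Direction is the fold change relative to 1.  Returns
    ``(up_ids, down_ids, counts)``.
    """
    if "p_welch" not in table.columns:
        raise ValueError("run welch_table first (no p_welch column)")
    ids = table[id_col] if id_col else table.index.to_series()
    p = table["p_welch"].to_numpy(dtype=float)
    fc = table["fold_change"].to_numpy(dtype=float)
    sig = np.nan_to_num(p, nan=1.0) < p_max
    up = sig & (fc > 1.0)
    down = sig & (fc < 1.0)
    if require_fc:
        up &= fc > fc_min
        down &= fc < 1.0 / fc_min
    up_ids = list(ids[up])
    down_ids = list(ids[down])
    counts = {"up": len(up_ids), "down": len(down_ids), "total": len(up_ids) + len(down_ids)}
    return up_ids, down_ids, counts


def psea_rank_metric(log2_fc: float | np.ndarray, p: float | np.ndarray) -> float | np.ndarray:
    """Pre-ranked enrichment metric: signed log2 fold change × (1/p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p must be positive; apply a p-value floor before ranking")
    out = np.asarray(log2_fc, dtype=float) / p
    return float(out) if out.ndim == 0 else out


def rank_table(table: pd.DataFrame, id_col: Optional[str] = None) -> pd.DataFrame:
    """Two-column pre-ranked table (id, metric), metric descending.

    Ties are broken by id so the ordering is deterministic.
    """
    ids = (table[id_col] if id_col else table.index.to_series()).astype(str)
    metric = psea_rank_metric(
        table["log2_fc"].to_numpy(dtype=float), table["p_welch"].to_numpy(dtype=float)
    )
    out = pd.DataFrame({"id": ids.to_numpy(), "metric": metric})
    out = out.sort_values(["metric", "id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def overlap_fold(
    list_up: Iterable,
    list_down: Iterable,
    reference_set: Iterable,
) -> dict[str, Optional[float]]:
    """Per-direction overlap with a reference set and the down/up fold ratio.

    Fractions are |direction ∩ reference| / |direction|; the fold is the
    down fraction over the up fraction (None when a denominator is zero,
    with a warning for empty direction lists).
    """
    up, down, ref = set(list_up), set(list_down), set(reference_set)
    res: dict[str, Optional[float]] = {
        "n_up": len(up),
        "n_down": len(down),
        "n_up_overlap": len(up & ref),
        "n_down_overlap": len(down & ref),
    }
    if not up or not down:
        warnings.warn("empty direction list; overlap fold undefined")
    res["up_fraction"] = len(up & ref) / len(up) if up else None
    res["down_fraction"] = len(down & ref) / len(down) if down else None
    if res["up_fraction"] and res["down_fraction"] is not None:
        res["fold"] = res["down_fraction"] / res["up_fraction"]
    else:
        res["fold"] = None
    return res
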