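"""Per-contrast Welch's t-tests and fold-change screening of control ratios.

Altered probes are those with more than a 2-fold difference between group
means at p < 0.05 (both thresholds strict).  Tests run on log2-transformed
control ratios, where intensity noise is closer to symmetric; fold changes
are reported on the linear ratio scale.  No multiple-testing correction is
applied by default — the selection is a raw p < 0.05 screen by design, a
deliberate faithfulness choice; pass ``fdr=True`` to add a
Benjamini-Hochberg column and screen on it instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ContrastSpec:
    """Two disjoint array selections to compare (A vs B), optionally per-timepoint."""

    name: str
    group_a: str | Sequence[str]
    group_b: str | Sequence[str]
    timepoint: str | None = None


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch-Satterthwaite df, two-sided p.

    Degenerate inputs: if both groups have zero variance the statistic is 0
    with p = 1 when the means agree, and +/-inf with p = 0 (flagged with a
    warning) when they do not.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("welch_t requires finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        df = float(na + nb - 2)
        if diff == 0:
            return 0.0, df, 1.0
        warnings.warn("zero variance in both groups with unequal means; p -> 0",
                      RuntimeWarning, stacklevel=2)
        return float(np.sign(diff) * np.inf), df, 0.0
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fold_change(a, b) -> float:
    """Linear-scale ratio of group means, mean(a) / mean(b).

    Returns NaN (record excluded downstream) when mean(b) is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mb = b.mean()
    if mb == 0:
        return float("nan")
    return float(a.mean() / mb)


def _welch_rows(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t over two probe x array blocks (log scale)."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0
    equal = degenerate & (ma == mb)
    t[equal] = 0.0
    t[degenerate & ~equal] = np.sign((ma - mb)[degenerate & ~equal]) * np.inf
    df[degenerate] = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[equal] = 1.0
    p[degenerate & ~equal] = 0.0
    return t, df, p


def differential_table(m: ExpressionMatrix, contrast: ContrastSpec) -> pd.DataFrame:
    """Per-probe fold change and Welch test for one contrast.

    Probes with an undefined ratio (NaN) on any selected array, or an
    undefined fold change, are dropped.  Columns: fold_change, t, df, p.
    """
    if m.scale != "control_ratio":
        raise ValueError(f"expected control_ratio matrix, got {m.scale!r}")
    arrays_a = m.arrays_where(group=contrast.group_a, timepoint=contrast.timepoint)
    arrays_b = m.arrays_where(group=contrast.group_b, timepoint=contrast.timepoint)
    if not arrays_a or not arrays_b:
        raise ValueError(f"contrast {contrast.name!r}: empty group selection")
    if set(arrays_a) & set(arrays_b):
        raise ValueError(f"contrast {contrast.name!r}: group selections overlap")
    sub = m.values[arrays_a + arrays_b]
    ok = sub.notna().all(axis=1) & (sub > 0).all(axis=1)
    sub = sub[ok]
    A = sub[arrays_a].to_numpy()
    B = sub[arrays_b].to_numpy()
    fc = A.mean(axis=1) / B.mean(axis=1)
    t, df, p = _welch_rows(np.log2(A), np.log2(B))
    out = pd.DataFrame({"fold_change": fc, "t": t, "df": df, "p": p}, index=sub.index)
    return out[np.isfinite(out["fold_change"])]


def select_altered(m: ExpressionMatrix, contrast: ContrastSpec,
                   fc_min: float = 2.0, p_max: float = 0.05,
                   fdr: bool = False) -> pd.DataFrame:
    """Probes altered in a contrast: fold change beyond fc_min and p below p_max.

    Both thresholds are strict (fold must exceed ``fc_min`` or fall below
    ``1/fc_min``; p must be strictly below ``p_max``).  Returns the
    differential records of the selected probes, indexed by probe id.
    """
    table = differential_table(m, contrast)
    pcol = table["p"]
    if fdr:
        table = table.assign(p_adj=_bh_adjust(table["p"].to_numpy()))
        pcol = table["p_adj"]
    keep = ((table["fold_change"] > fc_min) | (table["fold_change"] < 1.0 / fc_min))
    keep &= pcol < p_max
    selected = table[keep]
    logger.info("contrast %s: %d altered probes", contrast.name, len(selected))
    return selected


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def combine_lists(lists) -> list[str]:
    """Set union of probe lists preserving first-seen order."""
    lists = list(lists)
    seen: dict[str, None] = {}
    for lst in lists:
        for p in lst:
            seen.setdefault(p, None)
    combined = list(seen)
    logger.info("combined %d lists into %d unique probes", len(lists), len(combined))
    return combined
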