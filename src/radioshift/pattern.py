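"""Dominant coordinate expression pattern by PCA over the altered-probe set.

Probes are the observations and arrays the variables: each probe's log2
control-ratio profile is mean-centered across arrays and the principal
components are taken from the resulting covariance structure (via SVD).
The first component (PC1) is the dominant treatment-associated pattern
across arrays.  Probes whose profiles correlate with PC1 at p < 0.001
(exact t transform of Pearson's r, n_arrays - 2 df) form the coordinately
regulated set, partitioned into elevated (r > 0) and diminished (r < 0)
probes under a fixed sign convention: PC1 is oriented so that its mean
score over the 18-week irradiation-alone arrays is positive, which makes
"elevated" mean elevated by irradiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PatternResult:
    """PC scores over arrays, variance fractions and per-probe PC1 statistics."""

    scores: pd.DataFrame                 # arrays x components (unit-norm loadings)
    variance_fractions: np.ndarray       # per component, sums to 1
    orientation: dict = field(default_factory=dict)
    per_probe: pd.DataFrame | None = None   # columns r, p (vs PC1)
    selected: list[str] = field(default_factory=list)
    elevated: list[str] = field(default_factory=list)
    diminished: list[str] = field(default_factory=list)

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def _log_ratio_block(m: ExpressionMatrix, probes) -> pd.DataFrame:
    if m.scale != "control_ratio":
        raise ValueError(f"expected control_ratio matrix, got {m.scale!r}")
    sub = m.values.loc[list(probes)]
    sub = sub[sub.notna().all(axis=1) & (sub > 0).all(axis=1)]
    return np.log2(sub)


def run_pca(m: ExpressionMatrix, probes, orient_group: str = "RT_IgG",
            orient_timepoint: str = "18w") -> PatternResult:
    """PCA of the probe x array log-ratio block.

    Returns per-array component scores (unit-norm loading vectors in array
    space) and the fraction of total variance captured by each component.
    PC1's sign is fixed by the orientation rule; the remaining components
    get a deterministic convention (largest-magnitude entry positive).
    """
    X = _log_ratio_block(m, probes).to_numpy()
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 probes and 2 arrays with defined ratios")
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("constant matrix: no variance to decompose")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    fractions = s ** 2 / np.sum(s ** 2)
    comps = vt  # k x arrays

    arrays = list(m.values.columns)
    orient_arrays = m.arrays_where(group=orient_group, timepoint=orient_timepoint)
    orientation = {"group": orient_group, "timepoint": orient_timepoint,
                   "arrays": orient_arrays, "flipped": False}
    comps = comps.copy()
    for k in range(comps.shape[0]):
        row = comps[k]
        if k == 0 and orient_arrays:
            idx = [arrays.index(a) for a in orient_arrays]
            if row[idx].mean() < 0:
                comps[k] = -row
                orientation["flipped"] = True
        else:
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                comps[k] = -row
    scores = pd.DataFrame(comps.T, index=arrays,
                          columns=[f"PC{k + 1}" for k in range(comps.shape[0])])
    return PatternResult(scores=scores, variance_fractions=fractions,
                         orientation=orientation)


def correlate_with_pc1(m: ExpressionMatrix, probes, pattern: PatternResult,
                       p_max: float = 0.001) -> tuple[pd.DataFrame, list[str]]:
    """Pearson r of each probe's profile with the PC1 array scores.

    Two-sided p from the exact t transform with n_arrays - 2 degrees of
    freedom.  Zero-variance probe profiles have undefined r and are
    excluded.  Returns the per-probe (r, p) table and the probes selected
    at p < p_max.
    """
    X = _log_ratio_block(m, probes)
    pc1 = pattern.pc1.loc[X.columns].to_numpy()
    n = X.shape[1]
    if n != len(pattern.pc1):
        raise ValueError("pattern was computed on a different array set")
    Xc = X.to_numpy() - X.to_numpy().mean(axis=1, keepdims=True)
    yc = pc1 - pc1.mean()
    ynorm = np.linalg.norm(yc)
    xnorm = np.linalg.norm(Xc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (xnorm * ynorm)
    r = np.clip(r, -1.0, 1.0)
    valid = xnorm > 0
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    table = pd.DataFrame({"r": r, "p": p}, index=X.index)[valid]
    selected = list(table.index[table["p"] < p_max])
    logger.info("PC1 correlation: %d of %d probes at p < %g", len(selected), len(table), p_max)
    return table, selected


def partition_by_sign(selected, per_probe: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split PC1-correlated probes into elevated (r > 0) and diminished (r < 0)."""
    r = per_probe.loc[list(selected), "r"]
    elevated = list(r.index[r > 0])
    diminished = list(r.index[r < 0])
    logger.info("partition: %d elevated, %d diminished", len(elevated), len(diminished))
    return elevated, diminished


def extract_pattern(m: ExpressionMatrix, probes, p_max: float = 0.001,
                    orient_group: str = "RT_IgG", orient_timepoint: str = "18w",
                    ) -> PatternResult:
    """run_pca -> correlate_with_pc1 -> partition_by_sign in one call."""
    result = run_pca(m, probes, orient_group, orient_timepoint)
    per_probe, selected = correlate_with_pc1(m, probes, result, p_max)
    elevated, diminished = partition_by_sign(selected, per_probe)
    result.per_probe = per_probe
    result.selected = selected
    result.elevated = elevated
    result.diminished = diminished
    return result


def hierarchical_order(m: ExpressionMatrix, probes) -> tuple[list[str], np.ndarray]:
    """Average-linkage ordering of probes on centered-correlation distance.

    Probes are pre-sorted lexicographically so ties resolve
    deterministically.  Zero-variance profiles (undefined correlation) are
    assigned the maximal distance 2 to everything.  Returns the leaf order
    and the linkage matrix.
    """
    X = _log_ratio_block(m, sorted(probes))
    if X.shape[0] < 2:
        return list(X.index), np.empty((0, 4))
    d = pdist(X.to_numpy(), metric="correlation")
    d = np.nan_to_num(d, nan=2.0)
    Z = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(Z)
    return [X.index[i] for i in order], Z
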