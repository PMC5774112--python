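"""Cell-type distinguishing gene panels from an expression atlas.

A gene distinguishes a cell type when its average (linear-scale) intensity
in that type's atlas samples exceeds 64 times the pooled mean of all other
samples and the rank-based Mann-Whitney test is significant at p < 0.001
(two-sided).  Genes qualifying for more than one cell type are removed from
every list, so the final panels are pairwise disjoint.  Panels derived on
one platform are carried onto the study platform through an identifier
mapping table; a gene mapping to several probes contributes all of them,
and probes shared between panels after mapping are removed to restore
disjointness.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CellTypeAtlas, MarkerPanel

logger = logging.getLogger(__name__)

EXACT_MAX_POOLED_N = 12   # exact enumeration up to this pooled sample count
DENOM_FLOOR = 1e-9        # guards the linear-ratio denominator


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Rank-sum Mann-Whitney U of sample ``a`` with midrank ties.

    The p-value is exact (enumeration over all assignments of the pooled
    midranks) when the pooled sample size is at most 12, otherwise a
    tie-corrected normal approximation without continuity correction.
    ``alternative`` is "two-sided" or "greater" (a tends larger).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("mann_whitney requires non-empty samples")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    U = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0

    if np.all(pooled == pooled[0]):
        return U, 1.0

    if na + nb <= EXACT_MAX_POOLED_N:
        total = 0
        count = 0
        u_obs = U
        dev_obs = abs(U - mu)
        for comb in itertools.combinations(range(na + nb), na):
            u = ranks[list(comb)].sum() - na * (na + 1) / 2.0
            total += 1
            if alternative == "greater":
                count += u >= u_obs - 1e-12
            else:
                count += abs(u - mu) >= dev_obs - 1e-12
        return U, count / total

    n = na + nb
    tie = _tie_term(pooled)
    var = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return U, 1.0
    z = (U - mu) / np.sqrt(var)
    if alternative == "greater":
        return U, float(stats.norm.sf(z))
    return U, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _mw_p_rows(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p (tie-corrected normal approximation).

    Same statistic/convention as :func:`mann_whitney`'s large-sample path,
    vectorized over genes.  Ranks are computed once per gene over all
    samples, which is valid because the comparison pools every sample.
    """
    n_genes, n = values.shape
    na = int(mask_a.sum())
    nb = n - na
    ranks = stats.rankdata(values, axis=1)
    U = ranks[:, mask_a].sum(axis=1) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    tie = np.empty(n_genes)
    for i in range(n_genes):
        tie[i] = _tie_term(values[i])
    var = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    p = np.ones(n_genes)
    ok = var > 0
    z = np.zeros(n_genes)
    z[ok] = (U[ok] - mu) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z[ok])))
    return p


def derive_panels(atlas: CellTypeAtlas, fold_min: float = 64.0, p_max: float = 0.001,
                  comparator: str = "pooled_mean") -> list[MarkerPanel]:
    """Non-overlapping cell-type distinguishing gene panels from an atlas.

    A gene enters cell type c's list iff its mean intensity over c's
    samples exceeds ``fold_min`` times the comparator over all other
    samples (``pooled_mean``: their pooled mean; ``max``: the largest
    per-type mean among the others) and the two-sided Mann-Whitney p is
    below ``p_max``.  Genes on more than one list are then removed from
    all lists.  Cell types with fewer than two samples are excluded with a
    warning (the rank test needs replication).
    """
    if comparator not in ("pooled_mean", "max"):
        raise ValueError(f"unknown comparator {comparator!r}")
    V = atlas.values.to_numpy(dtype=float)
    genes = np.array(atlas.gene_ids)
    labels = atlas.cell_type_of.to_numpy()
    per_type_mean = {ct: V[:, labels == ct].mean(axis=1) for ct in atlas.cell_types}

    raw_lists: dict[str, list[str]] = {}
    for ct in atlas.cell_types:
        mask = labels == ct
        if mask.sum() < 2:
            warnings.warn(f"cell type {ct!r} has a single sample; excluded from "
                          "panel derivation", UserWarning, stacklevel=2)
            continue
        mean_c = per_type_mean[ct]
        if comparator == "pooled_mean":
            other = V[:, ~mask].mean(axis=1)
        else:
            other = np.max([per_type_mean[o] for o in atlas.cell_types if o != ct], axis=0)
        ratio = mean_c / (other + DENOM_FLOOR)
        if V.shape[1] <= EXACT_MAX_POOLED_N:
            p = np.array([mann_whitney(V[i, mask], V[i, ~mask])[1]
                          for i in range(V.shape[0])])
        else:
            p = _mw_p_rows(V, mask)
        qualifies = (ratio > fold_min) & (p < p_max)
        raw_lists[ct] = list(genes[qualifies])

    counts: dict[str, int] = {}
    for lst in raw_lists.values():
        for g in lst:
            counts[g] = counts.get(g, 0) + 1
    panels = []
    for ct, lst in raw_lists.items():
        unique = [g for g in lst if counts[g] == 1]
        n_shared = len(lst) - len(unique)
        if n_shared:
            logger.info("panel %s: removed %d genes shared with other panels", ct, n_shared)
        panels.append(MarkerPanel(ct, unique,
                                  provenance={"fold_min": fold_min, "p_max": p_max,
                                              "comparator": comparator}))
    return panels


def map_panels(panels: Sequence[MarkerPanel], platform_map) -> list[MarkerPanel]:
    """Carry panels onto the study platform through a gene -> probe mapping.

    ``platform_map`` is an iterable of (atlas_gene_id, study_probe_id)
    pairs, possibly one-to-many; duplicate pairs are dropped.  Unmapped
    genes are removed and counted; probes shared between panels after
    mapping are removed from all panels.
    """
    if isinstance(platform_map, pd.DataFrame):
        pairs = list(platform_map.itertuples(index=False, name=None))
    else:
        pairs = list(platform_map)
    if not pairs:
        raise ValueError("empty platform map")
    mapping: dict[str, list[str]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for gene, probe in pairs:
        if (gene, probe) in seen_pairs:
            continue
        seen_pairs.add((gene, probe))
        mapping.setdefault(gene, []).append(probe)

    mapped_lists: dict[str, list[str]] = {}
    for panel in panels:
        probes: dict[str, None] = {}
        n_dropped = 0
        for g in panel.gene_ids:
            if g in mapping:
                for pr in mapping[g]:
                    probes.setdefault(pr, None)
            else:
                n_dropped += 1
        if n_dropped:
            logger.info("panel %s: dropped %d unmapped genes", panel.cell_type, n_dropped)
        mapped_lists[panel.cell_type] = list(probes)

    counts: dict[str, int] = {}
    for lst in mapped_lists.values():
        for pr in lst:
            counts[pr] = counts.get(pr, 0) + 1
    out = []
    for panel in panels:
        lst = [pr for pr in mapped_lists[panel.cell_type] if counts[pr] == 1]
        prov = dict(panel.provenance)
        prov["mapped"] = True
        out.append(MarkerPanel(panel.cell_type, lst, provenance=prov))
    return out
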