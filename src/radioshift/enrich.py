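"""Fold-enrichment and chi-square scoring of marker panels in a gene list.

For a query list of t probes on a platform of T probes, a panel with N
probes on the platform of which n appear in the query has

    fold enrichment = (n / t) / (N / T)

the ratio of the panel's frequency in the query to its frequency on the
platform.  Deviation from proportionality is scored with the 2x2
contingency chi-square (no continuity correction, 1 df, upper-tail p) on

    [[n, t - n], [N - n, (T - t) - (N - n)]]

Each panel carries its own platform total T, because panels may originate
from platforms of different sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, MarkerPanel

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """One row of the cell-type representation table."""

    cell_type: str
    n: int
    N: int
    t: int
    T: int
    fold: float
    chi2: float
    p: float


def fold_enrichment(n: int, t: int, N: int, T: int) -> float:
    """Ratio of proportions (n/t)/(N/T), at full precision."""
    if t <= 0 or N <= 0 or T <= 0:
        raise ValueError("fold_enrichment requires t > 0, N > 0 and T > 0")
    if n < 0:
        raise ValueError("n must be non-negative")
    return (n / t) / (N / T)


def chi2_representation(n: int, t: int, N: int, T: int) -> tuple[float, float]:
    """2x2 contingency chi-square (df=1, no continuity correction) and upper-tail p."""
    a = n
    b = t - n
    c = N - n
    d = (T - t) - (N - n)
    if min(a, b, c, d) < 0:
        raise ValueError(f"inconsistent counts: derived cell(s) negative in "
                         f"[[{a}, {b}], [{c}, {d}]]")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        raise ValueError("degenerate table: a zero margin gives undefined expected counts")
    total = a + b + c + d
    chi2 = total * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def representation_table(query: Sequence[str], panels: Sequence[MarkerPanel],
                         platform_totals: int | Mapping[str, int],
                         platform_probes: Sequence[str] | None = None,
                         ) -> list[EnrichmentRecord]:
    """Score each panel's representation in a query probe list.

    ``platform_totals`` is the platform size T, either one integer for all
    panels or a mapping cell_type -> T.  If ``platform_probes`` is given,
    query probes absent from it are dropped from t with a warning.
    Records are sorted by descending fold enrichment.
    """
    qset: dict[str, None] = {}
    for p in query:
        qset.setdefault(p, None)
    if platform_probes is not None:
        universe = set(platform_probes)
        unknown = [p for p in qset if p not in universe]
        if unknown:
            warnings.warn(f"{len(unknown)} query probes absent from the platform "
                          "universe; excluded", UserWarning, stacklevel=2)
            for p in unknown:
                del qset[p]
    t = len(qset)
    records = []
    for panel in panels:
        T = platform_totals if isinstance(platform_totals, int) \
            else platform_totals[panel.cell_type]
        N = len(set(panel.gene_ids))
        n = len(set(panel.gene_ids) & qset.keys())
        fold = fold_enrichment(n, t, N, T)
        try:
            chi2, p = chi2_representation(n, t, N, T)
        except ValueError:
            # degenerate table (e.g. query spans the whole platform): no
            # departure from proportionality is expressible
            chi2, p = 0.0, 1.0
        records.append(EnrichmentRecord(panel.cell_type, n, N, t, T, fold, chi2, p))
    records.sort(key=lambda r: (-r.fold, r.cell_type))
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_type": r.cell_type, "n": r.n, "N": r.N, "t": r.t, "T": r.T,
        "fold_enrichment": r.fold, "chi2": r.chi2, "p": r.p,
    } for r in records]).set_index("cell_type")


def fold_change_report(m: ExpressionMatrix, probes: Sequence[str],
                       reference_group: str) -> pd.DataFrame:
    """Per-probe, per-group linear fold change vs timepoint-matched controls.

    On the control-ratio scale the fold change for a (group, timepoint)
    cell is the group's mean ratio divided by the reference group's mean
    ratio at the same timepoint, so the reference group reports exactly 1.
    Rows are the requested probes; columns a (group, timepoint) MultiIndex.
    """
    if m.scale != "control_ratio":
        raise ValueError(f"expected control_ratio matrix, got {m.scale!r}")
    groups = list(dict.fromkeys(m.annotations["group"]))
    tps = list(dict.fromkeys(m.annotations["timepoint"]))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    sub = m.values.loc[list(probes)]
    cols = {}
    for tp in tps:
        ref_arrays = m.arrays_where(group=reference_group, timepoint=tp)
        if not ref_arrays:
            raise ValueError(f"reference group {reference_group!r} missing at {tp!r}")
        ref_mean = sub[ref_arrays].mean(axis=1)
        for g in groups:
            arrays = m.arrays_where(group=g, timepoint=tp)
            if not arrays:
                raise ValueError(f"group {g!r} missing at timepoint {tp!r}")
            cols[(g, tp)] = sub[arrays].mean(axis=1) / ref_mean
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "timepoint"])
    return out
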