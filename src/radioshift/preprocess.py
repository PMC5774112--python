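"""Normalization and low-intensity filtering of raw intensity matrices.

Two-step normalization: each chip is divided by a percentile (default the
50th) of its own positive measurements, then each probe is divided by the
median of its values across the timepoint-matched ("contemporaneous")
non-irradiated control arrays.  Low-intensity probes — those whose raw
signal is indistinguishable from background on most arrays — are removed
before differential testing.

The background scale per array is estimated as the MAD (scaled to an
SD-equivalent by 1.4826) of the array's lowest-decile intensities.  This is
a documented robust stand-in for a vendor-defined per-array error
coefficient; the 3x multiplier and the >=28-array failure count are kept as
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


@dataclass
class FilterConfig:
    """Parameters of the low-intensity probe filter."""

    error_coefficient_multiplier: float = 3.0
    min_failing_arrays: int = 28
    percentile: float = 50.0

    def __post_init__(self) -> None:
        if not self.error_coefficient_multiplier > 0:
            raise ValueError("error_coefficient_multiplier must be > 0")
        if self.min_failing_arrays < 1:
            raise ValueError("min_failing_arrays must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")


def normalize_to_percentile(m: ExpressionMatrix, percentile: float = 50.0) -> ExpressionMatrix:
    """Divide each array by the given percentile of its own positive values.

    Percentiles interpolate linearly between order statistics (the numpy
    default).  Requires a raw-scale matrix; errors name any array whose
    percentile is zero or that has no positive values.
    """
    if m.scale != "raw":
        raise ValueError(f"expected raw-scale matrix, got {m.scale!r}")
    out = m.values.copy().astype(float)
    for arr in m.array_ids:
        col = out[arr].to_numpy()
        pos = col[col > 0]
        if pos.size == 0:
            raise ValueError(f"array {arr!r} has no positive values")
        denom = float(np.percentile(pos, percentile))
        if denom == 0:
            raise ValueError(f"array {arr!r}: percentile {percentile} of positive values is 0")
        out[arr] = col / denom
    return m.with_values(out, "chip_normalized")


def normalize_to_control_median(m: ExpressionMatrix, control_group: str,
                                ) -> ExpressionMatrix:
    """Divide each probe by the timepoint-matched control median.

    For every timepoint, each array's values are divided per probe by the
    median of that probe across the control-group arrays of the same
    timepoint.  Probes whose control median is zero become NaN (undefined
    ratio) for that timepoint and are excluded downstream.
    """
    if m.scale != "chip_normalized":
        raise ValueError(f"expected chip_normalized matrix, got {m.scale!r}")
    out = m.values.copy().astype(float)
    for tp in m.annotations["timepoint"].unique():
        ctrl = m.arrays_where(group=control_group, timepoint=tp)
        if not ctrl:
            raise ValueError(f"no {control_group!r} control arrays at timepoint {tp!r}")
        med = m.values[ctrl].median(axis=1)
        cols = m.arrays_where(timepoint=tp)
        denom = med.replace(0, np.nan)
        out[cols] = m.values[cols].div(denom, axis=0)
    n_undef = int(out.isna().any(axis=1).sum())
    if n_undef:
        logger.info("control-median normalization: %d probes with undefined ratios", n_undef)
    return m.with_values(out, "control_ratio")


def estimate_error_coefficient(m: ExpressionMatrix) -> pd.Series:
    """Per-array background-noise scale from the lowest-decile intensities.

    Returns 1.4826 * MAD of the lowest 10% of each array's intensities — an
    SD-equivalent robust scale of the near-background signal.
    """
    if m.scale != "raw":
        raise ValueError(f"expected raw-scale matrix, got {m.scale!r}")
    n = m.values.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 probes to estimate background, got {n}")
    k = max(1, int(np.ceil(n * 0.1)))
    coefs = {}
    for arr in m.array_ids:
        low = np.sort(m.values[arr].to_numpy())[:k]
        coefs[arr] = MAD_TO_SD * float(np.median(np.abs(low - np.median(low))))
    return pd.Series(coefs, name="error_coefficient")


def filter_low_intensity(m_raw: ExpressionMatrix, cfg: FilterConfig | None = None,
                         ) -> list[str]:
    """Retained probe ids after removing near-background probes.

    A probe is removed iff its raw signal falls below
    ``multiplier * error_coefficient`` of the respective array on at least
    ``min_failing_arrays`` arrays.
    """
    cfg = cfg or FilterConfig()
    if cfg.min_failing_arrays > m_raw.n_arrays:
        raise ValueError(
            f"min_failing_arrays ({cfg.min_failing_arrays}) exceeds array count "
            f"({m_raw.n_arrays})")
    coef = estimate_error_coefficient(m_raw)
    thresholds = cfg.error_coefficient_multiplier * coef
    below = m_raw.values.lt(thresholds, axis=1)
    n_fail = below.sum(axis=1)
    retained = m_raw.values.index[n_fail < cfg.min_failing_arrays]
    n_removed = m_raw.values.shape[0] - retained.size
    logger.info("low-intensity filter: removed %d of %d probes",
                n_removed, m_raw.values.shape[0])
    return list(retained)
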