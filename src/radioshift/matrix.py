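"""Core in-memory containers for expression data.

An :class:`ExpressionMatrix` is a probe x array intensity table plus a
per-array annotation frame (group, timepoint, replicate) and a scale flag
tracking where it sits in the normalization chain.  A
:class:`CellTypeAtlas` is a gene x sample intensity table with a cell-type
label per sample, the input for marker-panel derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SCALES = ("raw", "chip_normalized", "control_ratio")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Probe x array intensities with per-array annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per array id.
    annotations
        DataFrame indexed by array id; expected columns are ``group``,
        ``timepoint`` and ``replicate`` (extra columns are carried along).
    scale
        One of ``raw`` (vendor intensities), ``chip_normalized``
        (per-chip percentile normalized) or ``control_ratio``
        (normalized to the timepoint-matched control median).  NaN values
        are only permitted on the ``control_ratio`` scale, where they mark
        ratios with an undefined (zero) control median.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate array ids: {dups[:5]}")
        if set(self.values.columns) != set(self.annotations.index):
            raise ValidationError("annotation index does not match array columns")
        # keep annotation rows in column order
        self.annotations = self.annotations.loc[self.values.columns]
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "control_ratio":
            if np.isinf(arr).any():
                raise ValidationError("non-finite (inf) values in matrix")
        elif not np.isfinite(arr).all():
            raise ValidationError(f"non-finite values in {self.scale} matrix")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def arrays_where(self, group: str | Sequence[str] | None = None,
                     timepoint: str | None = None) -> list[str]:
        """Array ids matching a group (or list of groups) and/or timepoint."""
        mask = pd.Series(True, index=self.annotations.index)
        if group is not None:
            groups = [group] if isinstance(group, str) else list(group)
            mask &= self.annotations["group"].isin(groups)
        if timepoint is not None:
            mask &= self.annotations["timepoint"] == timepoint
        return list(self.annotations.index[mask])

    def subset(self, probes: Sequence[str] | None = None,
               arrays: Sequence[str] | None = None) -> "ExpressionMatrix":
        v = self.values
        if probes is not None:
            v = v.loc[list(probes)]
        if arrays is not None:
            v = v[list(arrays)]
        ann = self.annotations.loc[v.columns]
        return ExpressionMatrix(v, ann, self.scale)

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.annotations.copy(), scale)


@dataclass
class CellTypeAtlas:
    """Gene x sample intensities with a cell-type label per sample."""

    values: pd.DataFrame
    cell_type_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in atlas")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in atlas")
        if set(self.values.columns) != set(self.cell_type_of.index):
            raise ValidationError("cell_type_of index does not match atlas samples")
        self.cell_type_of = self.cell_type_of.loc[self.values.columns]
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite values in atlas")
        if (arr <= 0).any():
            raise ValidationError("atlas intensities must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        # first-seen order of labels
        seen: dict[str, None] = {}
        for ct in self.cell_type_of:
            seen.setdefault(ct, None)
        return list(seen)

    def samples_of(self, cell_type: str) -> list[str]:
        return list(self.cell_type_of.index[self.cell_type_of == cell_type])


@dataclass
class MarkerPanel:
    """A cell type's list of distinguishing gene (or probe) identifiers."""

    cell_type: str
    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)


def assert_panels_disjoint(panels: Sequence[MarkerPanel]) -> None:
    """Raise if any identifier appears in more than one panel."""
    seen: dict[str, str] = {}
    for p in panels:
        for g in p.gene_ids:
            if g in seen and seen[g] != p.cell_type:
                raise ValidationError(
                    f"identifier {g!r} appears in panels {seen[g]!r} and {p.cell_type!r}")
            seen[g] = p.cell_type
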