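"""Published reference counts for the cell-type representation analysis.

``CELL_TYPE_REPRESENTATION_COUNTS`` holds the reported (n, N) probe counts
per cell type from the irradiated-lung study this pipeline reimplements,
with t the size of the radiation-elevated probe set and T the size of the
array platform each panel was derived from (two platform universes were
used).  These are inputs for replaying the published representation table
and for validating :func:`radioshift.enrich.fold_enrichment`.
"""

from __future__ import annotations

T_QUERY_PLATFORM = 29806   # platform of the study arrays (most panels)
T_ALT_PLATFORM = 19515     # platform for neutrophil/endothelial/lung-epithelial panels
T_ELEVATED = 1676          # radiation-elevated probe set size

# cell type -> (n, N, T, reported fold enrichment as printed)
CELL_TYPE_REPRESENTATION_COUNTS: dict[str, tuple[int, int, int, float]] = {
    "Macrophage": (98, 123, T_QUERY_PLATFORM, 14.2),
    "Dendritic Cell": (26, 45, T_QUERY_PLATFORM, 10.3),
    "Mesenchymal Cell": (28, 73, T_QUERY_PLATFORM, 6.8),
    "Mast Cell": (42, 149, T_QUERY_PLATFORM, 5.0),
    "Neutrophil": (14, 49, T_ALT_PLATFORM, 3.3),
    "B Cell": (11, 81, T_QUERY_PLATFORM, 2.4),
    "Endothelial Cell": (9, 43, T_ALT_PLATFORM, 2.4),
    "T Cell": (7, 81, T_QUERY_PLATFORM, 1.5),
    "Epithelial Cell (Lung)": (10, 91, T_ALT_PLATFORM, 1.3),
    "Epithelial Cell (Retina)": (2, 115, T_QUERY_PLATFORM, 0.31),
}

# Reported sizes of the altered-probe lists and their union.
N_RT_ALTERED = 2570
N_TREATED_ALTERED = 3644
N_COMBINED_UNIQUE = 4798
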