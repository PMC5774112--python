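# radioshift

Microarray analysis of cell-type composition shifts in irradiated lung.

Radiation therapy of thoracic tumours causes delayed pneumonitis and
fibrosis, accompanied by infiltration of immune and mesenchymal cells into
the lung. `radioshift` reimplements, as a tested pipeline, an expression
analysis built to quantify those shifts from bulk microarrays of a mouse
irradiation study (7 treatment groups × 2 timepoints × 2 replicates,
including several regimens of an anti-CTGF antibody):

1. **preprocess** — per-chip normalization to the 50th percentile of each
   array's measurements, per-probe normalization to the median of
   timepoint-matched non-irradiated controls, and removal of low-intensity
   probes whose raw signal falls below 3× a per-array background scale on
   ≥ 28 arrays.
2. **diffexpr** — Welch's *t*-tests on log2 control ratios with a strict
   > 2-fold change at *p* < 0.05 screen per contrast (irradiation vs.
   control; each antibody regimen vs. irradiation alone), with the altered
   lists combined by ordered set union.
3. **pattern** — PCA over the combined altered-probe set (probes as
   observations, arrays as variables), selection of probes correlated with
   PC1 at *p* < 0.001, and partition into irradiation-elevated (r > 0) and
   irradiation-diminished (r < 0) sets; average-linkage clustering order
   for heatmap export.
4. **markers** — derivation of non-overlapping cell-type distinguishing
   gene panels from an expression atlas: mean expression > 64× higher in
   one cell type than in all other samples, Mann–Whitney *p* < 0.001,
   genes on more than one list removed; panels mapped onto the study
   platform.
5. **enrich** — fold enrichment of each panel in a query gene list,

       Enrichment = (n/t) / (N/T)

   where *n* = panel probes in the query list, *t* = query-list size,
   *N* = panel probes on the platform, *T* = platform size, with a 2×2
   contingency χ² (df = 1, no continuity correction) for departure from
   proportionality; plus per-group fold-change reporting relative to
   unirradiated controls.
6. **simulate** — a first-class synthetic-data generator producing a
   cell-type atlas with planted type-exclusive markers and a bulk study
   matrix as noisy mixtures of cell-type profiles with planted composition
   shifts, so every downstream stage is testable against known ground
   truth without any download.

## Worked example

```python
from radioshift import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(seed=1))
manifest, outputs = run_pipeline(cfg)

print(manifest.counts["elevated"], manifest.counts["diminished"])
for r in outputs["enrichment"][:4]:
    print(f"{r.cell_type:15s} n={r.n:3d} N={r.N:3d} fold={r.fold:5.1f} p={r.p:.2e}")
```

prints

```
101 16
mast_cell       n= 29 N= 30 fold= 19.1 p=5.84e-118
macrophage      n= 28 N= 30 fold= 18.5 p=1.13e-109
mesenchymal     n= 23 N= 30 fold= 15.2 p=7.97e-73
dendritic_cell  n= 21 N= 30 fold= 13.9 p=3.17e-60
```

Of 2000 synthetic probes, 101 are elevated by irradiation and reversed by
treatment and 16 diminished; the four cell types whose fractions were
planted to expand after irradiation (macrophages, mast cells, dendritic
cells, mesenchymal cells) head the representation table with fold
enrichments far above 1, while unshifted cell types score 0 — the
synthetic analogue of the published finding that irradiation enriches
these compartments and antibody treatment reverses the enrichment.

The same analysis is available from a shell:

```sh
radioshift run --seed 1 --out results/
radioshift simulate --seed 1 --out sim/
radioshift preprocess --matrix sim/raw.tsv --annot sim/samples.tsv \
    --out norm.tsv --retained kept.txt
```

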