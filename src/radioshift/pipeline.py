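"""End-to-end orchestration: simulate/ingest -> preprocess -> select -> pattern -> panels -> enrichment.

``run_pipeline`` executes the stages in order and returns a
:class:`RunManifest` recording every probe-count attrition step (probes
retained after the low-intensity filter, per-contrast altered counts, the
combined-list size, the PC1-correlated count and its elevated/diminished
split, per-panel enrichment) together with a parameter snapshot and
checksums of the stage outputs.  The manifest fully determines a re-run:
identical configuration and seed give bit-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrich, io, markers, pattern, preprocess, simulate
from .matrix import CellTypeAtlas, ExpressionMatrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and carries the cause."""


@dataclass
class PipelineConfig:
    """Every stage's thresholds and definitions, with study defaults."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    filter: preprocess.FilterConfig = field(default_factory=preprocess.FilterConfig)
    percentile: float = 50.0
    control_group: str = "noRT_IgG"
    rt_group: str = "RT_IgG"
    treated_groups: list[str] = field(default_factory=lambda: [
        "RT_FG_dm2", "RT_FG_d2", "RT_FG_d20", "RT_FG_d112"])
    pooled_treated: bool = False   # pool treated arrays into one contrast instead of a union
    fc_min: float = 2.0
    p_max: float = 0.05
    pc1_p_max: float = 0.001
    marker_fold_min: float = 64.0
    marker_p_max: float = 0.001
    orient_timepoint: str = "18w"
    cluster: bool = True
    version: str = "radioshift-0.1.0"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        shifts = sim_raw.pop("composition_shift", None)
        if shifts is not None:
            # YAML mapping keys are "group/timepoint" strings
            sim_raw["composition_shift"] = {
                tuple(k.split("/")): v for k, v in shifts.items()}
        filt_raw = raw.pop("filter", {})
        return cls(simulation=simulate.SimulationConfig(**sim_raw),
                   filter=preprocess.FilterConfig(**filt_raw), **raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["composition_shift"] = {
            "/".join(k): v for k, v in self.simulation.composition_shift.items()}
        return d


@dataclass
class RunManifest:
    """Probe-count audit trail and reproducibility record of one run."""

    params: dict
    counts: dict
    checksums: dict
    enrichment: list[dict]

    def to_dict(self) -> dict:
        return {"params": self.params, "counts": self.counts,
                "checksums": self.checksums, "enrichment": self.enrichment}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)

    def __eq__(self, other) -> bool:
        return isinstance(other, RunManifest) and self.to_json() == other.to_json()


def _checksum_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update("\x1f".join(map(str, df.index)).encode())
    h.update("\x1f".join(map(str, df.columns)).encode())
    h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()


def _checksum_list(items) -> str:
    return hashlib.sha256("\n".join(map(str, items)).encode()).hexdigest()


def default_contrasts(cfg: PipelineConfig, timepoints) -> list[diffexpr.ContrastSpec]:
    """Irradiation-vs-control and each-regimen-vs-irradiation, per timepoint.

    The "any treatment vs irradiation alone" list is realized as the union
    over regimen-specific contrasts unless ``pooled_treated`` is set, in
    which case all treated arrays form one pooled group.
    """
    contrasts = []
    for tp in timepoints:
        contrasts.append(diffexpr.ContrastSpec(
            f"RT_vs_ctrl_{tp}", cfg.rt_group, cfg.control_group, timepoint=tp))
    if cfg.pooled_treated:
        for tp in timepoints:
            contrasts.append(diffexpr.ContrastSpec(
                f"FG_pooled_vs_RT_{tp}", list(cfg.treated_groups), cfg.rt_group, timepoint=tp))
    else:
        for g in cfg.treated_groups:
            for tp in timepoints:
                contrasts.append(diffexpr.ContrastSpec(
                    f"{g}_vs_RT_{tp}", g, cfg.rt_group, timepoint=tp))
    return contrasts


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 study: ExpressionMatrix | None = None,
                 atlas: CellTypeAtlas | None = None,
                 atlas_truth: simulate.AtlasTruth | None = None,
                 platform_map=None) -> tuple[RunManifest, dict]:
    """Run the full analysis; returns (manifest, stage outputs).

    With no ``study``/``atlas`` supplied, both are generated from
    ``cfg.simulation`` (ground truth included in the outputs); externally
    read matrices can be passed instead for ingest mode.
    """
    outputs: dict = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # -- simulate / ingest -------------------------------------------------
    study_truth = None
    if atlas is None:
        atlas, atlas_truth = stage("simulate", simulate.generate_atlas, cfg.simulation)
    if study is None:
        study, study_truth = stage("simulate", simulate.generate_study,
                                   cfg.simulation, atlas, atlas_truth)
    if platform_map is None:
        platform_map = simulate.default_platform_map(atlas.gene_ids)
    outputs.update(study=study, atlas=atlas, atlas_truth=atlas_truth,
                   study_truth=study_truth)

    # -- preprocess --------------------------------------------------------
    chip = stage("preprocess", preprocess.normalize_to_percentile, study, cfg.percentile)
    ratios = stage("preprocess", preprocess.normalize_to_control_median,
                   chip, cfg.control_group)
    retained = stage("preprocess", preprocess.filter_low_intensity, study, cfg.filter)
    ratios_kept = ratios.subset(probes=retained)
    outputs.update(ratios=ratios_kept, retained=retained)

    # -- differential selection --------------------------------------------
    timepoints = list(dict.fromkeys(study.annotations["timepoint"]))
    contrasts = default_contrasts(cfg, timepoints)
    per_contrast: dict[str, list[str]] = {}
    tables = {}
    for c in contrasts:
        tab = stage("diffexpr", diffexpr.select_altered, ratios_kept, c,
                    cfg.fc_min, cfg.p_max)
        per_contrast[c.name] = list(tab.index)
        tables[c.name] = tab
    combined = stage("diffexpr", diffexpr.combine_lists, per_contrast.values())
    outputs.update(contrast_tables=tables, combined=combined)

    # -- pattern -----------------------------------------------------------
    pat = stage("pattern", pattern.extract_pattern, ratios_kept, combined,
                cfg.pc1_p_max, cfg.rt_group, cfg.orient_timepoint)
    outputs["pattern"] = pat
    if cfg.cluster and len(pat.selected) >= 2:
        order, _ = stage("pattern", pattern.hierarchical_order, ratios_kept, pat.selected)
        outputs["cluster_order"] = order

    # -- markers -----------------------------------------------------------
    panels = stage("markers", markers.derive_panels, atlas,
                   cfg.marker_fold_min, cfg.marker_p_max)
    mapped = stage("markers", markers.map_panels, panels, platform_map)
    outputs.update(panels=panels, mapped_panels=mapped)

    # -- enrichment --------------------------------------------------------
    T = len(study.probe_ids)
    records = stage("enrich", enrich.representation_table, pat.elevated, mapped,
                    T, study.probe_ids)
    outputs["enrichment"] = records

    counts = {
        "probes_total": len(study.probe_ids),
        "probes_retained": len(retained),
        "altered_per_contrast": {k: len(v) for k, v in per_contrast.items()},
        "combined_unique": len(combined),
        "pc1_correlated": len(pat.selected),
        "elevated": len(pat.elevated),
        "diminished": len(pat.diminished),
        "pc1_variance_fraction": float(pat.variance_fractions[0]),
        "panel_sizes": {p.cell_type: len(p) for p in mapped},
    }
    checksums = {
        "study": _checksum_frame(study.values),
        "ratios": _checksum_frame(ratios_kept.values.fillna(np.inf)),
        "combined": _checksum_list(combined),
        "elevated": _checksum_list(pat.elevated),
        "diminished": _checksum_list(pat.diminished),
        "panels": _checksum_list(
            f"{p.cell_type}:{','.join(p.gene_ids)}" for p in mapped),
        "enrichment": _checksum_list(
            f"{r.cell_type}:{r.n}:{r.N}:{r.t}:{r.T}:{r.fold!r}" for r in records),
    }
    manifest = RunManifest(
        params=cfg.snapshot(),
        counts=counts,
        checksums=checksums,
        enrichment=[dataclasses.asdict(r) for r in records],
    )

    if out_dir is not None:
        _write_outputs(Path(out_dir), manifest, outputs)
    return manifest, outputs


def _write_outputs(out_dir: Path, manifest: RunManifest, outputs: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_expression(outputs["study"], out_dir / "raw.tsv", out_dir / "samples.tsv")
    io.write_matrix(outputs["ratios"].values, out_dir / "normalized.tsv")
    io.write_probe_list(outputs["retained"], out_dir / "retained_probes.txt")
    io.write_probe_list(outputs["combined"], out_dir / "combined_probes.txt")
    pat = outputs["pattern"]
    pat.scores.to_csv(out_dir / "pc_scores.tsv", sep="\t", index_label="array_id")
    if pat.per_probe is not None:
        pat.per_probe.to_csv(out_dir / "pc1_correlation.tsv", sep="\t",
                             index_label="probe_id")
    io.write_probe_list(pat.elevated, out_dir / "elevated_probes.txt")
    io.write_probe_list(pat.diminished, out_dir / "diminished_probes.txt")
    if "cluster_order" in outputs:
        ordered = outputs["ratios"].values.loc[outputs["cluster_order"]]
        io.write_matrix(ordered, out_dir / "heatmap_matrix.tsv")
    io.write_panels(outputs["mapped_panels"], out_dir / "panels.tsv")
    enrich.records_to_frame(outputs["enrichment"]).to_csv(
        out_dir / "enrichment.tsv", sep="\t")
    (out_dir / "manifest.json").write_text(manifest.to_json())
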