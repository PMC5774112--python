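"""Synthetic atlases and study matrices with known ground truth.

The generator emulates the design the analysis was built for: a lung
irradiation study with seven treatment groups (non-irradiated controls with
IgG or antibody, irradiation alone, and four antibody regimens started at
different times relative to irradiation), two harvest timepoints (18 and 30
weeks) and two biological replicates per cell — 28 arrays in total.  Each
bulk array is a composition-weighted mixture of cell-type mean profiles
taken from a synthetic expression atlas in which every cell type carries a
set of planted marker genes expressed ``marker_fold`` times higher in that
type than anywhere else.  Irradiated groups receive multiplicative shifts
of the immune/mesenchymal compartment fractions, which the downstream
pipeline should recover as fold enrichment of the corresponding marker
panels.

Noise is multiplicative log-normal with a configurable coefficient of
variation, the natural noise model for intensity-scale microarray data.
All randomness flows from the explicit ``seed`` field; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import CellTypeAtlas, ExpressionMatrix


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


DEFAULT_GROUPS = [
    "noRT_IgG", "noRT_FG", "RT_IgG", "RT_FG_dm2", "RT_FG_d2", "RT_FG_d20", "RT_FG_d112",
]
DEFAULT_TIMEPOINTS = ["18w", "30w"]
DEFAULT_CELL_TYPES = [
    "macrophage", "mast_cell", "dendritic_cell", "mesenchymal",
    "t_cell", "endothelial", "epithelial",
]
# Resting lung is parenchyma-dominated; immune compartments are small.
DEFAULT_BASELINE_COMPOSITION = {
    "macrophage": 0.04, "mast_cell": 0.01, "dendritic_cell": 0.02,
    "mesenchymal": 0.08, "t_cell": 0.05, "endothelial": 0.25, "epithelial": 0.55,
}
# Irradiation expands macrophage/mast/dendritic/mesenchymal fractions at 18
# weeks; regimens started 20 or 112 days after irradiation normalize the
# response at 18 weeks, and every regimen normalizes it by 30 weeks, when the
# untreated response itself is milder.
_SHIFT_18W = {"macrophage": 8.0, "mast_cell": 10.0, "dendritic_cell": 6.0, "mesenchymal": 5.0}
_SHIFT_30W = {"macrophage": 4.0, "mast_cell": 5.0, "dendritic_cell": 3.0, "mesenchymal": 2.5}
DEFAULT_COMPOSITION_SHIFT = {
    ("RT_IgG", "18w"): dict(_SHIFT_18W),
    ("RT_FG_dm2", "18w"): dict(_SHIFT_18W),
    ("RT_FG_d2", "18w"): dict(_SHIFT_18W),
    ("RT_IgG", "30w"): dict(_SHIFT_30W),
}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic generator."""

    n_cell_types: int = 7
    cell_types: list[str] | None = None
    n_atlas_samples_per_type: int = 6
    n_genes: int = 2000
    n_markers_per_type: int = 30
    marker_fold: float = 128.0
    study_groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    timepoints: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    replicates_per_cell: int = 2
    baseline_composition: dict[str, float] | None = None
    composition_shift: dict[tuple[str, str], dict[str, float]] | None = None
    noise_cv: float = 0.2
    floor_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_types is None:
            if self.n_cell_types == len(DEFAULT_CELL_TYPES):
                self.cell_types = list(DEFAULT_CELL_TYPES)
            else:
                self.cell_types = [f"celltype_{i + 1:02d}" for i in range(self.n_cell_types)]
        self.n_cell_types = len(self.cell_types)
        if self.baseline_composition is None:
            if set(self.cell_types) == set(DEFAULT_BASELINE_COMPOSITION):
                self.baseline_composition = dict(DEFAULT_BASELINE_COMPOSITION)
            else:
                f = 1.0 / self.n_cell_types
                self.baseline_composition = {ct: f for ct in self.cell_types}
        if self.composition_shift is None:
            if set(self.cell_types) == set(DEFAULT_CELL_TYPES):
                self.composition_shift = {k: dict(v) for k, v in DEFAULT_COMPOSITION_SHIFT.items()}
            else:
                self.composition_shift = {}
        self.validate()

    def validate(self) -> None:
        if self.n_cell_types < 1:
            raise SimulationConfigError("n_cell_types must be >= 1")
        if self.n_atlas_samples_per_type < 1:
            raise SimulationConfigError("n_atlas_samples_per_type must be >= 1")
        if self.n_genes < 1:
            raise SimulationConfigError("n_genes must be >= 1")
        if self.n_markers_per_type < 0:
            raise SimulationConfigError("n_markers_per_type must be >= 0")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise SimulationConfigError(
                "n_markers_per_type: n_markers_per_type * n_cell_types exceeds n_genes")
        if not self.marker_fold > 1:
            raise SimulationConfigError("marker_fold must be > 1")
        if self.replicates_per_cell < 1:
            raise SimulationConfigError("replicates_per_cell must be >= 1")
        if self.noise_cv < 0:
            raise SimulationConfigError("noise_cv must be >= 0")
        if self.floor_intensity < 0:
            raise SimulationConfigError("floor_intensity must be >= 0")
        comp = self.baseline_composition
        if set(comp) != set(self.cell_types):
            raise SimulationConfigError(
                "baseline_composition keys must match cell_types exactly")
        fr = np.array(list(comp.values()), dtype=float)
        if (fr < 0).any() or (fr > 1).any():
            raise SimulationConfigError("baseline_composition fractions must lie in [0, 1]")
        if not math.isclose(fr.sum(), 1.0, abs_tol=1e-9):
            raise SimulationConfigError("baseline_composition fractions must sum to 1")
        for key, shifts in self.composition_shift.items():
            g, tp = key
            if g not in self.study_groups:
                raise SimulationConfigError(f"composition_shift: unknown group {g!r}")
            if tp not in self.timepoints:
                raise SimulationConfigError(f"composition_shift: unknown timepoint {tp!r}")
            for ct, mult in shifts.items():
                if ct not in self.cell_types:
                    raise SimulationConfigError(f"composition_shift: unknown cell type {ct!r}")
                if mult <= 0:
                    raise SimulationConfigError("composition_shift multipliers must be > 0")

    @property
    def n_arrays(self) -> int:
        return len(self.study_groups) * len(self.timepoints) * self.replicates_per_cell

    @property
    def shifted_cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for shifts in self.composition_shift.values():
            for ct, mult in shifts.items():
                if mult != 1.0:
                    seen.setdefault(ct, None)
        return list(seen)


@dataclass
class AtlasTruth:
    """Ground truth of the synthetic atlas: which genes were planted as markers."""

    planted_markers: dict[str, list[str]]

    def all_markers(self) -> set[str]:
        return {g for lst in self.planted_markers.values() for g in lst}


@dataclass
class StudyTruth:
    """Ground truth of the synthetic study.

    ``composition`` holds the realized per-array cell-type fractions (rows
    sum to 1); ``expected_direction`` maps (group, timepoint) to the
    planted enrichment direction ("up"/"none") per cell type.
    """

    composition: pd.DataFrame
    expected_direction: dict[tuple[str, str], dict[str, str]]
    shifted_cell_types: list[str]


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def gene_to_probe(gene_id: str) -> str:
    """Study-platform probe id for an atlas gene id (synthetic platform link)."""
    return "P" + gene_id[1:]


def default_platform_map(gene_ids) -> list[tuple[str, str]]:
    """One-to-one atlas-gene -> study-probe mapping for the synthetic platform."""
    return [(g, gene_to_probe(g)) for g in gene_ids]


def generate_atlas(config: SimulationConfig) -> tuple[CellTypeAtlas, AtlasTruth]:
    """Generate a cell-type atlas with planted type-exclusive markers.

    Each planted marker's noise-free mean is ``marker_fold`` times higher in
    its own cell type's samples than everywhere else; non-marker genes share
    a common (gene-specific) baseline across all samples.  Noise is applied
    per ``noise_cv``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = _gene_ids(config.n_genes)
    base = rng.lognormal(mean=math.log(100.0), sigma=0.8, size=config.n_genes)

    marker_idx = rng.choice(config.n_genes,
                            size=config.n_markers_per_type * config.n_cell_types,
                            replace=False)
    planted: dict[str, list[str]] = {}
    sample_ids: list[str] = []
    type_of: list[str] = []
    for ct in config.cell_types:
        for k in range(config.n_atlas_samples_per_type):
            sample_ids.append(f"{ct}_{k + 1}")
            type_of.append(ct)

    mean = np.tile(base[:, None], (1, len(sample_ids)))
    type_arr = np.array(type_of)
    for i, ct in enumerate(config.cell_types):
        lo = i * config.n_markers_per_type
        idx = marker_idx[lo:lo + config.n_markers_per_type]
        planted[ct] = [genes[j] for j in sorted(idx)]
        cols = type_arr == ct
        mean[np.ix_(idx, cols)] = base[idx, None] * config.marker_fold

    values = mean * _lognormal_noise(rng, config.noise_cv, mean.shape)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    atlas = CellTypeAtlas(df, pd.Series(type_of, index=sample_ids, name="cell_type"))
    return atlas, AtlasTruth(planted)


def type_mean_profiles(atlas: CellTypeAtlas) -> pd.DataFrame:
    """Gene x cell-type matrix of per-type mean intensities."""
    return atlas.values.T.groupby(atlas.cell_type_of).mean().T


def generate_study(config: SimulationConfig, atlas: CellTypeAtlas,
                   truth: AtlasTruth) -> tuple[ExpressionMatrix, StudyTruth]:
    """Generate a bulk study matrix as noisy mixtures of atlas profiles.

    Each array's probe intensities are the composition-weighted mean of the
    atlas cell-type mean profiles, times log-normal noise, plus
    ``floor_intensity``.  Composition shifts are applied per
    (group, timepoint) and renormalized to sum to 1.  Probe ids are the
    study-platform ids linked one-to-one to atlas genes.
    """
    profiles = type_mean_profiles(atlas)
    missing = [ct for ct in config.baseline_composition if ct not in profiles.columns]
    if missing:
        raise SimulationConfigError(
            f"baseline_composition: cell types not in atlas: {missing}")
    rng = np.random.default_rng([config.seed, 2])
    prof = profiles[list(config.baseline_composition)].to_numpy()

    array_ids, groups, tps, reps, comps = [], [], [], [], []
    direction: dict[tuple[str, str], dict[str, str]] = {}
    base = np.array(list(config.baseline_composition.values()), dtype=float)
    cts = list(config.baseline_composition)
    for g in config.study_groups:
        for tp in config.timepoints:
            shifts = config.composition_shift.get((g, tp), {})
            mult = np.array([shifts.get(ct, 1.0) for ct in cts])
            comp = base * mult
            comp = comp / comp.sum()
            direction[(g, tp)] = {
                ct: ("up" if shifts.get(ct, 1.0) > 1 else
                     "down" if shifts.get(ct, 1.0) < 1 else "none")
                for ct in cts}
            for r in range(1, config.replicates_per_cell + 1):
                array_ids.append(f"{g}_{tp}_r{r}")
                groups.append(g)
                tps.append(tp)
                reps.append(r)
                comps.append(comp)

    comp_mat = np.array(comps)                       # arrays x types
    bulk = prof @ comp_mat.T                         # genes x arrays
    bulk = bulk * _lognormal_noise(rng, config.noise_cv, bulk.shape)
    bulk = bulk + config.floor_intensity

    probes = [gene_to_probe(g) for g in atlas.gene_ids]
    values = pd.DataFrame(bulk, index=pd.Index(probes, name="probe_id"), columns=array_ids)
    ann = pd.DataFrame({"group": groups, "timepoint": tps, "replicate": reps},
                       index=pd.Index(array_ids, name="array_id"))
    m = ExpressionMatrix(values, ann, scale="raw")
    comp_df = pd.DataFrame(comp_mat, index=array_ids, columns=cts)
    return m, StudyTruth(comp_df, direction, config.shifted_cell_types)


@dataclass
class PatternTruth:
    """Ground truth for a planted two-pattern study matrix."""

    primary_probes: list[str]      # probes following the dominant array pattern
    secondary_probes: list[str]    # probes following the orthogonal pattern
    primary_sign: pd.Series        # +1 / -1 per primary probe
    primary_pattern: pd.Series     # dominant pattern over arrays (unit norm)
    secondary_pattern: pd.Series
    variance_split: float


def generate_pattern_study(n_pattern_probes: int = 300, n_null_probes: int = 300,
                           variance_split: float = 0.7, amplitude: float = 7.0,
                           noise_sd: float = 0.15, seed: int = 0,
                           groups: list[str] | None = None,
                           timepoints: list[str] | None = None,
                           replicates: int = 2) -> tuple[ExpressionMatrix, PatternTruth]:
    """Plant two orthogonal, group-aligned expression patterns in a raw matrix.

    The dominant pattern is an irradiation response (high in the untreated
    and early-regimen irradiated groups at 18 weeks, milder at 30 weeks);
    the secondary pattern separates the late antibody regimens.  Half the
    pattern probes load on each, with amplitudes set so the dominant
    pattern carries ``variance_split`` of the planted variance.  Primary
    probes carry a random +/- sign so the elevated/diminished partition is
    testable.  Values are returned on the raw intensity scale
    (``100 * 2**signal``) so the matrix can flow through the full
    normalization chain; the control groups sit at baseline.
    """
    groups = list(DEFAULT_GROUPS) if groups is None else groups
    timepoints = list(DEFAULT_TIMEPOINTS) if timepoints is None else timepoints
    rng = np.random.default_rng([seed, 3])

    array_ids, ga, ta, ra = [], [], [], []
    for g in groups:
        for tp in timepoints:
            for r in range(1, replicates + 1):
                array_ids.append(f"{g}_{tp}_r{r}")
                ga.append(g)
                ta.append(tp)
                ra.append(r)
    ann = pd.DataFrame({"group": ga, "timepoint": ta, "replicate": ra},
                       index=pd.Index(array_ids, name="array_id"))
    n_arrays = len(array_ids)

    v1 = np.zeros(n_arrays)
    v2 = np.zeros(n_arrays)
    for i in range(n_arrays):
        if ga[i] in ("RT_IgG", "RT_FG_dm2", "RT_FG_d2") and ta[i] == "18w":
            v1[i] = 1.0
        elif ga[i] == "RT_IgG" and ta[i] == "30w":
            v1[i] = 0.4
        if ga[i] in ("RT_FG_d20", "RT_FG_d112"):
            v2[i] = 1.0
    v1 -= v1.mean()
    v1 /= np.linalg.norm(v1)
    v2 -= v2.mean()
    v2 -= (v2 @ v1) * v1
    v2 /= np.linalg.norm(v2)

    n1 = n_pattern_probes // 2
    n2 = n_pattern_probes - n1
    a1 = amplitude * math.sqrt(variance_split / 0.5)
    a2 = amplitude * math.sqrt((1 - variance_split) / 0.5)
    signs = rng.choice([-1.0, 1.0], size=n1)
    signs2 = rng.choice([-1.0, 1.0], size=n2)

    signal = np.zeros((n_pattern_probes + n_null_probes, n_arrays))
    signal[:n1] = np.outer(signs * a1, v1)
    signal[n1:n_pattern_probes] = np.outer(signs2 * a2, v2)
    signal += rng.normal(0.0, noise_sd, size=signal.shape)

    probes = [f"P{i:05d}" for i in range(signal.shape[0])]
    raw = 100.0 * np.exp2(signal)
    values = pd.DataFrame(raw, index=pd.Index(probes, name="probe_id"), columns=array_ids)
    m = ExpressionMatrix(values, ann, scale="raw")
    truth = PatternTruth(
        primary_probes=probes[:n1],
        secondary_probes=probes[n1:n_pattern_probes],
        primary_sign=pd.Series(signs, index=probes[:n1]),
        primary_pattern=pd.Series(v1, index=array_ids),
        secondary_pattern=pd.Series(v2, index=array_ids),
        variance_split=variance_split,
    )
    return m, truth
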