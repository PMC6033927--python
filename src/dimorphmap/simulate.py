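"""Synthetic longitudinal cohorts with known ground truth.

The study design being emulated: male and female C57BL/6J mice scanned at
nine postnatal days (3, 5, 7, 10, 17, 23, 29, 36, 65) with roughly 11-15
mice per sex per timepoint and occasional missing scans; per-mouse random
intercepts induce within-subject correlation.  Four archetypal
sex-difference trajectories are plantable, matching the developmental
patterns seen in sexually dimorphic mouse neuroanatomy:

1. male-larger from early life onward;
2. male-larger emerging late;
3. male-larger early, crossing over to female-larger across puberty;
4. no early difference, female-larger emerging after ~day 17.

Volumes are generated on the log scale so the absolute/relative
decomposition is additive: log absolute determinant = log relative
determinant + log global brain scale, exactly as in deformation-based
morphometry.  Because no per-structure variance components are published
for this design, the default noise levels here are stated modelling
assumptions (see docs/methods.md), not estimates.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .volumes import DeterminantField, LabelAtlas, TABLE_COLUMNS

__all__ = [
    "CohortConfig",
    "ArchetypeSpec",
    "ExpressionPanel",
    "default_brain_growth",
    "default_archetypes",
    "generate_cohort",
    "generate_null_responses",
    "generate_determinant_fields",
    "generate_expression_panel",
    "generate_cortex_phantom",
]

DEFAULT_TIMEPOINTS = (3, 5, 7, 10, 17, 23, 29, 36, 65)


def default_brain_growth(age_days):
    """Saturating (Gompertz) whole-brain growth, mm^3.

    Plateaus after ~day 36 at ~435 mm^3, the adult whole-brain volume
    implied by published structure tables for this strain.
    """
    t = np.asarray(age_days, dtype=float)
    return 435.0 * np.exp(-np.exp(-(t + 2.0) / 7.0))


@dataclasses.dataclass
class CohortConfig:
    """Design and noise parameters of a synthetic cohort.

    ``sigma_mouse`` and ``sigma_noise`` are standard deviations on the
    log-volume scale (so 0.03 is roughly a 3% coefficient of variation).
    Dropout never removes a mouse's first or last scan, so every subject
    retains the endpoints needed by the individualization analyses; this
    is a deliberate deviation from fully random missingness.
    """

    n_per_sex: int = 14
    timepoints: tuple = DEFAULT_TIMEPOINTS
    sigma_mouse: float = 0.015
    sigma_noise: float = 0.015
    dropout_rate: float = 0.05
    brain_growth: Callable = default_brain_growth
    seed: int = 0

    def __post_init__(self):
        if self.n_per_sex < 2:
            raise ValueError("need at least 2 mice per sex")
        tps = np.asarray(self.timepoints, dtype=float)
        if not (np.diff(tps) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if not 0.0 <= self.dropout_rate <= 0.3:
            raise ValueError("dropout_rate must lie in [0, 0.3]")

    def mice(self) -> pd.DataFrame:
        ids = [f"M{i:02d}" for i in range(self.n_per_sex)] + [
            f"F{i:02d}" for i in range(self.n_per_sex)
        ]
        sexes = ["M"] * self.n_per_sex + ["F"] * self.n_per_sex
        return pd.DataFrame({"mouse_id": ids, "sex": sexes})


@dataclasses.dataclass
class ArchetypeSpec:
    """One planted sex-difference trajectory.

    ``effect_curve(age) -> signed effect`` on the log relative volume
    (positive = larger in males).  ``structures`` names the volume-table
    structures carrying the effect; ``roi`` is a boolean grid mask for
    determinant-field generation (either may be empty).
    """

    archetype_id: int
    effect_curve: Callable
    structures: tuple = ()
    roi: np.ndarray | None = None

    def __post_init__(self):
        if not 1 <= self.archetype_id <= 4:
            raise ValueError("archetype_id must be 1..4")


def default_archetypes(amplitude: float = 0.05,
                       structures: Sequence[str] = ("arch1", "arch2", "arch3", "arch4"),
                       ) -> list[ArchetypeSpec]:
    """The four canonical trajectories at a given peak amplitude (log scale)."""
    a = float(amplitude)

    def early_male(t):
        return a * (1.0 - np.exp(-np.asarray(t, float) / 5.0))

    def late_male(t):
        return a / (1.0 + np.exp(-(np.asarray(t, float) - 25.0) / 5.0))

    def crossover(t):
        # positive before day 20, negative after: changes sign exactly once
        return a * (20.0 - np.asarray(t, float)) / 30.0

    def late_female(t):
        t = np.asarray(t, float)
        s = np.clip((t - 17.0) / (36.0 - 17.0), 0.0, None)
        return -a * np.minimum(s, 1.0 + 0.1 * np.maximum(s - 1.0, 0.0))

    curves = [early_male, late_male, crossover, late_female]
    return [
        ArchetypeSpec(archetype_id=i + 1, effect_curve=curves[i], structures=(structures[i],))
        for i in range(4)
    ]


def _scan_layout(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per retained (mouse, timepoint) scan."""
    mice = config.mice()
    tps = list(config.timepoints)
    rows = []
    for _, mouse in mice.iterrows():
        keep = rng.random(len(tps)) >= config.dropout_rate
        keep[0] = True
        keep[-1] = True
        for k, (t, kp) in enumerate(zip(tps, keep)):
            if kp:
                rows.append((mouse.mouse_id, mouse.sex, float(t), k))
    return pd.DataFrame(rows, columns=["mouse_id", "sex", "age_days", "timepoint_index"])


def generate_cohort(config: CohortConfig,
                    archetypes: Sequence[ArchetypeSpec] = (),
                    n_background_structures: int = 4,
                    baseline_fraction: float = 0.005) -> pd.DataFrame:
    """Long-format structure-volume table with planted sex effects.

    Each structure's log volume is baseline(age) + archetype effect x
    male indicator + per-mouse intercept + iid noise; the whole-brain
    column carries its own per-mouse intercept.  Sexes are balanced
    before dropout.
    """
    seen: set[str] = set()
    for arch in archetypes:
        overlap = seen & set(arch.structures)
        if overlap:
            raise ValueError(f"structures assigned to multiple archetypes: {sorted(overlap)}")
        seen |= set(arch.structures)

    rng = np.random.default_rng(config.seed)
    layout = _scan_layout(config, rng)
    mice = config.mice()

    structures: list[tuple[str, Callable | None]] = []
    for arch in archetypes:
        for s in arch.structures:
            structures.append((s, arch.effect_curve))
    for i in range(n_background_structures):
        structures.append((f"bg{i}", None))

    b_brain = dict(zip(mice.mouse_id, rng.normal(0.0, config.sigma_mouse, len(mice))))
    b_struct = {
        (m, s): rng.normal(0.0, config.sigma_mouse)
        for m in mice.mouse_id
        for s, _ in structures
    }

    recs = []
    for _, scan in layout.iterrows():
        age = scan.age_days
        brain = float(config.brain_growth(age)) * float(
            np.exp(b_brain[scan.mouse_id] + rng.normal(0.0, config.sigma_noise / 2.0))
        )
        for s, curve in structures:
            logv = np.log(baseline_fraction * config.brain_growth(age))
            if curve is not None and scan.sex == "M":
                logv = logv + float(curve(age))
            logv = logv + b_struct[(scan.mouse_id, s)] + rng.normal(0.0, config.sigma_noise)
            recs.append(
                (scan.mouse_id, scan.sex, age, int(scan.timepoint_index), s,
                 float(np.exp(logv)), brain)
            )
    return pd.DataFrame(recs, columns=TABLE_COLUMNS)


def generate_null_responses(config: CohortConfig, n_sims: int,
                            seed: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Many independent null response vectors on one dropout-free layout.

    Returns (layout, Y) where ``layout`` has one row per (mouse, timepoint)
    and ``Y`` is (n_scans, n_sims): mouse intercept + residual noise only,
    no sex effect.  Intended for calibration studies (type-I error, Wilks
    reference) where thousands of refits share a design.
    """
    cfg = dataclasses.replace(config, dropout_rate=0.0)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = _scan_layout(cfg, rng)
    mouse_codes, mouse_idx = np.unique(layout.mouse_id, return_inverse=True)
    b = rng.normal(0.0, cfg.sigma_mouse, (len(mouse_codes), n_sims))
    eps = rng.normal(0.0, cfg.sigma_noise, (len(layout), n_sims))
    return layout, b[mouse_idx] + eps


def generate_determinant_fields(config: CohortConfig,
                                grid_shape: tuple = (24, 24, 24),
                                archetypes: Sequence[ArchetypeSpec] = (),
                                brain_radius_frac: float = 0.42,
                                ) -> tuple[list[DeterminantField], LabelAtlas]:
    """Relative + absolute log-determinant fields with planted ROI effects.

    The relative field is planted effect x male indicator + per-(mouse,
    voxel) intercept + iid noise inside a spherical brain mask; the
    absolute field adds the scan's log global brain scale (constant over
    voxels).  The atlas labels the archetype ROIs plus octant background
    structures.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    center = (np.asarray(grid_shape) - 1) / 2.0
    ii = np.indices(grid_shape).astype(float)
    r = np.sqrt(sum((ii[a] - center[a]) ** 2 for a in range(3)))
    brain = r <= brain_radius_frac * min(grid_shape)

    labels = np.zeros(grid_shape, dtype=np.int32)
    # octant background parcellation of the brain mask
    octant = (
        (ii[0] >= center[0]).astype(int)
        + 2 * (ii[1] >= center[1]).astype(int)
        + 4 * (ii[2] >= center[2]).astype(int)
    )
    labels[brain] = 100 + octant[brain]
    names = {100 + k: f"bg_octant{k}" for k in range(8)}

    roi_masks = []
    for j, arch in enumerate(archetypes):
        if arch.roi is None:
            raise ValueError(f"archetype {arch.archetype_id} has no ROI mask")
        roi = np.asarray(arch.roi, dtype=bool)
        if roi.shape != grid_shape:
            raise ValueError("archetype ROI shape does not match the grid")
        if (roi & ~brain).any():
            raise ValueError("archetype ROI extends outside the brain mask")
        labels[roi] = j + 1
        names[j + 1] = f"arch{arch.archetype_id}"
        roi_masks.append((roi, arch.effect_curve))

    voxel_volume = 1.0
    atlas = LabelAtlas(labels=labels, names=names, voxel_volume=voxel_volume)

    rng = np.random.default_rng(config.seed)
    layout = _scan_layout(config, rng)
    mice = config.mice()
    b_voxel = {
        m: rng.normal(0.0, config.sigma_mouse, grid_shape) for m in mice.mouse_id
    }
    b_scale = dict(zip(mice.mouse_id, rng.normal(0.0, config.sigma_mouse, len(mice))))
    ref_age = config.timepoints[-1]

    fields: list[DeterminantField] = []
    for _, scan in layout.iterrows():
        rel = rng.normal(0.0, config.sigma_noise, grid_shape)
        rel += b_voxel[scan.mouse_id]
        if scan.sex == "M":
            for roi, curve in roi_masks:
                rel[roi] += float(curve(scan.age_days))
        rel[~brain] = 0.0
        log_scale = float(
            np.log(config.brain_growth(scan.age_days) / config.brain_growth(ref_age))
            + b_scale[scan.mouse_id]
        )
        common = dict(voxel_volume=voxel_volume, mouse_id=scan.mouse_id,
                      sex=scan.sex, age_days=scan.age_days)
        fields.append(DeterminantField(values=rel, kind="relative", **common))
        fields.append(DeterminantField(values=rel + log_scale, kind="absolute", **common))
    return fields, atlas


def box_roi(grid_shape: tuple, corner: tuple, size: tuple) -> np.ndarray:
    """Convenience: an axis-aligned box mask for planting ROIs."""
    m = np.zeros(tuple(grid_shape), dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    m[sl] = True
    return m


def generate_individualization_cohort(config: CohortConfig,
                                      n_structures: int = 8,
                                      onset_male: float = 7.0,
                                      onset_female: float = 7.0,
                                      sigma_identity: float = 0.10,
                                      ) -> pd.DataFrame:
    """Cohort whose subject-specific anatomy emerges at a set age per sex.

    Before its sex's onset age a mouse's structure volumes follow the
    population growth curve plus noise; from the onset onward each
    (mouse, structure) acquires a persistent log-scale offset of SD
    ``sigma_identity``.  Early scans therefore carry no information about
    a subject's mature anatomy, so leave-one-out prediction error stays
    flat until the accessed timepoint crosses the onset — the construction
    behind individualization-timing analyses.  Equal onsets make the sexes
    exchangeable (a null cohort for the permutation test).
    """
    rng = np.random.default_rng(config.seed)
    layout = _scan_layout(config, rng)
    mice = config.mice()
    fracs = 0.002 * (1.0 + np.arange(n_structures))
    offs = {
        (m, j): rng.normal(0.0, sigma_identity)
        for m in mice.mouse_id
        for j in range(n_structures)
    }
    onset = {"M": onset_male, "F": onset_female}
    recs = []
    for _, scan in layout.iterrows():
        age = scan.age_days
        brain = float(config.brain_growth(age))
        active = 1.0 if age >= onset[scan.sex] else 0.0
        for j in range(n_structures):
            logv = (
                np.log(fracs[j] * brain)
                + active * offs[(scan.mouse_id, j)]
                + rng.normal(0.0, config.sigma_noise)
            )
            recs.append(
                (scan.mouse_id, scan.sex, age, int(scan.timepoint_index),
                 f"s{j}", float(np.exp(logv)), brain)
            )
    return pd.DataFrame(recs, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Expression panels

@dataclasses.dataclass
class ExpressionPanel:
    """Per-gene 3-D expression maps aligned to an atlas grid."""

    genes: pd.DataFrame          # columns: gene, chromosome
    maps: np.ndarray             # (n_genes, *grid), nonnegative

    def __post_init__(self):
        if (self.maps < 0).any():
            raise ValueError("expression maps must be nonnegative")
        if len(self.genes) != self.maps.shape[0]:
            raise ValueError("gene table and map stack disagree in length")

    def map_for(self, gene: str) -> np.ndarray:
        idx = self.genes.index[self.genes.gene == gene]
        if len(idx) == 0:
            raise KeyError(gene)
        return self.maps[idx[0]]


def generate_expression_panel(atlas: LabelAtlas, n_genes: int,
                              enriched: Sequence[tuple] = (),
                              seed: int = 0,
                              sex_chrom_fraction: float = 0.05,
                              noise_shape: float = 20.0) -> ExpressionPanel:
    """Gamma-noise expression maps, homogeneous except for planted folds.

    ``enriched`` holds (gene_index, roi_mask, fold) triples: the in-ROI
    mean level is solved so that mean_in / mean_brain equals the requested
    fold on average.  Chromosome labels are assigned deterministically:
    the first ``sex_chrom_fraction`` of genes alternate X/Y, the rest are
    autosomes.
    """
    rng = np.random.default_rng(seed)
    brain = atlas.brain_mask
    n_brain = int(brain.sum())
    grid = atlas.labels.shape

    n_sex = max(int(round(sex_chrom_fraction * n_genes)), 0)
    chroms = ["X" if i % 2 == 0 else "Y" for i in range(n_sex)]
    chroms += [str(1 + i % 19) for i in range(n_genes - n_sex)]
    genes = pd.DataFrame({"gene": [f"g{i:04d}" for i in range(n_genes)],
                          "chromosome": chroms})

    levels = np.ones((n_genes, n_brain))
    for gene_idx, roi, fold in enriched:
        fold = float(fold)
        if fold <= 0:
            raise ValueError("requested fold must be positive")
        roi = np.asarray(roi, dtype=bool)
        roi_in_brain = roi[brain]
        n_roi = int(roi_in_brain.sum())
        if n_roi == 0:
            raise ValueError("enrichment ROI is empty within the brain mask")
        if fold * n_roi >= n_brain:
            raise ValueError(
                f"fold {fold} infeasible for an ROI of {n_roi}/{n_brain} brain voxels"
            )
        # level a inside the ROI, 1 outside, such that a / brain_mean = fold
        a = fold * (n_brain - n_roi) / (n_brain - fold * n_roi)
        levels[gene_idx, roi_in_brain] = a

    noise = rng.gamma(noise_shape, 1.0 / noise_shape, size=(n_genes, n_brain))
    maps = np.zeros((n_genes,) + grid, dtype=float)
    maps[:, brain] = levels * noise
    return ExpressionPanel(genes=genes, maps=maps)


# ---------------------------------------------------------------------------
# Cortex phantoms

def generate_cortex_phantom(kind: str, geometry: dict,
                            grid_shape: tuple = (24, 24, 24)):
    """Slab or spherical-shell cortical ribbon with known thickness.

    Returns (ribbon, inner, outer) boolean masks.  Boundary voxels sit
    within half a voxel of the respective geometric surface, so Dirichlet
    node centers average onto the surface; the ribbon is every voxel
    strictly between the two surfaces.  Ground-truth thickness is the
    plate separation (slab) or r_out - r_in (shell), measured between the
    Dirichlet surfaces.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if kind == "slab":
        separation = int(geometry["separation"])
        z0 = int(geometry.get("z0", (grid_shape[2] - separation) // 2))
        z1 = z0 + separation
        if separation < 2 or z0 < 0 or z1 >= grid_shape[2]:
            raise ValueError("degenerate slab geometry")
        zz = np.indices(grid_shape)[2]
        inner = zz == z0
        outer = zz == z1
        ribbon = (zz > z0) & (zz < z1)
        return ribbon, inner, outer
    if kind == "shell":
        r_in = float(geometry["r_in"])
        r_out = float(geometry["r_out"])
        half = min(grid_shape) / 2.0
        if not (0.0 < r_in < r_out < half):
            raise ValueError("degenerate shell geometry: need 0 < r_in < r_out < half-width")
        center = (np.asarray(grid_shape) - 1) / 2.0
        ii = np.indices(grid_shape).astype(float)
        r = np.sqrt(sum((ii[a] - center[a]) ** 2 for a in range(3)))
        inner = np.abs(r - r_in) <= 0.5
        outer = np.abs(r - r_out) <= 0.5
        ribbon = (r > r_in) & (r < r_out)
        return ribbon, inner, outer
    raise ValueError(f"unknown phantom kind {kind!r}")
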