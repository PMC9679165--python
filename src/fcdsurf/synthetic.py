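"""Synthetic multi-site cohort generator.

Emulates the statistical structure the detection pipeline assumes, without
any imaging data: a bilaterally symmetric template (mirrored icospheres with
a polar "medial wall" cap), 11 base features with smooth spatial structure,
age and sex effects, per-site additive and multiplicative shifts, variable
FLAIR availability, and contiguous planted lesions realizing three feature
archetypes:

* ``group1`` — increased cortical thickness and intrinsic curvature,
  decreased grey-white contrast, increased white-matter FLAIR;
* ``group2`` — decreased grey-white contrast and decreased intracortical
  FLAIR, mildly increased intrinsic curvature;
* ``group3`` — heterogeneous, with all offsets below 0.5 SD.

Archetype offsets are expressed in units of the subject's across-cortex
feature SD (the same unit the downstream intrasubject z-scoring uses), so
planted effect sizes are directly recoverable by the normalization stages.

Spatially correlated noise is produced by smoothing white noise with a
15 mm geodesic Gaussian kernel and restoring unit per-vertex variance.
Principal curvature fields k1, k2 are generated directly with a
folding-like sinusoidal base pattern; the curvature features are derived
from them through the same combinators the real pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse

from . import features as ft
from .cohort import CohortFeatureStore, Subject
from .mesh import SurfaceMesh, SymmetricTemplate, geodesic_distance

__all__ = [
    "SiteConfig",
    "LesionArchetype",
    "SyntheticConfig",
    "GroundTruth",
    "DEFAULT_ARCHETYPES",
    "make_template",
    "simulate_cohort",
]


@dataclass
class SiteConfig:
    """One scanning site of the synthetic cohort."""

    site_id: str
    n_patients: int
    n_controls: int
    scanner: str = "3T"  # "1.5T" | "3T"
    flair_fraction: float = 0.7
    additive_shift: dict[str, float] = field(default_factory=dict)  # raw units
    scale: dict[str, float] = field(default_factory=dict)  # multiplicative

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("subject counts must be non-negative")
        if any(v <= 0 for v in self.scale.values()):
            raise ValueError("multiplicative scales must be positive")


@dataclass
class LesionArchetype:
    """Named per-feature lesional offset pattern, in control-SD units."""

    name: str
    offsets: dict[str, float]


DEFAULT_ARCHETYPES = (
    LesionArchetype(
        "group1",
        {
            "thickness": 2.0,
            "intrinsic_curvature": 2.0,
            "gw_contrast": -2.0,
            "wm_flair_0.5mm": 1.5,
            "wm_flair_1mm": 1.5,
        },
    ),
    LesionArchetype(
        "group2",
        {
            "gw_contrast": -2.0,
            "intrinsic_curvature": 1.0,
            "gm_flair_25": -1.5,
            "gm_flair_50": -1.5,
            "gm_flair_75": -1.5,
        },
    ),
    LesionArchetype(
        "group3",
        {
            "thickness": 0.3,
            "gw_contrast": -0.3,
            "gm_flair_50": -0.2,
            "intrinsic_curvature": 0.2,
        },
    ),
)

# plausible raw-unit control levels: (mean, noise SD, spatial-pattern SD).
# The spatial pattern is kept at 30% of the noise SD so the across-vertex
# (intrasubject) and per-vertex (control-reference) SD scales stay
# commensurate and planted effect sizes survive both normalizations.
_CONTROL_LEVELS = {
    "thickness": (2.5, 0.25, 0.075),
    "gw_contrast": (0.85, 0.04, 0.012),
    "sulcal_depth": (0.0, 3.0, 0.9),
    "gm_flair_25": (110.0, 6.0, 1.8),
    "gm_flair_50": (105.0, 6.0, 1.8),
    "gm_flair_75": (100.0, 6.0, 1.8),
    "flair_boundary": (95.0, 6.0, 1.8),
    "wm_flair_0.5mm": (90.0, 6.0, 1.8),
    "wm_flair_1mm": (85.0, 6.0, 1.8),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``age_slope`` and ``sex_offset`` are raw feature units per year and per
    male sex respectively; lesion ``effect_scale`` multiplies every archetype
    offset (1.0 keeps the defaults).
    """

    sites: list[SiteConfig] = field(
        default_factory=lambda: [
            SiteConfig("siteA", 24, 16, "3T", 0.8),
            SiteConfig("siteB", 24, 16, "1.5T", 0.6),
            SiteConfig("siteC", 24, 16, "3T", 0.7),
        ]
    )
    subdivision_level: int = 5
    radius_mm: float = 60.0
    noise_fwhm_mm: float = 15.0
    age_slope: dict[str, float] = field(
        default_factory=lambda: {"thickness": -0.01}
    )
    sex_offset: dict[str, float] = field(
        default_factory=lambda: {"thickness": 0.05}
    )
    lesion_radius_range: tuple[float, float] = (15.0, 30.0)
    archetypes: tuple[LesionArchetype, ...] = DEFAULT_ARCHETYPES
    archetype_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    effect_scale: float = 1.0
    age_range: tuple[float, float] = (3.0, 60.0)
    rng_seed: int = 0
    #: seeds the shared "population anatomy" (per-vertex mean maps); cohorts
    #: with different rng_seed but equal anatomy_seed sample one population
    anatomy_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion radii must be positive and ordered")
        if len(self.archetype_weights) != len(self.archetypes):
            raise ValueError("one weight per archetype required")


@dataclass
class GroundTruth:
    """What was planted: site effects and per-lesion provenance."""

    site_additive: dict[str, dict[str, float]]
    site_scale: dict[str, dict[str, float]]
    lesions: dict[str, dict]  # subject_id -> {archetype, hemi, seed, radius_mm}


# ---------------------------------------------------------------------------


def make_template(
    subdivision_level: int, radius_mm: float = 60.0, wall_cap: float = 0.92
) -> SymmetricTemplate:
    """Two mirrored icospheres with a polar non-cortex cap.

    A level-n icosphere has 10*4**n + 2 vertices.  The right hemisphere is
    the exact mirror image of the left across the x = 0 plane; vertices with
    z/r above ``wall_cap`` are marked non-cortex (medial-wall stand-in).
    """
    if subdivision_level < 1:
        raise ValueError("subdivision_level must be >= 1")
    ico = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=radius_mm)
    verts = np.asarray(ico.vertices, dtype=float)
    tris = np.asarray(ico.faces, dtype=np.int64)
    cortex = verts[:, 2] / radius_mm < wall_cap
    shift = np.array([1.25 * radius_mm, 0.0, 0.0])
    left = SurfaceMesh(verts - shift, tris, cortex)
    right = SurfaceMesh((verts - shift) * np.array([-1.0, 1.0, 1.0]), tris, cortex)
    return SymmetricTemplate(left, right)


def _unit_variance_smoother(mesh: SurfaceMesh, fwhm: float) -> sparse.csr_matrix:
    """Smoothing operator rescaled so smoothed white noise has unit variance."""
    W = mesh.smoothing_matrix(fwhm)
    sq = W.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.sum(axis=1)).ravel()
    var[var == 0] = 1.0
    return sparse.diags(1.0 / np.sqrt(var)) @ W


def _smooth_noise(S: sparse.csr_matrix, rng, n_cols: int, n_vert: int) -> np.ndarray:
    return S @ rng.standard_normal((n_vert, n_cols))


def _folding_pattern(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sinusoidal folding-like base for k1, k2 (1/mm)."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1, 1))
    phi = np.arctan2(v[:, 1], np.abs(v[:, 0]))  # |x|: mirror-symmetric
    k1 = 0.08 * np.sin(6 * theta) * np.cos(4 * phi) + 1.0 / r
    k2 = 0.05 * np.cos(5 * theta + 2 * phi) - 0.02
    return k1, k2


def simulate_cohort(
    config: SyntheticConfig, template: SymmetricTemplate | None = None
) -> tuple[CohortFeatureStore, GroundTruth]:
    """Generate a cohort store with planted site effects and lesions.

    Bit-reproducible under ``config.rng_seed``.  FLAIR features of subjects
    without FLAIR are NaN.  Patient lesion masks are stored in the returned
    store; archetype assignments and site effects come back as ground truth.
    """
    rng = np.random.default_rng(config.rng_seed)
    if template is None:
        template = make_template(config.subdivision_level, config.radius_mm)
    n_vert = template.n_vertices
    cortex = template.cortex_mask
    names = ft.BASE_FEATURES
    smoothers = {
        h: _unit_variance_smoother(template.hemi(h), config.noise_fwhm_mm)
        for h in ("left", "right")
    }

    # shared "anatomy": smooth per-vertex mean surfaces, identical across subjects
    anatomy_rng = np.random.default_rng(np.random.SeedSequence([config.anatomy_seed, 7]))
    mean_maps = {}
    for h in ("left", "right"):
        g = _smooth_noise(smoothers[h], anatomy_rng, len(_CONTROL_LEVELS), n_vert)
        mean_maps[h] = {
            name: m + amp * g[:, j]
            for j, (name, (m, _sd, amp)) in enumerate(_CONTROL_LEVELS.items())
        }

    subjects: list[Subject] = []
    for site in config.sites:
        for i in range(site.n_patients + site.n_controls):
            group = "patient" if i < site.n_patients else "control"
            subjects.append(
                Subject(
                    subject_id=f"{site.site_id}_{group[0]}{i:03d}",
                    group=group,
                    site_id=site.site_id,
                    scanner=site.scanner,
                    age_at_scan=float(rng.uniform(*config.age_range)),
                    sex=int(rng.integers(0, 2)),
                    flair_available=bool(rng.random() < site.flair_fraction),
                    operated=bool(rng.random() < 0.6) if group == "patient" else None,
                )
            )
    store = CohortFeatureStore(template, subjects, names)
    base = store.features["base"]
    site_map = {s.site_id: s for s in config.sites}

    arch_names = [a.name for a in config.archetypes]
    weights = np.asarray(config.archetype_weights, dtype=float)
    weights = weights / weights.sum()
    truth = GroundTruth(
        site_additive={s.site_id: dict(s.additive_shift) for s in config.sites},
        site_scale={s.site_id: dict(s.scale) for s in config.sites},
        lesions={},
    )
    cortex_idx = np.flatnonzero(cortex)

    for si, subj in enumerate(subjects):
        site = site_map[subj.site_id]
        for hi, hemi in enumerate(("left", "right")):
            eps = _smooth_noise(smoothers[hemi], rng, 11, n_vert)
            vals = np.empty((n_vert, len(names)))
            k1b, k2b = _folding_pattern(template.hemi(hemi))
            k1 = k1b + 0.02 * eps[:, 9]
            k2 = k2b + 0.02 * eps[:, 10]
            for fi, name in enumerate(names):
                if name == "mean_curvature":
                    vals[:, fi] = ft.mean_curvature(k1, k2)
                elif name == "intrinsic_curvature":
                    vals[:, fi] = ft.intrinsic_curvature(k1, k2)
                else:
                    m, sd, _amp = _CONTROL_LEVELS[name]
                    j = list(_CONTROL_LEVELS).index(name)
                    x = mean_maps[hemi][name] + sd * site.scale.get(name, 1.0) * eps[:, j]
                    x = x + subj.age_at_scan * config.age_slope.get(name, 0.0)
                    x = x + subj.sex * config.sex_offset.get(name, 0.0)
                    x = x + site.additive_shift.get(name, 0.0)
                    vals[:, fi] = x
            base[si, hi] = vals

        if subj.is_patient:
            k = int(rng.choice(len(arch_names), p=weights))
            arch = config.archetypes[k]
            hemi = "left" if rng.random() < 0.5 else "right"
            hi = ("left", "right").index(hemi)
            seed_v = int(rng.choice(cortex_idx))
            radius = float(rng.uniform(*config.lesion_radius_range))
            d = geodesic_distance(template.hemi(hemi), [seed_v], max_dist=radius)
            mask = np.isfinite(d)
            # offsets in units of the subject's across-cortex SD (both hemis)
            for fname, off in arch.offsets.items():
                fi = names.index(fname)
                sd_subj = np.std(
                    np.concatenate([base[si, 0, cortex, fi], base[si, 1, cortex, fi]])
                )
                base[si, hi, mask, fi] += config.effect_scale * off * sd_subj
            store.set_lesion_mask(subj.subject_id, hemi, mask)
            truth.lesions[subj.subject_id] = {
                "archetype": arch.name,
                "hemisphere": hemi,
                "seed_vertex": seed_v,
                "radius_mm": radius,
            }

        if not subj.flair_available:
            flair_cols = [names.index(f) for f in ft.FLAIR_FEATURES]
            base[si, :, :, flair_cols] = np.nan

    base[:, :, ~cortex, :] = 0.0
    store.log_stage(
        "synthetic",
        seed=config.rng_seed,
        n_subjects=len(subjects),
        subdivision_level=config.subdivision_level,
    )
    return store, truth
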