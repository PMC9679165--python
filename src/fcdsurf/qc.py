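"""Automated quality control: region-wise outlier detection.

A feature is flagged for a subject when its regional mean deviates from the
cohort mean of that region by more than 2.7 cohort SDs in strictly more
than 10 non-lesional regions; subjects with at least two such features
(T1-only) or at least three (FLAIR available) are excluded.

Regions come from a cortical parcellation.  On the synthetic template a
Desikan–Killiany stand-in is built as geodesic Voronoi regions grown from
farthest-point seeds, mirrored across hemispheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortFeatureStore
from .mesh import SymmetricTemplate, geodesic_distance

__all__ = [
    "Parcellation",
    "make_parcellation",
    "regional_summaries",
    "detect_outlier_features",
    "flag_outlier_subjects",
    "run_qc",
]

OUTLIER_SD = 2.7
OUTLIER_MIN_REGIONS = 10  # strictly more than this many regions
MAX_FEATURES_T1 = 2  # >= 2 outlier features excludes a T1-only subject
MAX_FEATURES_FLAIR = 3

_MIN_REGIONS = 12


@dataclass
class Parcellation:
    """Vertex labels 1..n_regions per hemisphere (0 = medial wall)."""

    labels: np.ndarray  # (n_vertices,), identical for both hemispheres
    n_regions: int

    def region_vertices(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.labels == region)


def make_parcellation(
    template: SymmetricTemplate, n_regions: int = 34
) -> Parcellation:
    """Geodesic Voronoi parcellation from farthest-point seeds.

    Deterministic: the first seed is the lowest-index cortex vertex and each
    subsequent seed is the cortex vertex farthest from all previous seeds.
    The same labels apply to both hemispheres (mirrored template).
    """
    mesh = template.left
    cortex = np.flatnonzero(mesh.cortex_mask)
    if n_regions < 2 or n_regions > len(cortex):
        raise ValueError("invalid region count")
    seeds = [int(cortex[0])]
    dmin = geodesic_distance(mesh, seeds[:1])
    while len(seeds) < n_regions:
        cand = int(cortex[np.argmax(dmin[cortex])])
        seeds.append(cand)
        dmin = np.minimum(dmin, geodesic_distance(mesh, [cand]))
    dists = np.stack([geodesic_distance(mesh, [s]) for s in seeds])
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[mesh.cortex_mask] = np.argmin(dists[:, mesh.cortex_mask], axis=0) + 1
    return Parcellation(labels, n_regions)


def regional_summaries(
    store: CohortFeatureStore,
    parcellation: Parcellation,
    feature_set: str = "base",
) -> np.ndarray:
    """Mean of each feature over each region's cortex vertices.

    Returns an array of shape (n_subjects, 2, n_regions, n_features); the
    region axis indexes regions 1..n_regions of each hemisphere.
    """
    src = store.features[feature_set]
    n_sub, _, _, n_feat = src.shape
    out = np.full((n_sub, 2, parcellation.n_regions, n_feat), np.nan)
    with warnings.catch_warnings():
        # all-NaN feature columns (missing FLAIR) are expected
        warnings.simplefilter("ignore", RuntimeWarning)
        for r in range(1, parcellation.n_regions + 1):
            verts = parcellation.region_vertices(r)
            out[:, :, r - 1, :] = np.nanmean(src[:, :, verts, :], axis=2)
    return out


def detect_outlier_features(
    store: CohortFeatureStore,
    parcellation: Parcellation,
    feature_set: str = "base",
) -> dict[str, set[str]]:
    """Per subject, the set of features failing the regional outlier rule.

    Cohort mean/SD are computed per (hemisphere, region, feature) over all
    participants, including the candidate subject.  Regions intersecting a
    patient's lesion mask are non-informative for that patient and are
    skipped.
    """
    if parcellation.n_regions < _MIN_REGIONS:
        raise ValueError(
            f"parcellation must have at least {_MIN_REGIONS} regions "
            f"for the >{OUTLIER_MIN_REGIONS}-region rule to be meaningful"
        )
    summ = regional_summaries(store, parcellation, feature_set)
    mean = np.nanmean(summ, axis=0)  # (2, R, F)
    sd = np.nanstd(summ, axis=0)
    extreme = np.abs(summ - mean[None]) > OUTLIER_SD * sd[None]

    # mask out lesional regions per patient
    lesional = np.zeros(summ.shape[:3], dtype=bool)  # (n_sub, 2, R)
    for sid, (hemi, mask) in store.lesion_masks.items():
        si, hi = store.idx(sid), ("left", "right").index(hemi)
        regions = np.unique(parcellation.labels[mask])
        for r in regions[regions > 0]:
            lesional[si, hi, r - 1] = True
    extreme &= ~lesional[..., None]
    extreme &= ~np.isnan(summ)

    counts = extreme.sum(axis=(1, 2))  # (n_sub, F)
    result: dict[str, set[str]] = {}
    for si, subj in enumerate(store.subjects):
        flagged = {
            store.feature_names[fi]
            for fi in np.flatnonzero(counts[si] > OUTLIER_MIN_REGIONS)
        }
        result[subj.subject_id] = flagged
    return result


def flag_outlier_subjects(
    outlier_features: dict[str, set[str]],
    store: CohortFeatureStore,
) -> pd.DataFrame:
    """Exclusion decisions: one row per subject with reasons.

    A subject is excluded when it has >= 2 outlier features (T1-only) or
    >= 3 (FLAIR available).
    """
    rows = []
    for subj in store.subjects:
        flagged = sorted(outlier_features.get(subj.subject_id, set()))
        limit = MAX_FEATURES_FLAIR if subj.flair_available else MAX_FEATURES_T1
        rows.append(
            {
                "subject_id": subj.subject_id,
                "flair_available": subj.flair_available,
                "n_outlier_features": len(flagged),
                "outlier_features": ";".join(flagged),
                "excluded": len(flagged) >= limit,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def run_qc(
    store: CohortFeatureStore,
    parcellation: Parcellation | None = None,
    feature_set: str = "base",
) -> pd.DataFrame:
    """Full QC pass; logs the exclusions on the store's provenance."""
    if parcellation is None:
        parcellation = make_parcellation(store.template)
    report = flag_outlier_subjects(
        detect_outlier_features(store, parcellation, feature_set), store
    )
    store.log_stage(
        "qc", excluded=sorted(report.index[report["excluded"]].tolist())
    )
    return report
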