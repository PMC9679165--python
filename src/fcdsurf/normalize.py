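"""Three-stage feature normalization.

Starting from the harmonized ("combat") features the pipeline produces two
further feature sets:

1. *intrasubject z-scoring* — per subject and feature, z-score across all
   cortex vertices of both hemispheres, absorbing inter-individual shifts
   (for example age-related global thinning);
2. *interhemispheric asymmetry* — left minus right (and vice versa) on the
   symmetric template, exposing unilateral abnormality;
3. *control normalization* — per-vertex z-scoring by the healthy-control
   mean and SD of the same stage, absorbing normal regional variability.

Stage-1 output normalized by controls is the "normalized" set; stage-2
output normalized by controls is the "asymmetry" set.  The control
reference is built from (train-cohort) controls only.

Missing FLAIR features (NaN) stay NaN through every stage; imputation
happens only at classifier-input assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import CohortFeatureStore

__all__ = [
    "ControlReference",
    "intrasubject_zscore",
    "interhemispheric_asymmetry",
    "build_control_reference",
    "control_normalize",
    "run_normalization",
]

#: control-SD floor (z-units) protecting near-constant vertices
SD_FLOOR = 1e-3


@dataclass
class ControlReference:
    """Per-vertex control mean/SD for one feature set stage."""

    feature_set: str
    mean: np.ndarray  # (2, n_vertices, n_features)
    sd: np.ndarray  # (2, n_vertices, n_features), floored positive
    n_controls: int


def intrasubject_zscore(
    store: CohortFeatureStore, feature_set: str = "combat", dest: str = "intra"
) -> np.ndarray:
    """Z-score each subject's features across cortex vertices of both hemispheres.

    Features that are entirely missing for a subject (no FLAIR) remain NaN.
    A finite feature with zero within-subject variance is an error naming the
    subject and feature.
    """
    src = store.features[feature_set]
    cortex = store.template.cortex_mask
    out = np.zeros_like(src)
    for si, subj in enumerate(store.subjects):
        block = src[si][:, cortex, :]  # (2, n_cortex, f)
        pooled = block.reshape(-1, block.shape[-1])
        with warnings.catch_warnings():
            # all-NaN feature columns (missing FLAIR) are expected
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(pooled, axis=0)
            sd = np.nanstd(pooled, axis=0)
        all_nan = np.all(np.isnan(pooled), axis=0)
        bad = (~all_nan) & (sd == 0)
        if bad.any():
            fname = store.feature_names[int(np.flatnonzero(bad)[0])]
            raise ValueError(
                f"zero within-subject variance: subject {subj.subject_id!r}, "
                f"feature {fname!r}"
            )
        sd = np.where(all_nan, np.nan, sd)
        z = (src[si] - mean) / sd
        z[:, ~cortex, :] = 0.0
        out[si] = z
    store.features[dest] = out
    store.log_stage("intrasubject_zscore", source=feature_set)
    return out


def interhemispheric_asymmetry(
    store: CohortFeatureStore, feature_set: str = "intra", dest: str = "asym_raw"
) -> np.ndarray:
    """Left-minus-right (and right-minus-left) maps in template correspondence.

    By construction ``asym_left[v] == -asym_right[v]`` exactly.
    """
    src = store.features[feature_set]
    out = np.empty_like(src)
    out[:, 0] = src[:, 0] - src[:, 1]
    out[:, 1] = src[:, 1] - src[:, 0]
    out[:, :, ~store.template.cortex_mask, :] = 0.0
    store.features[dest] = out
    store.log_stage("asymmetry", source=feature_set)
    return out


def build_control_reference(
    store: CohortFeatureStore,
    feature_set: str,
    control_ids: list[str] | None = None,
) -> ControlReference:
    """Per-vertex mean/SD over healthy controls for one feature set.

    ``control_ids`` restricts the reference (typically to train-cohort
    controls); patients are always excluded.  SDs below the floor are
    clamped.
    """
    ids = [
        s.subject_id
        for s in store.controls()
        if control_ids is None or s.subject_id in set(control_ids)
    ]
    if len(ids) < 2:
        raise ValueError("need at least two controls to build a reference")
    rows = [store.idx(sid) for sid in ids]
    block = store.features[feature_set][rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(block, axis=0)
        sd = np.nanstd(block, axis=0)
    sd = np.where(np.isnan(sd), np.nan, np.maximum(sd, SD_FLOOR))
    return ControlReference(feature_set, mean, sd, len(ids))


def control_normalize(
    store: CohortFeatureStore,
    feature_set: str,
    reference: ControlReference,
    dest: str,
) -> np.ndarray:
    """Z-score a feature set by the per-vertex control reference."""
    if reference.mean.shape[1] != store.template.n_vertices:
        raise ValueError("reference/template vertex-count mismatch")
    src = store.features[feature_set]
    out = (src - reference.mean[None]) / reference.sd[None]
    out[:, :, ~store.template.cortex_mask, :] = 0.0
    store.features[dest] = out
    store.log_stage("control_normalize", source=feature_set, dest=dest)
    return out


def run_normalization(
    store: CohortFeatureStore,
    control_ids: list[str] | None = None,
    source: str = "combat",
) -> tuple[ControlReference, ControlReference]:
    """Run the full three-stage normalization, producing "normalized" and
    "asymmetry" feature sets.  Refuses to run twice on the same store.

    Returns the two control references (stage-1 and stage-2) so test
    subjects can be normalized against the training-time reference.
    """
    if "normalized" in store.features or "asymmetry" in store.features:
        raise RuntimeError("normalization already ran on this store")
    intrasubject_zscore(store, source, dest="intra")
    interhemispheric_asymmetry(store, "intra", dest="asym_raw")
    ref_intra = build_control_reference(store, "intra", control_ids)
    ref_asym = build_control_reference(store, "asym_raw", control_ids)
    control_normalize(store, "intra", ref_intra, dest="normalized")
    control_normalize(store, "asym_raw", ref_asym, dest="asymmetry")
    # the harmonized block itself, scaled per vertex by control statistics:
    # puts all classifier inputs in z-units so the zero vector (the saliency
    # baseline and the missing-FLAIR imputation constant) is the control mean
    ref_combat = build_control_reference(store, source, control_ids)
    control_normalize(store, source, ref_combat, dest="combat_z")
    return ref_intra, ref_asym
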