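"""End-to-end orchestration of the detection pipeline.

Glue for the common sequences: annotate lesions with border zones, run the
post-processing stages, train the ensemble, predict and score a cohort.
Each step delegates to its module; nothing here adds behaviour beyond
wiring and bookkeeping.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .cohort import CohortFeatureStore, CohortSplit, split_cohort
from .evaluate import CohortMetrics, compute_metrics, form_clusters
from .harmonize import ComBatModel, fit_combat
from .lesions import LesionAnnotation, fill_mask_defects, make_border_zones
from .network import EnsembleModel, TrainingConfig, predict, train_ensemble
from .normalize import run_normalization

__all__ = [
    "annotate_cohort",
    "prepare_features",
    "train_detector",
    "evaluate_cohort",
    "vertex_auc",
]


def annotate_cohort(
    store: CohortFeatureStore, close: bool = True, n_close_iter: int = 5
) -> dict[str, LesionAnnotation]:
    """Close every patient's lesion mask and build its 20/40 mm rings."""
    annotations = {}
    for sid, (hemi, mask) in store.lesion_masks.items():
        mesh = store.template.hemi(hemi)
        closed = fill_mask_defects(mask, mesh, n_close_iter) if close else mask
        annotations[sid] = make_border_zones(closed, mesh, hemi)
    return annotations


def prepare_features(
    store: CohortFeatureStore,
    split: CohortSplit | None = None,
    eb: bool = True,
) -> ComBatModel:
    """Harmonize and normalize a cohort in place (combat -> three stages).

    The control reference uses train-cohort controls when a split is given.
    """
    model = fit_combat(store, eb=eb)
    control_ids = split.train_ids if split is not None else None
    run_normalization(store, control_ids=control_ids)
    return model


def train_detector(
    store: CohortFeatureStore,
    config: TrainingConfig,
    split: CohortSplit | None = None,
    annotations: dict[str, LesionAnnotation] | None = None,
) -> tuple[EnsembleModel, CohortSplit, dict[str, LesionAnnotation]]:
    """Split, annotate and train; returns model, split and annotations."""
    if split is None:
        split = split_cohort(store, n_folds=config.n_folds, seed=config.seed)
    if annotations is None:
        annotations = annotate_cohort(store)
    model = train_ensemble(store, split, annotations, config)
    return model, split, annotations


def evaluate_cohort(
    model: EnsembleModel,
    store: CohortFeatureStore,
    annotations: dict[str, LesionAnnotation],
    subject_ids: list[str] | None = None,
    min_size: int | None = None,
) -> CohortMetrics:
    """Predict every subject, form clusters and compute cohort metrics."""
    from .evaluate import MIN_CLUSTER_SIZE

    if min_size is None:
        min_size = MIN_CLUSTER_SIZE
    ids = subject_ids if subject_ids is not None else store.subject_ids
    clusters = {}
    for sid in ids:
        probs, binary = predict(model, store, sid)
        clusters[sid] = form_clusters(binary, store.template, sid, probs, min_size)
    subjects = [store.subject(sid) for sid in ids]
    return compute_metrics(clusters, annotations, subjects)


def vertex_auc(
    model: EnsembleModel,
    store: CohortFeatureStore,
    annotations: dict[str, LesionAnnotation],
    subject_ids: list[str],
) -> float:
    """Vertex-level ROC AUC over patients: lesional vs non-excluded cortex."""
    scores, labels = [], []
    cortex = store.template.cortex_mask
    for sid in subject_ids:
        if not store.subject(sid).is_patient:
            continue
        ann = annotations[sid]
        probs, _ = predict(model, store, sid)
        hi = ("left", "right").index(ann.hemisphere)
        keep = cortex & ~(ann.ring20 | ann.ring40)
        scores.append(probs[hi][keep])
        labels.append(ann.mask[keep])
        other = 1 - hi
        scores.append(probs[other][cortex])
        labels.append(np.zeros(int(cortex.sum()), dtype=bool))
    return float(roc_auc_score(np.concatenate(labels), np.concatenate(scores)))
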