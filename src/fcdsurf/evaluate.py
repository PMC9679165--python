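"""Cluster formation, cohort-level detection metrics and factor regression.

Thresholded vertex predictions are grouped into spatially connected
clusters per hemisphere; clusters below 100 vertices are filtered out as
disproportionately false positive.  Cohort metrics follow the surface-
detection conventions: a patient counts as detected when any cluster shares
at least one vertex with the lesion mask (sensitivity) or with the mask
plus its 20 mm border ring (sensitivity+); specificity is the fraction of
controls with zero post-filter clusters.

Whether clinical/demographic factors influence detection is assessed with
logistic regression fit by IRLS, permutation p-values (outcome labels
permuted) and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lesions import LesionAnnotation
from .mesh import SurfaceMesh, connected_components

__all__ = [
    "PredictedCluster",
    "CohortMetrics",
    "MIN_CLUSTER_SIZE",
    "form_clusters",
    "compute_metrics",
    "logistic_irls",
    "detection_factor_regression",
]

MIN_CLUSTER_SIZE = 100

HEMIS = ("left", "right")


@dataclass
class PredictedCluster:
    subject_id: str
    hemisphere: str
    vertices: np.ndarray
    mean_probability: float
    overlaps_mask: bool = False
    overlaps_border20: bool = False

    @property
    def size(self) -> int:
        return len(self.vertices)


@dataclass
class CohortMetrics:
    sensitivity: float
    sensitivity_plus: float
    specificity: float
    clusters_per_patient: tuple[float, float, float]  # median, q1, q3
    clusters_per_control: tuple[float, float, float]
    detection_table: pd.DataFrame = field(repr=False, default=None)


def form_clusters(
    binary: np.ndarray,
    template,
    subject_id: str = "",
    probabilities: np.ndarray | None = None,
    min_size: int = MIN_CLUSTER_SIZE,
) -> list[PredictedCluster]:
    """Connected clusters of a (2, n_vertices) boolean prediction.

    Components smaller than ``min_size`` vertices are removed; survivors
    are sorted by size, largest first.
    """
    clusters: list[PredictedCluster] = []
    for hi, hemi in enumerate(HEMIS):
        mesh: SurfaceMesh = template.hemi(hemi)
        labels, sizes = connected_components(mesh, binary[hi])
        for lab, size in enumerate(sizes, start=1):
            if size < min_size:
                continue
            verts = np.flatnonzero(labels == lab)
            mp = float(probabilities[hi][verts].mean()) if probabilities is not None else np.nan
            clusters.append(PredictedCluster(subject_id, hemi, verts, mp))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def compute_metrics(
    clusters_by_subject: dict[str, list[PredictedCluster]],
    annotations: dict[str, LesionAnnotation],
    subjects,
) -> CohortMetrics:
    """Cohort detection metrics from per-subject cluster lists.

    ``subjects`` is any iterable of :class:`~fcdsurf.cohort.Subject`; every
    patient must have an annotation.
    """
    rows = []
    for subj in subjects:
        clusters = clusters_by_subject.get(subj.subject_id, [])
        n_clusters = len(clusters)
        if subj.is_patient:
            ann = annotations.get(subj.subject_id)
            if ann is None:
                raise KeyError(f"patient {subj.subject_id!r} has no annotation")
            detected = detected_plus = False
            for c in clusters:
                if c.hemisphere != ann.hemisphere:
                    continue
                in_c = np.zeros_like(ann.mask)
                in_c[c.vertices] = True
                c.overlaps_mask = bool((in_c & ann.mask).any())
                c.overlaps_border20 = bool((in_c & (ann.mask | ann.ring20)).any())
                detected |= c.overlaps_mask
                detected_plus |= c.overlaps_border20
            rows.append(
                dict(
                    subject_id=subj.subject_id,
                    group="patient",
                    n_clusters=n_clusters,
                    detected=detected,
                    detected_plus=detected_plus,
                )
            )
        else:
            rows.append(
                dict(
                    subject_id=subj.subject_id,
                    group="control",
                    n_clusters=n_clusters,
                    detected=np.nan,
                    detected_plus=np.nan,
                )
            )
    table = pd.DataFrame(rows).set_index("subject_id")
    pat = table[table.group == "patient"]
    ctl = table[table.group == "control"]

    def _summary(counts):
        if len(counts) == 0:
            return (np.nan, np.nan, np.nan)
        return tuple(float(np.percentile(counts, q)) for q in (50, 25, 75))

    return CohortMetrics(
        sensitivity=float(pat.detected.mean()) if len(pat) else np.nan,
        sensitivity_plus=float(pat.detected_plus.mean()) if len(pat) else np.nan,
        specificity=float((ctl.n_clusters == 0).mean()) if len(ctl) else np.nan,
        clusters_per_patient=_summary(pat.n_clusters.to_numpy()),
        clusters_per_control=_summary(ctl.n_clusters.to_numpy()),
        detection_table=table,
    )


# ---------------------------------------------------------------------------
# detection-factor regression
# ---------------------------------------------------------------------------


def logistic_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """Logistic regression by iteratively reweighted least squares.

    ``X`` excludes the intercept (added internally).  Returns coefficients
    (intercept first) and a convergence flag; separation is reported as
    non-convergence.
    """
    X = np.c_[np.ones(len(X)), np.asarray(X, dtype=float)]
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        if np.abs(beta).max() > 20:  # quasi-separation guard
            break
        XtW = X.T * W
        try:
            delta = np.linalg.solve(XtW @ X + 1e-10 * np.eye(X.shape[1]), X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.abs(delta).max() < tol:
            converged = True
            break
    return beta, converged


def detection_factor_regression(
    table: pd.DataFrame,
    factors: list[str],
    outcome: str = "detected",
    n_perm: int = 1000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Permutation logistic regression of detection on clinical factors.

    The outcome labels are permuted within the cohort, preserving the
    correlation structure among factors; two-sided p-values use |beta|,
    p = (1 + #{|b_perm| >= |b_obs|}) / (1 + n_perm), and the Benjamini-
    Hochberg procedure is applied across the factors at ``q``.
    """
    df = table.dropna(subset=[outcome, *factors])
    X = df[factors].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    beta_obs, conv = logistic_irls(X, y)
    if not conv:
        warnings.warn("logistic regression did not converge (separation?)", stacklevel=2)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factors))
    for _ in range(n_perm):
        b_perm, _ = logistic_irls(X, rng.permutation(y))
        exceed += np.abs(b_perm[1:]) >= np.abs(beta_obs[1:])
    p_perm = (1.0 + exceed) / (1.0 + n_perm)
    reject, p_adj, *_ = multipletests(p_perm, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {
            "beta": beta_obs[1:],
            "p_perm": p_perm,
            "p_bh": p_adj,
            "significant": reject,
            "converged": conv,
        },
        index=factors,
    )
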