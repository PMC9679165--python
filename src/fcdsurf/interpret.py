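"""Interpretability: integrated-gradients saliency, lesion phenotyping and
per-patient reports.

Integrated gradients attribute the classifier output to the 33 input
features along the straight path from the zero baseline to the input,
approximated with a right Riemann sum; the completeness axiom
(sum of attributions = F(x) - F(0)) is verified for every report.

Lesion phenotyping summarises the T1-derived normalized features within
each lesion mask (with size-matched pseudo-lesions sampled on controls),
embeds the summaries with UMAP and clusters the 2-D coordinates with a
Gaussian mixture model (3 groups by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .cohort import CohortFeatureStore, assemble_classifier_input
from .features import BASE_FEATURES, FEATURE_SETS, T1_FEATURES
from .evaluate import PredictedCluster, form_clusters
from .mesh import geodesic_distance
from .network import EnsembleModel, predict
from .qc import Parcellation

__all__ = [
    "integrated_gradients",
    "completeness_residual",
    "lesion_feature_summary",
    "control_pseudo_lesions",
    "embed_and_cluster",
    "LesionPhenotype",
    "patient_report",
]

IG_STEPS = 256
COMPLETENESS_RTOL = 0.01

#: classifier input feature labels, "<set>:<feature>" in input order
INPUT_FEATURE_LABELS = tuple(
    f"{s}:{f}" for s in FEATURE_SETS for f in BASE_FEATURES
)


def integrated_gradients(model, x: np.ndarray, steps: int = IG_STEPS) -> np.ndarray:
    """Zero-baseline integrated gradients of the lesional probability.

    ``model`` is anything with an ``input_gradients`` method (a single MLP
    or the ensemble; the ensemble attribution equals the mean of member
    attributions).  Right Riemann sum:
    IG_i = x_i * (1/m) * sum_k dF/dx_i at (k/m) x, k = 1..m.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float)
    alphas = np.arange(1, steps + 1) / steps
    grads = model.input_gradients(alphas[:, None] * x[None, :])
    return x * grads.mean(axis=0)


def completeness_residual(model, x: np.ndarray, steps: int = IG_STEPS) -> float:
    """|sum IG - (F(x) - F(0))| for a single input vector."""
    ig = integrated_gradients(model, x, steps)
    fx = float(model.predict_proba(np.asarray(x, dtype=float)[None, :])[0])
    f0 = float(model.predict_proba(np.zeros((1, len(x))))[0])
    return abs(float(ig.sum()) - (fx - f0))


# ---------------------------------------------------------------------------
# lesion phenotyping
# ---------------------------------------------------------------------------


def lesion_feature_summary(
    store: CohortFeatureStore,
    vertex_sets: dict[str, tuple[str, np.ndarray]],
    feature_set: str = "normalized",
    features: tuple[str, ...] = T1_FEATURES,
) -> pd.DataFrame:
    """Mean features over each vertex set.

    ``vertex_sets`` maps a set key (subject id or pseudo-lesion id) to a
    ``(hemisphere, vertex index array)`` pair.  Empty sets raise.
    """
    cols = [store.feature_names.index(f) for f in features]
    rows = {}
    for key, (hemi, verts) in vertex_sets.items():
        verts = np.asarray(verts)
        if verts.size == 0:
            raise ValueError(f"empty vertex set {key!r}")
        sid = key.split("@")[0]
        block = store.get(feature_set, sid, hemi)
        rows[key] = block[verts][:, cols].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(features))


def control_pseudo_lesions(
    store: CohortFeatureStore,
    sizes: list[int],
    seed: int = 0,
) -> dict[str, tuple[str, np.ndarray]]:
    """Random geodesic discs on controls, size-matched to patient lesions.

    One pseudo-lesion per control, cycling through the requested sizes; the
    disc radius is grown until the vertex count is within 10% of (or first
    exceeds) the target size.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[str, np.ndarray]] = {}
    cortex_idx = np.flatnonzero(store.template.cortex_mask)
    for i, subj in enumerate(store.controls()):
        target = sizes[i % len(sizes)]
        hemi = "left" if rng.random() < 0.5 else "right"
        mesh = store.template.hemi(hemi)
        seed_v = int(rng.choice(cortex_idx))
        d = geodesic_distance(mesh, [seed_v])
        order = np.argsort(d)
        verts = order[: max(target, 1)]
        verts = verts[np.isfinite(d[verts])]
        out[f"{subj.subject_id}@pseudo"] = (hemi, verts)
    return out


@dataclass
class LesionPhenotype:
    """UMAP coordinates and mixture-group assignment for one lesion."""

    key: str
    embedding: tuple[float, float]
    group: int
    mean_features: dict[str, float] = field(default_factory=dict)


def embed_and_cluster(
    summaries: pd.DataFrame, n_groups: int = 3, seed: int = 0
) -> tuple[list[LesionPhenotype], np.ndarray]:
    """UMAP embedding of feature summaries + GMM clustering of coordinates.

    Returns phenotypes (group = argmax responsibility, 1-based) and the raw
    (n, 2) embedding.  Deterministic under ``seed``.
    """
    import umap  # deferred: heavy import

    if len(summaries) < 5 * n_groups:
        raise ValueError("too few lesions for stable clustering")
    X = summaries.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate summaries: no variance to embed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap is chatty about random_state
        reducer = umap.UMAP(
            n_neighbors=15, min_dist=0.1, n_components=2, random_state=seed
        )
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
    gmm = GaussianMixture(n_components=n_groups, random_state=seed, n_init=5)
    labels = gmm.fit_predict(coords)
    phenos = [
        LesionPhenotype(
            key,
            (float(coords[i, 0]), float(coords[i, 1])),
            int(labels[i]) + 1,
            dict(summaries.iloc[i]),
        )
        for i, key in enumerate(summaries.index)
    ]
    return phenos, coords


# ---------------------------------------------------------------------------
# patient reports
# ---------------------------------------------------------------------------


def _cluster_location(cluster: PredictedCluster, store, parcellation) -> str:
    mesh = store.template.hemi(cluster.hemisphere)
    centroid = mesh.vertices[cluster.vertices].mean(axis=0)
    v = cluster.vertices[
        np.argmin(np.linalg.norm(mesh.vertices[cluster.vertices] - centroid, axis=1))
    ]
    return f"{cluster.hemisphere}_region_{int(parcellation.labels[v])}"


def patient_report(
    model: EnsembleModel,
    store: CohortFeatureStore,
    subject_id: str,
    parcellation: Parcellation,
    steps: int = IG_STEPS,
    min_size: int | None = None,
    out_dir=None,
) -> dict:
    """Structured per-patient report of predicted clusters.

    For each predicted cluster: hemisphere, size, cortical location
    (parcellation region of the cluster centroid), the 33 mean z-scored
    input features and their integrated-gradients saliencies with the
    completeness residual (report generation fails if the completeness
    axiom is violated beyond 1%).  Optionally renders a figure and writes
    ``report.json``/``report.png`` into ``out_dir``.
    """
    from .evaluate import MIN_CLUSTER_SIZE

    probs, binary = predict(model, store, subject_id)
    clusters = form_clusters(
        binary,
        store.template,
        subject_id,
        probs,
        MIN_CLUSTER_SIZE if min_size is None else min_size,
    )
    entries = []
    for i, c in enumerate(clusters):
        x = assemble_classifier_input(store, subject_id, c.hemisphere)
        x_mean = x[c.vertices].mean(axis=0)
        fx = float(model.predict_proba(x_mean[None])[0])
        f0 = float(model.predict_proba(np.zeros((1, len(x_mean))))[0])
        # the Riemann error is O(1/m); double the step count until the
        # completeness gate holds (strong lesional inputs saturate the
        # output sigmoid and need a finer path discretization)
        m = steps
        while True:
            ig = integrated_gradients(model, x_mean, m)
            residual = abs(float(ig.sum()) - (fx - f0))
            if residual <= max(COMPLETENESS_RTOL * abs(fx - f0), 1e-6):
                break
            if m >= 32 * steps:
                raise ArithmeticError(
                    f"integrated-gradients completeness violated for cluster {i}: "
                    f"residual {residual:.2e} vs |dF| {abs(fx - f0):.2e} at m={m}"
                )
            m *= 2
        entries.append(
            {
                "cluster": i + 1,
                "hemisphere": c.hemisphere,
                "size_vertices": int(c.size),
                "location": _cluster_location(c, store, parcellation),
                "mean_probability": float(c.mean_probability),
                "mean_features": dict(
                    zip(INPUT_FEATURE_LABELS, map(float, x_mean))
                ),
                "saliency": dict(zip(INPUT_FEATURE_LABELS, map(float, ig))),
                "completeness_residual": residual,
            }
        )
    report = {
        "subject_id": subject_id,
        "threshold": float(model.threshold),
        "n_clusters": len(entries),
        "message": "no clusters detected" if not entries else "",
        "clusters": entries,
    }
    if out_dir is not None:
        import pathlib

        d = pathlib.Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        (d / "report.json").write_text(json.dumps(report, indent=2))
        _render_report(report, d / "report.png")
    return report


def _render_report(report: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = max(len(report["clusters"]), 1)
    fig, axes = plt.subplots(n, 1, figsize=(10, 3.2 * n), squeeze=False)
    for ax, entry in zip(axes.ravel(), report["clusters"]):
        sal = np.array(list(entry["saliency"].values()))
        feats = np.array(list(entry["mean_features"].values()))
        colors = ["#c0392b" if s > 0 else "#2980b9" for s in sal]
        ax.bar(range(len(feats)), feats, color=colors)
        ax.set_xticks(range(len(feats)))
        ax.set_xticklabels(INPUT_FEATURE_LABELS, rotation=90, fontsize=5)
        ax.set_ylabel("mean z value")
        ax.set_title(
            f"{report['subject_id']} cluster {entry['cluster']} "
            f"({entry['location']}, {entry['size_vertices']} vertices); "
            "bar colour: saliency sign"
        )
    if not report["clusters"]:
        axes[0, 0].text(0.5, 0.5, "no clusters detected", ha="center")
        axes[0, 0].set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
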