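"""Feature registry, curvature combinators and the smoothing policy.

The pipeline consumes 11 per-vertex base features.  Five are morphological
(cortical thickness, grey-white contrast, mean curvature, sulcal depth,
intrinsic curvature) and six are FLAIR intensities sampled at cortical
depths 25/50/75% and subcortically at the boundary, 0.5 mm and 1 mm.
Thickness, contrast, sulcal depth and the FLAIR samples arrive as
precomputed per-vertex inputs (their volumetric definitions are upstream of
this package); the curvature features are derived here from the principal
curvatures k1, k2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASE_FEATURES",
    "T1_FEATURES",
    "FLAIR_FEATURES",
    "FEATURE_SETS",
    "CurvatureInputs",
    "SmoothingPolicy",
    "intrinsic_curvature",
    "mean_curvature",
    "apply_smoothing",
]

#: The 11 base features, in canonical order.
BASE_FEATURES = (
    "thickness",
    "gw_contrast",
    "mean_curvature",
    "sulcal_depth",
    "intrinsic_curvature",
    "gm_flair_25",
    "gm_flair_50",
    "gm_flair_75",
    "flair_boundary",
    "wm_flair_0.5mm",
    "wm_flair_1mm",
)

T1_FEATURES = BASE_FEATURES[:5]
FLAIR_FEATURES = BASE_FEATURES[5:]

#: Derived feature sets produced by the pipeline stages, in classifier order.
FEATURE_SETS = ("combat", "normalized", "asymmetry")

_DEFAULT_KERNELS = {
    "mean_curvature": 5.0,
    "sulcal_depth": 5.0,
    "thickness": 10.0,
    "gw_contrast": 10.0,
    "gm_flair_25": 10.0,
    "gm_flair_50": 10.0,
    "gm_flair_75": 10.0,
    "flair_boundary": 10.0,
    "wm_flair_0.5mm": 10.0,
    "wm_flair_1mm": 10.0,
    "intrinsic_curvature": 20.0,
}


@dataclass
class CurvatureInputs:
    """Principal curvatures k1, k2 per vertex (1/mm)."""

    k1: np.ndarray
    k2: np.ndarray

    def __post_init__(self) -> None:
        self.k1 = np.asarray(self.k1, dtype=float)
        self.k2 = np.asarray(self.k2, dtype=float)
        if self.k1.shape != self.k2.shape:
            raise ValueError("k1 and k2 must have equal shape")


@dataclass
class SmoothingPolicy:
    """Map feature name -> Gaussian kernel size in mm.

    Defaults follow the pipeline's convention: 5 mm for mean curvature and
    sulcal depth, 10 mm for thickness, grey-white contrast and all FLAIR
    features, 20 mm for intrinsic curvature.  Kernel sizes are interpreted
    as FWHM by default (``kernel_is_fwhm``).
    """

    kernels: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_KERNELS))
    kernel_is_fwhm: bool = True

    def kernel_for(self, feature: str) -> float:
        if feature not in self.kernels:
            raise KeyError(f"no smoothing kernel registered for feature {feature!r}")
        return self.kernels[feature]


def intrinsic_curvature(k1, k2) -> np.ndarray:
    """Intrinsic (Gaussian) curvature: the product k1 * k2 per vertex."""
    ci = CurvatureInputs(k1, k2)
    return ci.k1 * ci.k2


def mean_curvature(k1, k2, literal_reciprocal: bool = False) -> np.ndarray:
    """Mean curvature (k1 + k2) / 2 per vertex.

    ``literal_reciprocal`` instead returns 2 / (k1 + k2), the reciprocal of
    the mean — a dimensionally odd alternative reading kept available for
    comparison; it is never the default.
    """
    ci = CurvatureInputs(k1, k2)
    m = 0.5 * (ci.k1 + ci.k2)
    if literal_reciprocal:
        with np.errstate(divide="ignore"):
            return 1.0 / m
    return m


def apply_smoothing(store, policy: SmoothingPolicy | None = None) -> None:
    """Smooth every base feature of a cohort store with its policy kernel.

    Operates in place on ``store`` (a :class:`~fcdsurf.cohort.CohortFeatureStore`)
    and appends a provenance entry.  Unknown features in the policy raise.
    """
    from .mesh import gaussian_smooth  # local import to avoid cycle

    if policy is None:
        policy = SmoothingPolicy()
    unknown = set(policy.kernels) - set(BASE_FEATURES)
    if unknown:
        raise KeyError(f"smoothing policy names unknown features: {sorted(unknown)}")
    base = store.features["base"]
    for hi, hemi in enumerate(("left", "right")):
        mesh = store.template.hemi(hemi)
        for fi, name in enumerate(store.feature_names):
            if name not in policy.kernels:
                continue
            block = base[:, hi, :, fi].T  # vertices x subjects
            base[:, hi, :, fi] = gaussian_smooth(
                mesh, block, policy.kernel_for(name), policy.kernel_is_fwhm
            ).T
    store.log_stage("smoothed", kernels=dict(policy.kernels))
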