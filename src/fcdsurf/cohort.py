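"""Central cohort data model and HDF5 persistence.

A :class:`CohortFeatureStore` holds the template, the demographics table,
per-subject / per-hemisphere / per-vertex feature arrays for the 11 base
features and every derived feature set, per-patient lesion masks, and a
provenance log of the pipeline stages that have run.

Container layout (one HDF5 file)::

    /template/{left,right}/{vertices,triangles,cortex_mask}
    /features/<set_name>            (n_subjects, 2, n_vertices, 11)
    /lesions/<subject_id>           boolean mask, attrs: hemisphere
    /demographics                   one row per subject (pandas -> HDF5)
    attrs: provenance (JSON), feature_names, schema_version

Missing FLAIR features are stored as NaN and imputed to 0 (the control mean
in z-units) only when the classifier input is assembled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd

from .features import BASE_FEATURES, FLAIR_FEATURES
from .mesh import SurfaceMesh, SymmetricTemplate

__all__ = [
    "Subject",
    "CohortFeatureStore",
    "CohortSplit",
    "read_cohort",
    "write_cohort",
    "split_cohort",
    "assemble_classifier_input",
]

SCHEMA_VERSION = 1

HEMIS = ("left", "right")

#: feature sets concatenated into the 33-vector classifier input
CLASSIFIER_SETS = ("combat_z", "normalized", "asymmetry")


class SchemaError(ValueError):
    """Container does not match the expected cohort schema."""


@dataclass
class Subject:
    """Demographics and status flags for one participant."""

    subject_id: str
    group: str  # "patient" | "control"
    site_id: str
    scanner: str  # "1.5T" | "3T"
    age_at_scan: float
    sex: int  # 0 = female, 1 = male
    flair_available: bool
    operated: bool | None = None
    histology: str | None = None
    seizure_free: bool | None = None
    ever_mri_negative: bool | None = None
    lesion_hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"invalid group {self.group!r}")
        if self.age_at_scan < 3:
            raise ValueError("cohort includes participants over age 3 only")

    @property
    def is_patient(self) -> bool:
        return self.group == "patient"


class CohortFeatureStore:
    """Subjects x hemispheres x vertices x features, plus demographics."""

    def __init__(
        self,
        template: SymmetricTemplate,
        subjects: list[Subject],
        feature_names: tuple[str, ...] = BASE_FEATURES,
    ):
        self.template = template
        self.subjects = list(subjects)
        self.feature_names = tuple(feature_names)
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id")
        self._index = {sid: i for i, sid in enumerate(ids)}
        n = (len(subjects), 2, template.n_vertices, len(self.feature_names))
        self.features: dict[str, np.ndarray] = {"base": np.zeros(n)}
        self.lesion_masks: dict[str, tuple[str, np.ndarray]] = {}
        self.provenance: list[dict] = []

    # -- accessors ---------------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subject(self, subject_id: str) -> Subject:
        return self.subjects[self._index[subject_id]]

    def idx(self, subject_id: str) -> int:
        return self._index[subject_id]

    def get(self, set_name: str, subject_id: str, hemi: str) -> np.ndarray:
        """(n_vertices, n_features) block for one subject hemisphere."""
        return self.features[set_name][self._index[subject_id], HEMIS.index(hemi)]

    def patients(self) -> list[Subject]:
        return [s for s in self.subjects if s.is_patient]

    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if not s.is_patient]

    def set_lesion_mask(self, subject_id: str, hemi: str, mask: np.ndarray) -> None:
        if not self.subject(subject_id).is_patient:
            raise ValueError("controls never carry a lesion mask")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.template.n_vertices,):
            raise ValueError("mask length must equal template vertex count")
        self.lesion_masks[subject_id] = (hemi, mask)
        self.subject(subject_id).lesion_hemisphere = hemi

    def log_stage(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})

    def has_stage(self, stage: str) -> bool:
        return any(p["stage"] == stage for p in self.provenance)

    def demographics(self) -> pd.DataFrame:
        """One row per subject, columns as :class:`Subject` fields."""
        return pd.DataFrame([asdict(s) for s in self.subjects]).set_index(
            "subject_id"
        )


@dataclass
class CohortSplit:
    """Subject-level train/test split with train-fold assignment."""

    train_ids: list[str]
    test_ids: list[str]
    folds: dict[str, int] = field(default_factory=dict)  # subject_id -> 1..n_folds

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test cohorts must be disjoint")

    @property
    def n_folds(self) -> int:
        return max(self.folds.values(), default=0)

    def fold_members(self, fold: int) -> list[str]:
        return [sid for sid, f in self.folds.items() if f == fold]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def _write_mesh(grp: h5py.Group, mesh: SurfaceMesh) -> None:
    grp.create_dataset("vertices", data=mesh.vertices)
    grp.create_dataset("triangles", data=mesh.triangles)
    grp.create_dataset("cortex_mask", data=mesh.cortex_mask)


def _read_mesh(grp: h5py.Group) -> SurfaceMesh:
    return SurfaceMesh(
        grp["vertices"][()], grp["triangles"][()], grp["cortex_mask"][()]
    )


def write_cohort(store: CohortFeatureStore, path) -> None:
    """Serialize a cohort store losslessly to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["feature_names"] = json.dumps(list(store.feature_names))
        f.attrs["provenance"] = json.dumps(store.provenance)
        tgrp = f.create_group("template")
        _write_mesh(tgrp.create_group("left"), store.template.left)
        _write_mesh(tgrp.create_group("right"), store.template.right)
        fgrp = f.create_group("features")
        for name, arr in store.features.items():
            fgrp.create_dataset(name, data=arr)
        lgrp = f.create_group("lesions")
        for sid, (hemi, mask) in store.lesion_masks.items():
            d = lgrp.create_dataset(sid, data=mask)
            d.attrs["hemisphere"] = hemi
        rows = json.dumps([asdict(s) for s in store.subjects])
        f.create_dataset("demographics", data=rows.encode())


def read_cohort(path) -> CohortFeatureStore:
    """Read a cohort container written by :func:`write_cohort`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version mismatch: container {version}, expected {SCHEMA_VERSION}"
            )
        if "demographics" not in f:
            raise SchemaError("container missing demographics table")
        template = SymmetricTemplate(
            _read_mesh(f["template/left"]), _read_mesh(f["template/right"])
        )
        subjects = [
            Subject(**row) for row in json.loads(f["demographics"][()].decode())
        ]
        names = tuple(json.loads(f.attrs["feature_names"]))
        store = CohortFeatureStore(template, subjects, names)
        for name in f["features"]:
            arr = f["features"][name][()]
            if arr.shape[2] != template.n_vertices:
                raise SchemaError("feature vertex count mismatch with template")
            store.features[name] = arr
        for sid in f["lesions"]:
            d = f["lesions"][sid]
            store.set_lesion_mask(sid, d.attrs["hemisphere"], d[()])
        store.provenance = json.loads(f.attrs["provenance"])
    return store


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------


def split_cohort(
    store: CohortFeatureStore,
    train_fraction: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
) -> CohortSplit:
    """Random subject-level train/test split plus train-fold partition.

    Stratified by (site, group) so the patient/control ratio is preserved;
    folds are a near-equal (sizes differ by at most 1) random partition of
    the train cohort.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    strata: dict[tuple[str, str], list[str]] = {}
    for s in store.subjects:
        strata.setdefault((s.site_id, s.group), []).append(s.subject_id)
    for key in sorted(strata):
        ids = np.array(strata[key])
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    train_patients = [
        sid for sid in train_ids if store.subject(sid).is_patient
    ]
    if len(train_patients) < n_folds:
        raise ValueError(
            f"need at least {n_folds} train patients, have {len(train_patients)}"
        )
    shuffled = np.array(sorted(train_ids))
    rng.shuffle(shuffled)
    folds = {sid: (i % n_folds) + 1 for i, sid in enumerate(shuffled)}
    return CohortSplit(sorted(train_ids), sorted(test_ids), folds)


# ---------------------------------------------------------------------------
# classifier input assembly
# ---------------------------------------------------------------------------


def assemble_classifier_input(
    store: CohortFeatureStore, subject_id: str, hemi: str
) -> np.ndarray:
    """The ordered 33-feature classifier input for one subject hemisphere.

    Concatenation is ``[11 combat | 11 normalized | 11 asymmetry]`` with each
    block in :data:`~fcdsurf.features.BASE_FEATURES` order.  The combat block
    enters scaled per vertex by the control reference ("combat_z") so that
    every input is in z-units and 0 is the control mean; FLAIR-derived
    entries of subjects without FLAIR are imputed with that same 0.
    """
    missing = [s for s in CLASSIFIER_SETS if s not in store.features]
    if missing:
        raise ValueError(
            f"classifier input requested before stages ran: missing {missing}"
        )
    blocks = [store.get(s, subject_id, hemi) for s in CLASSIFIER_SETS]
    x = np.concatenate(blocks, axis=1)
    if not store.subject(subject_id).flair_available:
        flair_cols = [
            b * len(store.feature_names) + store.feature_names.index(f)
            for b in range(len(CLASSIFIER_SETS))
            for f in FLAIR_FEATURES
        ]
        x[:, flair_cols] = 0.0
    return np.nan_to_num(x, nan=0.0)
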