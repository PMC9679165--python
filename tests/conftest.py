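"""Shared fixtures: small synthetic templates and cohorts.

Everything is generated at test time; session scope keeps the heavier
cohorts shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import fcdsurf as fs
from fcdsurf.synthetic import SiteConfig, SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def template2():
    return fs.make_template(2)  # 162 vertices / hemisphere


@pytest.fixture(scope="session")
def template3():
    return fs.make_template(3)  # 642 vertices / hemisphere


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        sites=[
            SiteConfig("siteA", 12, 8, "3T", 0.8),
            SiteConfig("siteB", 12, 8, "1.5T", 0.6),
            SiteConfig("siteC", 12, 8, "3T", 0.7),
        ],
        subdivision_level=3,
        lesion_radius_range=(25.0, 40.0),
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """60-subject cohort on the level-3 template, with planted lesions."""
    store, truth = simulate_cohort(small_config)
    return store, truth


@pytest.fixture(scope="session")
def prepared_cohort(small_config):
    """Same cohort, harmonized and normalized, with a split."""
    store, truth = simulate_cohort(small_config)
    split = fs.split_cohort(store, 0.5, n_folds=2, seed=1)
    fs.prepare_features(store, split)
    return store, truth, split


@pytest.fixture(scope="session")
def trained_setup(prepared_cohort):
    """A reduced trained ensemble (2 folds x 2 inits) on the small cohort."""
    store, truth, split = prepared_cohort
    config = fs.TrainingConfig(
        n_lesional=500,
        n_nonlesional=500,
        epochs=15,
        n_folds=2,
        n_inits=2,
        seed=3,
    )
    model, split, annotations = fs.train_detector(store, config, split=split)
    return store, truth, split, model, annotations


def random_blob(mesh, seed, n_target):
    """The n_target cortex vertices nearest a random cortex seed."""
    rng = np.random.default_rng(seed)
    cortex = np.flatnonzero(mesh.cortex_mask)
    v0 = int(rng.choice(cortex))
    d = fs.geodesic_distance(mesh, [v0])
    order = np.argsort(np.where(np.isfinite(d), d, np.inf))
    flag = np.zeros(mesh.n_vertices, dtype=bool)
    flag[order[:n_target]] = True
    return flag & mesh.cortex_mask
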