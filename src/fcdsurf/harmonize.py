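"""Multi-site harmonization with parametric empirical-Bayes ComBat.

Removes additive (location) and multiplicative (scale) site effects from
every (feature, vertex) measurement while preserving the modelled biological
covariates — age, sex and disease status.  The model per measurement g is

    y_isg = alpha_g + X_i beta_g + gamma_sg + delta_sg * eps_isg

with site location gamma_sg and scale delta_sg shrunk across measurements by
empirical Bayes (normal prior for gamma, inverse-gamma for delta), and the
adjusted data

    y*_isg = sigma_g * (z_isg - gamma*_sg) / delta*_sg + alpha_g + X_i beta_g .

Because FLAIR availability varies by subject, the model is fit as two
complete sub-problems: T1-derived features on all subjects and FLAIR
features on the FLAIR subcohort.

A fitted model can harmonize a previously unseen site to the reference
cohort: intercept, covariate coefficients and pooled scale stay frozen and
only the new site's location/scale are estimated (and removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .cohort import CohortFeatureStore, Subject
from .features import FLAIR_FEATURES, T1_FEATURES

__all__ = ["ComBatModel", "SiteParams", "fit_combat", "harmonize_new_site"]

_MIN_VAR = 1e-12


@dataclass
class SiteParams:
    """EB-shrunk location/scale and the priors they were shrunk toward."""

    gamma_star: np.ndarray  # (G,)
    delta_star: np.ndarray  # (G,), > 0
    gamma_bar: float
    tau_sq: float
    a_prior: float
    b_prior: float
    n_subjects: int


@dataclass
class SubModel:
    """ComBat fit for one complete block of features."""

    feature_names: tuple[str, ...]
    beta: np.ndarray  # (n_covariates, G) covariate coefficients
    alpha: np.ndarray  # (G,) grand intercept
    var_pooled: np.ndarray  # (G,)
    valid: np.ndarray  # (G,) bool; zero-variance columns are skipped
    sites: dict[str, SiteParams] = field(default_factory=dict)


@dataclass
class ComBatModel:
    """Fitted harmonization model (covariates: age, sex, group)."""

    batch_key: str
    covariates: tuple[str, ...]
    eb: bool
    submodels: dict[str, SubModel] = field(default_factory=dict)

    @property
    def site_roster(self) -> set[str]:
        roster: set[str] = set()
        for sm in self.submodels.values():
            roster |= set(sm.sites)
        return roster

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["batch_key"] = self.batch_key
            f.attrs["covariates"] = list(self.covariates)
            f.attrs["eb"] = self.eb
            for name, sm in self.submodels.items():
                g = f.create_group(name)
                g.attrs["feature_names"] = list(sm.feature_names)
                for k in ("beta", "alpha", "var_pooled", "valid"):
                    g.create_dataset(k, data=getattr(sm, k))
                for sid, sp in sm.sites.items():
                    sg = g.create_group(f"site_{sid}")
                    sg.create_dataset("gamma_star", data=sp.gamma_star)
                    sg.create_dataset("delta_star", data=sp.delta_star)
                    for k in ("gamma_bar", "tau_sq", "a_prior", "b_prior", "n_subjects"):
                        sg.attrs[k] = getattr(sp, k)

    @classmethod
    def load(cls, path) -> "ComBatModel":
        with h5py.File(path, "r") as f:
            model = cls(
                batch_key=f.attrs["batch_key"],
                covariates=tuple(f.attrs["covariates"]),
                eb=bool(f.attrs["eb"]),
            )
            for name in f:
                g = f[name]
                sm = SubModel(
                    feature_names=tuple(g.attrs["feature_names"]),
                    beta=g["beta"][()],
                    alpha=g["alpha"][()],
                    var_pooled=g["var_pooled"][()],
                    valid=g["valid"][()].astype(bool),
                )
                for key in g:
                    if key.startswith("site_"):
                        sg = g[key]
                        sm.sites[key[5:]] = SiteParams(
                            gamma_star=sg["gamma_star"][()],
                            delta_star=sg["delta_star"][()],
                            gamma_bar=float(sg.attrs["gamma_bar"]),
                            tau_sq=float(sg.attrs["tau_sq"]),
                            a_prior=float(sg.attrs["a_prior"]),
                            b_prior=float(sg.attrs["b_prior"]),
                            n_subjects=int(sg.attrs["n_subjects"]),
                        )
                model.submodels[name] = sm
        return model


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _covariate_matrix(subjects: list[Subject], covariates: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in covariates:
        if name == "age":
            cols.append([s.age_at_scan for s in subjects])
        elif name == "sex":
            cols.append([float(s.sex) for s in subjects])
        elif name == "group":
            cols.append([float(s.is_patient) for s in subjects])
        else:
            raise KeyError(f"unknown covariate {name!r}")
    arr = np.asarray(cols, dtype=float).T if cols else np.empty((len(subjects), 0))
    # constant columns (e.g. "group" in a controls-only cohort) carry no
    # information beyond the intercept and are dropped
    keep = np.ptp(arr, axis=0) > 0 if arr.size else np.ones(0, dtype=bool)
    arr = arr[:, keep]
    if arr.shape[1] >= 2:
        rank = np.linalg.matrix_rank(np.c_[np.ones(len(subjects)), arr])
        if rank < arr.shape[1] + 1:
            raise ValueError("collinear covariates")
    return arr


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(d: np.ndarray) -> float:
    # inverse-gamma prior moment-matched to the observed per-site variances
    m, s2 = d.mean(), d.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else d.mean()


def _it_sol(z, gamma_hat, delta_hat, g_bar, t2, a, b, conv=1e-4, max_iter=200):
    """Iterative EB solution for one site (neuroCombat-style)."""
    n = z.shape[0]
    gamma_old, delta_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * t2 * gamma_hat + delta_old * g_bar) / (n * t2 + delta_old)
        ssq = ((z - gamma_new[None, :]) ** 2).sum(axis=0)
        delta_new = (0.5 * ssq + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(gamma_new - gamma_old).max(initial=0),
            np.abs(delta_new - delta_old).max(initial=0),
        )
        gamma_old, delta_old = gamma_new, delta_new
        if change < conv:
            break
    return gamma_old, delta_old


def _fit_block(
    Y: np.ndarray,
    sites: np.ndarray,
    X: np.ndarray,
    eb: bool,
    feature_names: tuple[str, ...],
) -> tuple[SubModel, np.ndarray]:
    """Fit ComBat on a complete (n, G) block; returns the model and Y*."""
    n, G = Y.shape
    site_ids = sorted(set(sites))
    counts = {s: int((sites == s).sum()) for s in site_ids}
    for s, c in counts.items():
        if c < 2:
            raise ValueError(f"site {s!r} has fewer than 2 subjects")
    B = np.stack([(sites == s).astype(float) for s in site_ids], axis=1)
    D = np.concatenate([B, X], axis=1)
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    gamma_hat_all = coef[: len(site_ids)]  # (K, G) per-site means
    beta = coef[len(site_ids) :]
    w = np.array([counts[s] / n for s in site_ids])
    alpha = w @ gamma_hat_all
    fitted = D @ coef
    var_pooled = ((Y - fitted) ** 2).mean(axis=0)
    valid = var_pooled > _MIN_VAR
    sigma = np.sqrt(np.where(valid, var_pooled, 1.0))

    stand_mean = alpha[None, :] + X @ beta
    Z = (Y - stand_mean) / sigma[None, :]

    sm = SubModel(feature_names, beta, alpha, var_pooled, valid)
    out = Y.copy()
    for s in site_ids:
        rows = sites == s
        zs = Z[rows][:, valid]
        g_hat = zs.mean(axis=0)
        # ddof=0 so a cohort with no batch effect is an exact fixed point
        d_hat = zs.var(axis=0)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var())
        a, b = _aprior(d_hat), _bprior(d_hat)
        if eb and t2 > 0:
            g_star, d_star = _it_sol(zs, g_hat, d_hat, g_bar, t2, a, b)
        else:
            g_star, d_star = g_hat, d_hat
        d_star = np.maximum(d_star, _MIN_VAR)
        gamma_full = np.zeros(G)
        delta_full = np.ones(G)
        gamma_full[valid] = g_star
        delta_full[valid] = d_star
        sm.sites[s] = SiteParams(
            gamma_full, delta_full, g_bar, t2, a, b, counts[s]
        )
        adj = sigma[valid] * (zs - g_star[None]) / np.sqrt(d_star)[None]
        block = out[rows]
        block[:, valid] = adj + stand_mean[rows][:, valid]
        out[rows] = block
    return sm, out


_BLOCKS = {"t1": T1_FEATURES, "flair": FLAIR_FEATURES}


def _block_view(store: CohortFeatureStore, feature_set: str, names, rows):
    idx = [store.feature_names.index(f) for f in names]
    arr = store.features[feature_set][rows][:, :, :, idx]
    n = arr.shape[0]
    return arr.reshape(n, -1), arr.shape


def fit_combat(
    store: CohortFeatureStore,
    batch_key: str = "site_id",
    covariates: tuple[str, ...] = ("age", "sex", "group"),
    eb: bool = True,
    source: str = "base",
    dest: str = "combat",
) -> ComBatModel:
    """Fit ComBat on a cohort store and write the harmonized feature set.

    The batch variable defaults to the site label; ``batch_key`` may name
    any ``Subject`` attribute (for example ``scanner``).  With ``eb=False``
    the raw per-site location/scale estimates are used (direct
    standardization, no shrinkage) — useful as an oracle.
    """
    model = ComBatModel(batch_key, covariates, eb)
    out = store.features[source].copy()
    for block_name, names in _BLOCKS.items():
        if block_name == "flair":
            rows = [i for i, s in enumerate(store.subjects) if s.flair_available]
        else:
            rows = list(range(len(store.subjects)))
        if len(rows) == 0:
            continue
        subjects = [store.subjects[i] for i in rows]
        sites = np.array([getattr(s, batch_key) for s in subjects])
        X = _covariate_matrix(subjects, covariates)
        Y, shape = _block_view(store, source, names, rows)
        sm, Ystar = _fit_block(Y, sites, X, eb, names)
        model.submodels[block_name] = sm
        idx = [store.feature_names.index(f) for f in names]
        out[np.ix_(rows, range(2), range(store.template.n_vertices), idx)] = (
            Ystar.reshape(shape)
        )
    store.features[dest] = out
    store.log_stage("combat", batch_key=batch_key, eb=eb)
    return model


def harmonize_new_site(
    model: ComBatModel,
    new_store: CohortFeatureStore,
    source: str = "base",
    dest: str = "combat",
) -> None:
    """Harmonize an unseen site to the reference cohort of a fitted model.

    Reference intercept, covariate coefficients and pooled scale are frozen;
    only the new sites' location/scale parameters are estimated (with EB
    shrinkage toward priors computed from the new site's own estimates) and
    removed.  Refuses sites already on the model's roster or with fewer
    than 2 subjects.
    """
    new_sites = {getattr(s, model.batch_key) for s in new_store.subjects}
    overlap = new_sites & model.site_roster
    if overlap:
        raise ValueError(f"sites already in reference roster: {sorted(overlap)}")
    out = new_store.features[source].copy()
    for block_name, names in _BLOCKS.items():
        if block_name not in model.submodels:
            continue
        sm = model.submodels[block_name]
        if block_name == "flair":
            rows = [i for i, s in enumerate(new_store.subjects) if s.flair_available]
        else:
            rows = list(range(len(new_store.subjects)))
        if not rows:
            continue
        subjects = [new_store.subjects[i] for i in rows]
        sites = np.array([getattr(s, model.batch_key) for s in subjects])
        X = _covariate_matrix(subjects, model.covariates)
        Y, shape = _block_view(new_store, source, names, rows)
        valid = sm.valid
        sigma = np.sqrt(np.where(valid, sm.var_pooled, 1.0))
        stand_mean = sm.alpha[None, :] + X @ sm.beta
        Z = (Y - stand_mean) / sigma[None, :]
        Ystar = Y.copy()
        for s in sorted(set(sites)):
            rws = sites == s
            if rws.sum() < 2:
                raise ValueError(f"new site {s!r} has fewer than 2 subjects")
            zs = Z[rws][:, valid]
            g_hat = zs.mean(axis=0)
            d_hat = zs.var(axis=0)
            g_bar, t2 = float(g_hat.mean()), float(g_hat.var())
            a, b = _aprior(d_hat), _bprior(d_hat)
            if model.eb and t2 > 0:
                g_star, d_star = _it_sol(zs, g_hat, d_hat, g_bar, t2, a, b)
            else:
                g_star, d_star = g_hat, d_hat
            d_star = np.maximum(d_star, _MIN_VAR)
            adj = sigma[valid] * (zs - g_star[None]) / np.sqrt(d_star)[None]
            block = Ystar[rws]
            block[:, valid] = adj + stand_mean[rws][:, valid]
            Ystar[rws] = block
        idx = [new_store.feature_names.index(f) for f in names]
        out[
            np.ix_(rows, range(2), range(new_store.template.n_vertices), idx)
        ] = Ystar.reshape(shape)
    new_store.features[dest] = out
    new_store.log_stage("combat_new_site", batch_key=model.batch_key)
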