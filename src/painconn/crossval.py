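"""Cross-validated multivariate prediction of pain intensity.

Leakage discipline: within every fold, ComBat harmonisation, within-site
z-scoring of the outcome, age regression, and feature standardisation are
estimated on the training rows only and applied to the held-out rows.  In
leave-one-site-out (LOSO) CV the held-out site is unseen by the
harmonisation model, so each test participant receives one prediction per
training-site assumption and the predictions are averaged
(``site_averaged_predict``); test-set normalisation and confounder removal
are performed independently on the test site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayescorr import BFResult, correlation_bf
from .enet import DEFAULT_GRID, HyperParamGrid, _standardise, fit_elastic_net, nested_cv_select
from .harmonise import combat_apply, combat_fit, residualise_age, zscore_within_site

__all__ = [
    "CVResult", "WeightStability", "loo_cv", "loso_cv",
    "site_averaged_predict", "bootstrap_weights", "bf_ratio", "ablate_features",
]


@dataclass
class CVResult:
    predictions: np.ndarray
    observations: np.ndarray
    fold_scheme: str  # LOO | LOSO
    participant_ids: list[str]
    sites: list[str]
    folds: np.ndarray
    r_pred_obs: float
    bf: BFResult
    selected: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant_id": self.participant_ids, "site": self.sites,
             "fold": self.folds, "y_obs": self.observations,
             "y_pred": self.predictions}
        )


@dataclass
class WeightStability:
    feature_names: list[str]
    median_weight: np.ndarray
    sign_flip_p: np.ndarray
    n_bootstrap: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "median_weight": self.median_weight,
             "p_sign_flip": self.sign_flip_p}
        ).set_index("feature")


class _FoldTransform:
    """Training-fold transformations (harmonise, z-score outcome,
    residualise age, standardise features) applied without leakage."""

    def __init__(self, features, meta, train_mask, outcome, harmonise=True):
        self.outcome = outcome
        self.age_is_outcome = outcome == "age"
        X = features.to_numpy(dtype=float)
        site = meta["site"].to_numpy(dtype=str)
        age = meta["age"].to_numpy(dtype=float)
        y = meta[outcome].to_numpy(dtype=float)
        tr = train_mask

        self.combat = None
        X_adj = X.copy()
        train_sites, counts = np.unique(site[tr], return_counts=True)
        if harmonise and len(train_sites) >= 2 and counts.min() >= 2:
            cov = None if self.age_is_outcome else meta[["age"]]
            self.combat = combat_fit(
                features.iloc[tr], site[tr],
                None if cov is None else cov.iloc[tr],
            )
            seen = np.isin(site, self.combat.sites)
            adj = combat_apply(
                self.combat, features.iloc[seen], site[seen],
                None if cov is None else cov.iloc[seen],
            )
            X_adj[seen] = adj.to_numpy()

        self.y_z, self.site_stats = zscore_within_site(y[tr], site[tr])
        y_all = np.full(len(y), np.nan)
        y_all[tr] = self.y_z
        seen_mask = np.isin(site, list(self.site_stats))
        y_seen, _ = zscore_within_site(
            y[seen_mask], site[seen_mask], fit_site_stats=self.site_stats
        )
        y_all[seen_mask] = y_seen

        if not self.age_is_outcome:
            X_adj = residualise_age(X_adj, age, fit_on=tr)
            y_all = residualise_age(y_all, age, fit_on=tr)
        Xs, _, self.mu, self.sd = _standardise(X_adj[tr])
        self.X_train, self.y_train = Xs, y_all[tr]
        self.X_all = (X_adj - self.mu) / self.sd
        self.y_all = y_all


def _final_fit(transform, grid, inner_k, seed, site_train):
    alpha, lam = nested_cv_select(
        transform.X_train, transform.y_train, grid=grid, inner_k=inner_k,
        seed=seed, site=site_train,
    )
    w, b0 = fit_elastic_net(transform.X_train, transform.y_train, alpha, lam)
    return (alpha, lam), w, b0


def loo_cv(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    outcome: str = "pain_intensity",
    grid: HyperParamGrid = DEFAULT_GRID,
    inner_k: int = 10,
    seed: int = 0,
    harmonise: bool = True,
) -> CVResult:
    """Leave-one-participant-out CV with per-fold nested hyperparameter
    selection; one prediction per participant; one-sided positive BF on the
    prediction-observation correlation."""
    n = len(features)
    if n < 20:
        raise ValueError("need at least 20 participants for LOO-CV")
    site = meta["site"].to_numpy(dtype=str)
    preds = np.empty(n)
    obs = np.empty(n)
    selected = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        t = _FoldTransform(features, meta, tr, outcome, harmonise)
        (alpha, lam), w, b0 = _final_fit(t, grid, inner_k, seed, site[tr])
        selected.append((alpha, lam))
        preds[i] = t.X_all[i] @ w + b0
        obs[i] = t.y_all[i]
    r = float(np.corrcoef(preds, obs)[0, 1])
    bf = correlation_bf(preds, obs, side="positive")
    return CVResult(
        predictions=preds, observations=obs, fold_scheme="LOO",
        participant_ids=list(features.index), sites=list(site),
        folds=np.arange(n), r_pred_obs=r, bf=bf, selected=selected,
    )


def site_averaged_predict(
    weights: np.ndarray,
    intercept: float,
    combat_model,
    feature_standardiser: tuple[np.ndarray, np.ndarray],
    test_features: pd.DataFrame,
    test_covariates: pd.DataFrame | None,
) -> np.ndarray:
    """Predictions for participants from a site unseen by harmonisation.

    One prediction per training-site assumption (the test rows are
    harmonised as if they originated from that site), arithmetic mean
    returned.  With no harmonisation model the plain prediction is used.
    """
    mu, sd = feature_standardiser
    if combat_model is None:
        Xs = (test_features.to_numpy(dtype=float) - mu) / sd
        return Xs @ weights + intercept
    preds = []
    for s in combat_model.sites:
        adj = combat_apply(combat_model, test_features, s, test_covariates)
        Xs = (adj.to_numpy() - mu) / sd
        preds.append(Xs @ weights + intercept)
    return np.mean(preds, axis=0)


def loso_cv(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    outcome: str = "pain_intensity",
    grid: HyperParamGrid = DEFAULT_GRID,
    inner_k: int = 10,
    seed: int = 0,
    harmonise: bool = True,
) -> CVResult:
    """Leave-one-site-out CV: per fold all participants of one site are
    held out; test-set normalisation/confounder removal are estimated on
    the test site itself, and features are adjusted via the site-averaged
    unseen-site procedure."""
    site = meta["site"].to_numpy(dtype=str)
    sites = sorted(set(site))
    if len(sites) < 3:
        raise ValueError("need at least 3 sites for LOSO-CV")
    n = len(features)
    preds = np.empty(n)
    obs = np.empty(n)
    folds = np.empty(n, dtype=int)
    selected = []
    for fi, held in enumerate(sites):
        te = site == held
        tr = ~te
        t = _FoldTransform(features, meta, tr, outcome, harmonise)
        (alpha, lam), w, b0 = _final_fit(t, grid, inner_k, seed, site[tr])
        selected.append((alpha, lam))
        # independent test-set normalisation
        y_te = meta[outcome].to_numpy(dtype=float)[te]
        y_te = (y_te - y_te.mean()) / (y_te.std() if y_te.std() > 0 else 1.0)
        X_te = features.iloc[te]
        age_te = meta["age"].to_numpy(dtype=float)[te]
        cov_te = None
        if t.combat is not None and t.combat.covariate_names:
            cov_te = meta[["age"]].iloc[te]
        if outcome != "age" and np.ptp(age_te) > 0:
            y_te = residualise_age(y_te, age_te)
            X_te = pd.DataFrame(
                residualise_age(X_te.to_numpy(dtype=float), age_te),
                index=X_te.index, columns=X_te.columns,
            )
        preds[te] = site_averaged_predict(
            w, b0, t.combat, (t.mu, t.sd), X_te, cov_te
        )
        obs[te] = y_te
        folds[te] = fi
    r = float(np.corrcoef(preds, obs)[0, 1])
    bf = correlation_bf(preds, obs, side="positive")
    return CVResult(
        predictions=preds, observations=obs, fold_scheme="LOSO",
        participant_ids=list(features.index), sites=list(site),
        folds=folds, r_pred_obs=r, bf=bf, selected=selected,
    )


def bootstrap_weights(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    outcome: str = "pain_intensity",
    n_bootstrap: int = 1000,
    grid: HyperParamGrid = DEFAULT_GRID,
    inner_k: int = 5,
    seed: int = 0,
    harmonise: bool = True,
) -> WeightStability:
    """Bootstrap stability of model weights.

    Participants are resampled with replacement; the full transformation +
    nested-selection + fit stack is re-run per sample.  Reported per
    feature: the median weight across samples and the empirical sign-flip
    p-value (fraction of samples whose weight sign differs from the sign of
    the median)."""
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(features)
    site = meta["site"].to_numpy(dtype=str)
    W = np.empty((n_bootstrap, features.shape[1]))
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, n)
            if np.std(meta[outcome].to_numpy(dtype=float)[idx]) > 0:
                break
        fb = features.iloc[idx]
        mb = meta.iloc[idx]
        t = _FoldTransform(fb, mb, np.ones(n, dtype=bool), outcome, harmonise)
        _, w, _ = _final_fit(t, grid, inner_k, seed + b, site[idx])
        W[b] = w
    med = np.median(W, axis=0)
    sign = np.where(med >= 0, 1.0, -1.0)
    p = (np.sign(W) != sign[None, :]).mean(axis=0)
    return WeightStability(
        feature_names=list(features.columns), median_weight=med,
        sign_flip_p=p, n_bootstrap=n_bootstrap,
    )


def bf_ratio(bf_reference: float, bf_alternative: float) -> float:
    """BF of the reference model divided by BF of the alternative model."""
    if bf_reference <= 0 or bf_alternative <= 0:
        raise ValueError("Bayes factors must be positive")
    return bf_reference / bf_alternative


def ablate_features(
    table: pd.DataFrame,
    drop_band: str | None = None,
    univariate: str | None = None,
) -> pd.DataFrame:
    """Reduced feature tables for the explanatory model comparisons.

    ``drop_band`` removes every column of one band (prefix match on
    ``band_``); ``univariate`` keeps a single named column (run through the
    identical CV machinery)."""
    if univariate is not None:
        if univariate not in table.columns:
            raise KeyError(f"feature {univariate!r} not in table")
        return table[[univariate]]
    if drop_band is not None:
        keep = [c for c in table.columns if not c.startswith(f"{drop_band}_")]
        if not keep or len(keep) == len(table.columns):
            raise ValueError(f"band {drop_band!r} not present or nothing left")
        return table[keep]
    raise ValueError("specify drop_band or univariate")
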