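"""Multi-site feature harmonisation and nuisance handling.

``combat_fit`` / ``combat_apply`` implement the parametric empirical-Bayes
location-scale batch correction (ComBat): per feature and site, additive
(gamma) and multiplicative (delta) site effects are estimated on
standardised residuals and shrunk toward common priors (normal on gamma,
inverse-gamma on delta) by the classic iterative EB solver.  Biological
covariates (age) are protected: their effects are estimated jointly in the
standardisation design and reinstated after correction.

``zscore_within_site`` and ``residualise_age`` handle dependent variables
and the age confound; both support fitting on a training subset only so
cross-validation never leaks test-set information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HarmonisationModel",
    "UnseenSiteError",
    "combat_fit",
    "combat_apply",
    "zscore_within_site",
    "residualise_age",
]


class UnseenSiteError(KeyError):
    """Site was not present when the harmonisation model was fitted; use the
    site-averaged prediction procedure for unseen-site data."""


@dataclass
class HarmonisationModel:
    sites: list[str]
    feature_names: list[str]
    grand_mean: np.ndarray  # per feature
    beta_cov: np.ndarray  # covariates x features
    var_pooled: np.ndarray  # per feature
    gamma_star: dict[str, np.ndarray] = field(default_factory=dict)
    delta_star: dict[str, np.ndarray] = field(default_factory=dict)
    covariate_names: list[str] = field(default_factory=list)
    covariate_center: np.ndarray | None = None


def _design(site: np.ndarray, sites: list[str], cov: np.ndarray | None) -> np.ndarray:
    B = np.column_stack([(site == s).astype(float) for s in sites])
    return B if cov is None else np.column_stack([B, cov])


def _aprior(g: np.ndarray) -> float:
    m, s2 = g.mean(), g.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(g: np.ndarray) -> float:
    m, s2 = g.mean(), g.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(gh, gbar, n, dstar, t2):
    return (t2 * n * gh + dstar * gbar) / (t2 * n + dstar)


def _postvar(s2sum, n, a, b):
    return (0.5 * s2sum + b) / (n / 2.0 + a - 1.0)


def _it_solve(sdat, ghat, dhat, gbar, t2, a, b, conv=1e-4, max_iter=500):
    n = (~np.isnan(sdat)).sum(axis=0).astype(float)
    g_old, d_old = ghat.copy(), dhat.copy()
    for _ in range(max_iter):
        gnew = _postmean(ghat, gbar, n, d_old, t2)
        ssum = np.nansum((sdat - gnew[None, :]) ** 2, axis=0)
        dnew = _postvar(ssum, n, a, b)
        change = max(
            np.max(np.abs(gnew - g_old) / np.abs(g_old + 1e-30)),
            np.max(np.abs(dnew - d_old) / np.abs(d_old + 1e-30)),
        )
        g_old, d_old = gnew, dnew
        if change < conv:
            break
    return g_old, d_old


def combat_fit(
    features: pd.DataFrame,
    site: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> HarmonisationModel:
    """Fit the parametric EB location-scale harmonisation model."""
    X = features.to_numpy(dtype=float)
    site = np.asarray(site).astype(str)
    sites = sorted(set(site))
    if len(sites) < 2:
        raise ValueError("need at least two sites to harmonise")
    counts = {s: int((site == s).sum()) for s in sites}
    bad = [s for s, c in counts.items() if c < 2]
    if bad:
        raise ValueError(f"sites with a single participant cannot be harmonised: {bad}")

    cov_names: list[str] = []
    cov_mat = None
    cov_center = None
    if covariates is not None and covariates.shape[1] > 0:
        cov_names = list(covariates.columns)
        cov_mat = covariates.to_numpy(dtype=float)
        cov_center = cov_mat.mean(axis=0)
        cov_mat = cov_mat - cov_center

    n, p = X.shape
    D = _design(site, sites, cov_mat)
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    site_prop = np.array([counts[s] / n for s in sites])
    grand = site_prop @ beta[: len(sites)]
    beta_cov = beta[len(sites):] if cov_mat is not None else np.zeros((0, p))

    fitted = D @ beta
    var_pooled = ((X - fitted) ** 2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand = grand[None, :] + (cov_mat @ beta_cov if cov_mat is not None else 0.0)
    sdat = (X - stand) / np.sqrt(var_pooled)[None, :]

    model = HarmonisationModel(
        sites=sites, feature_names=list(features.columns), grand_mean=grand,
        beta_cov=beta_cov, var_pooled=var_pooled,
        covariate_names=cov_names, covariate_center=cov_center,
    )
    gamma_hat = np.vstack([sdat[site == s].mean(axis=0) for s in sites])
    delta_hat = np.vstack([sdat[site == s].var(axis=0, ddof=1) for s in sites])
    if p < 2:
        # the EB priors are estimated across features; with one feature
        # fall back to the unshrunk location-scale estimates
        for i, s in enumerate(sites):
            model.gamma_star[s] = gamma_hat[i]
            model.delta_star[s] = np.maximum(delta_hat[i], 1e-12)
        return model
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    for i, s in enumerate(sites):
        a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
        g_star, d_star = _it_solve(
            sdat[site == s], gamma_hat[i], delta_hat[i], gamma_bar[i], t2[i], a, b
        )
        model.gamma_star[s] = g_star
        model.delta_star[s] = d_star
    return model


def combat_apply(
    model: HarmonisationModel,
    features: pd.DataFrame,
    site: pd.Series | np.ndarray | str,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply a fitted harmonisation model (no refitting).

    ``site`` may be a per-row array or a single site label applied to all
    rows (used by the unseen-site averaging procedure, which re-adjusts the
    same data under each training-site assumption).
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if isinstance(site, str):
        site_arr = np.full(n, site)
    else:
        site_arr = np.asarray(site).astype(str)
    unseen = sorted(set(site_arr) - set(model.sites))
    if unseen:
        raise UnseenSiteError(
            f"sites {unseen} were not in the harmonisation training set; "
            "use site-averaged prediction for unseen sites"
        )
    if model.covariate_names:
        if covariates is None:
            raise ValueError(f"covariates {model.covariate_names} required")
        cov = covariates[model.covariate_names].to_numpy(dtype=float) - model.covariate_center
        cov_part = cov @ model.beta_cov
    else:
        cov_part = 0.0
    stand = model.grand_mean[None, :] + cov_part
    sdat = (X - stand) / np.sqrt(model.var_pooled)[None, :]
    adj = np.empty_like(sdat)
    for s in set(site_arr):
        rows = site_arr == s
        adj[rows] = (sdat[rows] - model.gamma_star[s][None, :]) / np.sqrt(
            model.delta_star[s]
        )[None, :]
    out = adj * np.sqrt(model.var_pooled)[None, :] + stand
    return pd.DataFrame(out, columns=features.columns, index=features.index)


def zscore_within_site(
    values: pd.Series | np.ndarray,
    site: pd.Series | np.ndarray,
    fit_site_stats: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Per-site z-scores.  Returns (z, per-site (mean, sd)); pass
    ``fit_site_stats`` from a training set to transform held-out rows
    without leakage."""
    v = np.asarray(values, dtype=float)
    site = np.asarray(site).astype(str)
    out = np.empty_like(v)
    stats = {} if fit_site_stats is None else dict(fit_site_stats)
    for s in sorted(set(site)):
        rows = site == s
        if s not in stats:
            m, sd = float(v[rows].mean()), float(v[rows].std(ddof=0))
            if sd == 0:
                raise ValueError(f"constant values within site {s!r}")
            stats[s] = (m, sd)
        m, sd = stats[s]
        out[rows] = (v[rows] - m) / sd
    return out, stats


def residualise_age(
    x: np.ndarray | pd.Series | pd.DataFrame,
    age: np.ndarray | pd.Series,
    fit_on: np.ndarray | None = None,
) -> np.ndarray:
    """Remove a linear age effect, estimated on ``fit_on`` rows only
    (all rows by default), from every row."""
    X = np.asarray(x, dtype=float)
    one_d = X.ndim == 1
    X = X.reshape(len(X), -1)
    a = np.asarray(age, dtype=float)
    mask = np.ones(len(a), dtype=bool) if fit_on is None else np.asarray(fit_on, bool)
    if mask.sum() == 0:
        raise ValueError("empty fit subset")
    a_fit = a[mask]
    if np.ptp(a_fit) == 0:
        raise ValueError("age is constant in the fit subset")
    ac = a - a_fit.mean()
    ac_fit = ac[mask]
    denom = float(ac_fit @ ac_fit)
    slope = (ac_fit @ (X[mask] - X[mask].mean(axis=0))) / denom
    intercept = X[mask].mean(axis=0)
    resid = X - intercept[None, :] - np.outer(ac, slope)
    return resid.ravel() if one_d else resid
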