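"""Univariate Bayesian statistics: discovery, replication, mega-analysis.

The discovery set is tested bidirectionally (or with prespecified sides for
the standard features); the pooled replication sets are then tested
one-sidedly in the discovery direction, quantifying replicability as the
strength of evidence for a same-direction correlation.  The mega-analysis
merges all sites into one joint dataset.  Feature harmonisation (ComBat,
age-protected) is performed separately within discovery and replication
sets, and across all sites in the mega-analysis; the dependent variable is
z-scored within site and age is regressed out of both sides.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .bayescorr import DEFAULT_KAPPA, pearson_and_bf
from .harmonise import combat_fit, combat_apply, residualise_age, zscore_within_site

__all__ = ["prepare_analysis_set", "univariate_bf_table",
           "discovery_replication", "mega_analysis"]

logger = logging.getLogger(__name__)


def prepare_analysis_set(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    outcome: str = "pain_intensity",
    harmonise: bool = True,
    protect_age: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Harmonise features across the sites of one analysis set and return
    (adjusted features, adjusted outcome).

    Features are ComBat-harmonised (age-protected unless age is the
    outcome), the outcome is z-scored within site, and age is regressed out
    of both features and outcome (except when age is the outcome).
    """
    site = meta["site"].to_numpy(dtype=str)
    age_is_outcome = outcome == "age"
    X = features.copy()
    if harmonise and len(set(site)) >= 2:
        cov = meta[["age"]] if (protect_age and not age_is_outcome) else None
        model = combat_fit(X, site, cov)
        X = combat_apply(model, X, site, cov)
    y, _ = zscore_within_site(meta[outcome].to_numpy(dtype=float), site)
    if not age_is_outcome:
        age = meta["age"].to_numpy(dtype=float)
        X = pd.DataFrame(residualise_age(X.to_numpy(), age), index=X.index,
                         columns=X.columns)
        y = residualise_age(y, age)
    return X, y


def univariate_bf_table(
    X: pd.DataFrame,
    y: np.ndarray,
    sides: dict[str, str] | None = None,
    kappa: float = DEFAULT_KAPPA,
    fdr: bool = True,
) -> pd.DataFrame:
    """Per-feature Pearson r, Bayes factor, evidence label, and Spearman
    cross-check with FDR-corrected q-values."""
    rows = []
    for col in X.columns:
        side = (sides or {}).get(col, "two")
        res, rho, p = pearson_and_bf(X[col].to_numpy(), y, side=side, kappa=kappa)
        rows.append(
            {"feature": col, "r": res.r, "n": res.n, "bf": res.bf,
             "side": res.side, "label": res.evidence_label,
             "spearman_rho": rho, "p_spearman": p}
        )
    out = pd.DataFrame(rows).set_index("feature")
    if fdr:
        out["q_value"] = multipletests(out["p_spearman"], method="fdr_bh")[1]
    return out


def discovery_replication(
    discovery: tuple[pd.DataFrame, pd.DataFrame],
    replication: tuple[pd.DataFrame, pd.DataFrame],
    features: list[str] | None = None,
    outcome: str = "pain_intensity",
    discovery_sides: dict[str, str] | None = None,
    kappa: float = DEFAULT_KAPPA,
) -> pd.DataFrame:
    """Discovery-set correlations plus one-sided replication tests.

    ``discovery`` and ``replication`` are (features, meta) pairs;
    harmonisation and standardisation happen separately within the two
    sets.  Features missing from either set are skipped with a log entry.
    Replication sidedness follows the sign of the discovery correlation.
    """
    Xd_raw, md = discovery
    Xr_raw, mr = replication
    if features is None:
        features = [c for c in Xd_raw.columns]
    keep = [f for f in features if f in Xd_raw.columns and f in Xr_raw.columns]
    for f in features:
        if f not in keep:
            logger.warning("feature %s missing from one set; skipped", f)
    Xd, yd = prepare_analysis_set(Xd_raw[keep], md, outcome)
    Xr, yr = prepare_analysis_set(Xr_raw[keep], mr, outcome)
    disc = univariate_bf_table(Xd, yd, sides=discovery_sides, kappa=kappa)
    rep_sides = {
        f: ("positive" if disc.loc[f, "r"] >= 0 else "negative") for f in keep
    }
    rep = univariate_bf_table(Xr, yr, sides=rep_sides, kappa=kappa)
    disc.columns = [f"discovery_{c}" for c in disc.columns]
    rep.columns = [f"replication_{c}" for c in rep.columns]
    return disc.join(rep)


def mega_analysis(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    feature_names: list[str] | None = None,
    outcome: str = "pain_intensity",
    kappa: float = DEFAULT_KAPPA,
) -> pd.DataFrame:
    """Joint analysis of all sites merged into one dataset (two-sided)."""
    cols = feature_names or list(features.columns)
    X, y = prepare_analysis_set(features[cols], meta, outcome)
    return univariate_bf_table(X, y, kappa=kappa)
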