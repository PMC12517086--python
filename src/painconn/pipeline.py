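"""Orchestration of the three analyses: standard, network, explanatory.

Each run takes a feature-level cohort (either simulated or computed from
signal-level data) split into a discovery site and replication sites, and
produces result tables plus a JSON run manifest (config, seeds, versions).
Subgroup analyses (e.g. chronic back pain only, single gender) are plain
metadata filters on the same code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossval import ablate_features, bf_ratio, loo_cv, loso_cv
from .datatypes import BANDS
from .enet import DEFAULT_GRID, HyperParamGrid
from .stats import discovery_replication, mega_analysis

__all__ = ["AnalysisConfig", "run_standard_analysis", "run_network_analysis",
           "run_explanatory_analysis", "split_discovery_replication"]

logger = logging.getLogger(__name__)

#: Prespecified sidedness for the standard features: theta/beta power
#: positive, peak alpha frequency negative, alpha power bidirectional.
STANDARD_SIDES = {
    "power_theta": "positive",
    "power_beta": "positive",
    "paf_cog": "negative",
    "paf_localmax": "negative",
    "power_alpha": "two",
}


@dataclass
class AnalysisConfig:
    """Validated configuration for a pipeline run."""

    analysis: str = "network_univariate"
    outcome: str = "pain_intensity"
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    level: str = "network7"
    representative_method: str = "global"
    nc: int = 3
    epochs_required: int = 192
    grid: HyperParamGrid = DEFAULT_GRID
    inner_k: int = 10
    seed: int = 0
    discovery_site: str | None = None
    subgroup: dict[str, str] = field(default_factory=dict)

    _ANALYSES = ("standard", "network_univariate", "network_multivariate",
                 "explanatory", "age_control")

    def __post_init__(self) -> None:
        if self.analysis not in self._ANALYSES:
            raise ValueError(f"analysis must be one of {self._ANALYSES}")
        if self.level not in ("network7", "region25", "parcel100"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.representative_method not in ("global", "pairwise", "pca"):
            raise ValueError(f"unknown method {self.representative_method!r}")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"invalid band {name}: [{lo}, {hi})")
        if self.epochs_required < 1 or self.nc < 1:
            raise ValueError("epochs_required and nc must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid" in raw:
            raw["grid"] = HyperParamGrid(**raw["grid"])
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        return cls(**raw)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d, "config_hash": hashlib.sha256(blob.encode()).hexdigest()}


def _apply_subgroup(features: pd.DataFrame, meta: pd.DataFrame, subgroup: dict):
    mask = np.ones(len(meta), dtype=bool)
    for col, val in subgroup.items():
        mask &= (meta[col] == val).to_numpy()
    dropped = (~mask).sum()
    if dropped:
        logger.info("subgroup filter %s excluded %d participants", subgroup, dropped)
    return features.loc[mask], meta.loc[mask]


def split_discovery_replication(
    features: pd.DataFrame, meta: pd.DataFrame, discovery_site: str | None = None
):
    """Split a joint cohort into the discovery site (largest site when not
    named) and the pooled replication sites."""
    sites = meta["site"].astype(str)
    if discovery_site is None:
        discovery_site = sites.value_counts().idxmax()
    d = sites == discovery_site
    return ((features.loc[d], meta.loc[d]), (features.loc[~d], meta.loc[~d]))


def run_standard_analysis(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Univariate discovery/replication/mega statistics for the five
    standard sensor-level features, with prespecified sidedness."""
    config = config or AnalysisConfig(analysis="standard")
    features, meta = _apply_subgroup(features, meta, config.subgroup)
    cols = [c for c in STANDARD_SIDES if c in features.columns]
    if not cols:
        raise ValueError(
            "no standard feature columns (power_*/paf_*) in the table"
        )
    disc, rep = split_discovery_replication(features[cols], meta, config.discovery_site)
    dr = discovery_replication(
        disc, rep, outcome=config.outcome,
        discovery_sides={c: STANDARD_SIDES[c] for c in cols},
    )
    mega = mega_analysis(features[cols], meta, outcome=config.outcome)
    return {"discovery_replication": dr, "mega": mega}


def run_network_analysis(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    multivariate: bool = True,
) -> dict:
    """Univariate network-pair statistics and (optionally) the multivariate
    elastic-net models: LOO on the discovery set, LOO and LOSO on the joint
    set."""
    config = config or AnalysisConfig()
    features, meta = _apply_subgroup(features, meta, config.subgroup)
    disc, rep = split_discovery_replication(features, meta, config.discovery_site)
    out: dict = {}
    out["univariate"] = discovery_replication(disc, rep, outcome=config.outcome)
    out["univariate_mega"] = mega_analysis(features, meta, outcome=config.outcome)
    if multivariate:
        out["loo_discovery"] = loo_cv(
            disc[0], disc[1], outcome=config.outcome, grid=config.grid,
            inner_k=config.inner_k, seed=config.seed,
        )
        out["loo_joint"] = loo_cv(
            features, meta, outcome=config.outcome, grid=config.grid,
            inner_k=config.inner_k, seed=config.seed,
        )
        out["loso_joint"] = loso_cv(
            features, meta, outcome=config.outcome, grid=config.grid,
            inner_k=config.inner_k, seed=config.seed,
        )
    return out


def run_explanatory_analysis(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    reference_result=None,
    alternative_tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Compare the reference network-connectivity model against alternative
    models via BF-ratios.

    Always enumerated from the reference table: the three frequency-ablated
    models and the best-univariate model.  ``alternative_tables`` supplies
    models needing different features (activity at 7/25/100 structures,
    connectivity at 25/100 structures, PCA-derived connectivity).
    """
    config = config or AnalysisConfig(analysis="explanatory")
    features, meta = _apply_subgroup(features, meta, config.subgroup)
    if reference_result is None:
        reference_result = loo_cv(
            features, meta, outcome=config.outcome, grid=config.grid,
            inner_k=config.inner_k, seed=config.seed,
        )
    ref_bf = reference_result.bf.bf
    rows = [{"model": "reference", "r": reference_result.r_pred_obs,
             "bf": ref_bf, "bf_ratio": 1.0}]

    tables: dict[str, pd.DataFrame] = {}
    for band in config.bands:
        tables[f"minus_{band}"] = ablate_features(features, drop_band=band)
    mega = mega_analysis(features, meta, outcome=config.outcome)
    best_feature = mega["bf"].idxmax()
    tables["best_univariate"] = ablate_features(features, univariate=best_feature)
    for name, tab in (alternative_tables or {}).items():
        tables[name] = tab

    for name, tab in tables.items():
        res = loo_cv(
            tab, meta.loc[tab.index], outcome=config.outcome, grid=config.grid,
            inner_k=config.inner_k, seed=config.seed,
        )
        rows.append({"model": name, "r": res.r_pred_obs, "bf": res.bf.bf,
                     "bf_ratio": bf_ratio(ref_bf, res.bf.bf)})
    return pd.DataFrame(rows).set_index("model")
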