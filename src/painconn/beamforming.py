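"""Frequency-specific LCMV beamforming from sensors to parcel signals.

Unit array-gain linearly constrained minimum-variance spatial filters are
built per frequency band from a lead field and a band-specific sensor
covariance matrix.  The covariance is Tikhonov-regularised with 5 % of the
average sensor power (trace(C)/n_sensors).  With a free-orientation lead
field (three gain columns per parcel) the fixed orientation is chosen to
maximise the beamformer output variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datatypes import LeadField, SensorEpochs

__all__ = ["BandCovariance", "SpatialFilterSet", "band_covariance",
           "lcmv_filters", "apply_filters"]

REG_FRACTION_DEFAULT = 0.05


@dataclass
class BandCovariance:
    matrix: np.ndarray  # sensors x sensors
    band: str | None
    n_samples_used: int


@dataclass
class SpatialFilterSet:
    filters: np.ndarray  # parcels x sensors
    orientations: np.ndarray | None  # parcels x 3 unit vectors (free ori only)
    band: str | None
    reg_fraction: float


def band_covariance(epochs: SensorEpochs) -> BandCovariance:
    """Pooled sample covariance over all epochs after per-epoch mean removal.

    Concatenation of two epoch sets yields the sample-weighted average of
    their covariances.
    """
    X = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    n_total = epochs.n_epochs * epochs.n_samples
    if n_total < epochs.n_channels:
        warnings.warn(
            "fewer samples than channels: covariance is rank deficient; "
            "regularisation will compensate", stacklevel=2
        )
    C = np.einsum("ecs,eds->cd", X, X) / n_total
    return BandCovariance(matrix=C, band=epochs.band, n_samples_used=n_total)


def lcmv_filters(
    leadfield: LeadField,
    cov: BandCovariance,
    reg_fraction: float = REG_FRACTION_DEFAULT,
) -> SpatialFilterSet:
    """Unit-gain LCMV filters, one row per parcel.

    ``w = C_reg^{-1} l / (l^T C_reg^{-1} l)`` with
    ``C_reg = C + reg_fraction * (trace(C)/n_sensors) * I``.  Free
    orientations are resolved per parcel by minimising ``u^T L^T C_reg^{-1}
    L u`` over unit vectors u, i.e. maximising the unit-gain output
    variance ``1 / (l(u)^T C_reg^{-1} l(u))``.
    """
    C = np.asarray(cov.matrix, dtype=float)
    n_sens = C.shape[0]
    if leadfield.n_sensors != n_sens:
        raise ValueError(
            f"lead field has {leadfield.n_sensors} sensors, covariance {n_sens}"
        )
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("covariance has non-positive trace; cannot regularise")
    C_reg = C + reg_fraction * (tr / n_sens) * np.eye(n_sens)
    C_inv = linalg.inv(C_reg)

    orientations = None
    if leadfield.free_orientation:
        gains = np.empty((leadfield.n_parcels, n_sens))
        orientations = np.empty((leadfield.n_parcels, 3))
        for p in range(leadfield.n_parcels):
            L = leadfield.matrix[p]  # sensors x 3
            M = L.T @ C_inv @ L
            vals, vecs = linalg.eigh(M)
            u = vecs[:, 0]  # smallest eigenvalue -> max output variance
            orientations[p] = u
            gains[p] = L @ u
    else:
        gains = leadfield.matrix

    W = gains @ C_inv  # parcels x sensors (un-normalised)
    denom = np.einsum("ps,ps->p", W, gains)
    W = W / denom[:, None]
    return SpatialFilterSet(
        filters=W, orientations=orientations, band=cov.band, reg_fraction=reg_fraction
    )


def apply_filters(filters: SpatialFilterSet, epochs: SensorEpochs) -> np.ndarray:
    """Apply spatial filters to band-passed epochs.

    Returns parcel source epochs: epochs x parcels x samples.
    """
    if filters.band is not None and epochs.band is not None and filters.band != epochs.band:
        raise ValueError(
            f"band mismatch: filters for {filters.band!r}, epochs are {epochs.band!r}"
        )
    if filters.filters.shape[1] != epochs.n_channels:
        raise ValueError("channel count mismatch between filters and epochs")
    return np.einsum("pc,ecs->eps", filters.filters, epochs.data)
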