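"""Shared containers for the EEG network-connectivity pipeline.

Conventions
-----------
* Time series matrices are ``rows = signals/parcels/sensors``,
  ``columns = samples``.
* Epoched sensor data are ``epochs x channels x samples``; epochs are 2 s
  long with 50 % overlap and ordered by onset time.
* A lead field maps parcels to sensors: ``parcels x sensors`` for a fixed
  source orientation, ``parcels x sensors x 3`` for free orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical Yeo-7 large-scale network abbreviations, in display order:
#: visual, somatomotor, dorsal attention, salience (ventral attention),
#: limbic, frontoparietal, default.
YEO7 = ("VN", "SMN", "DAN", "SN", "LN", "FPN", "DN")

#: Canonical analysis bands (Hz, half-open [lo, hi)).
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: Alternative theta definition printed in some summaries (3-8 Hz).
BANDS_WIDE_THETA = {"theta": (3.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass
class BandSpec:
    """A frequency band, half-open interval [lo, hi)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band [{self.lo}, {self.hi})")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs < self.hi)


def band_specs(defs: dict[str, tuple[float, float]] | None = None) -> list[BandSpec]:
    defs = BANDS if defs is None else defs
    return [BandSpec(name, lo, hi) for name, (lo, hi) in defs.items()]


@dataclass
class SensorEpochs:
    """Epoched multi-channel EEG.

    ``continuous`` optionally retains the un-epoched record (channels x
    total samples) from which the epochs were cut; filtering operations use
    it to avoid edge effects on short epochs.
    """

    data: np.ndarray  # epochs x channels x samples
    fs: float
    channel_names: list[str]
    clean_flags: np.ndarray
    epoch_len_s: float = 2.0
    overlap: float = 0.5
    band: str | None = None
    continuous: np.ndarray | None = None
    onsets: np.ndarray | None = None  # epoch onset sample in `continuous`

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        self.clean_flags = np.asarray(self.clean_flags, dtype=bool)
        if self.clean_flags.shape[0] != self.data.shape[0]:
            raise ValueError("one clean flag per epoch required")
        n_samp = int(round(self.fs * self.epoch_len_s))
        if self.data.shape[2] != n_samp:
            raise ValueError(
                f"samples per epoch ({self.data.shape[2]}) must equal "
                f"fs*epoch_len_s ({n_samp})"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class LeadField:
    """Forward matrix mapping parcel sources to sensors.

    ``matrix`` is parcels x sensors (fixed orientation) or
    parcels x sensors x 3 (free orientation, one column triplet per parcel).
    ``network_labels`` assigns each parcel to a large-scale network.
    """

    matrix: np.ndarray
    network_labels: np.ndarray
    parcel_coords: np.ndarray | None = None
    network_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim not in (2, 3):
            raise ValueError("lead field must be 2-D or 3-D")
        self.network_labels = np.asarray(self.network_labels, dtype=int)
        if self.network_labels.shape[0] != self.n_parcels:
            raise ValueError("one network label per parcel required")

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[1]

    @property
    def free_orientation(self) -> bool:
        return self.matrix.ndim == 3

    @property
    def n_networks(self) -> int:
        return int(self.network_labels.max()) + 1

    def parcels_of(self, network: int) -> np.ndarray:
        return np.flatnonzero(self.network_labels == network)


@dataclass
class SourceTruth:
    """Ground-truth band-limited network and parcel signals."""

    network_signals: np.ndarray  # networks x samples
    parcel_signals: np.ndarray  # parcels x samples
    parcel_labels: np.ndarray  # parcel -> network
    envelope_corr_target: np.ndarray  # networks x networks
    band: str
    fs: float

    def __post_init__(self) -> None:
        C = np.asarray(self.envelope_corr_target, float)
        if not np.allclose(C, C.T):
            raise ValueError("envelope correlation target must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("envelope correlation target needs unit diagonal")
        counts = np.bincount(np.asarray(self.parcel_labels, int),
                             minlength=self.network_signals.shape[0])
        if (counts == 0).any():
            raise ValueError("every network needs at least one parcel")


@dataclass
class RepresentativeSolution:
    """A unit-norm representative time series and its diagnostics."""

    r: np.ndarray  # 1-D, length n, unit norm
    w: np.ndarray  # weights over the concatenated structure rows
    nu: float  # explained-variance fraction in the structure of interest
    objective: float
    converged: bool
    n_restarts_used: int = 1
    grad_norm: float = np.nan


@dataclass
class CohortConfig:
    """Configuration of the feature-level multi-site cohort generator.

    Defaults emulate the eight-site study layout (participant counts with at
    least 192 clean epochs per site; total n = 614).
    """

    n_per_site: tuple[int, ...] = (119, 63, 60, 57, 77, 68, 47, 123)
    planted_effects: tuple[tuple[str, float], ...] = ()
    multivariate_effect: tuple[int, float] | None = None  # (n_informative, R^2)
    site_shift: np.ndarray | None = None
    site_scale: np.ndarray | None = None
    age_effect: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.n_per_site)

    def __post_init__(self) -> None:
        for name, rho in self.planted_effects:
            if not abs(rho) < 1:
                raise ValueError(f"|rho| must be < 1 for feature {name}")
        if self.site_scale is not None and np.any(np.asarray(self.site_scale) <= 0):
            raise ValueError("site_scale must be positive")
        if self.planted_effects and self.multivariate_effect is not None:
            raise ValueError(
                "planted_effects and multivariate_effect are mutually exclusive"
            )
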