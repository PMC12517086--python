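"""Synthetic multi-site EEG cohorts with controlled statistical structure.

Two tiers of generators are provided:

* **Signal level** -- band-limited network source signals with a prescribed
  cross-network amplitude-envelope correlation structure, mixed into sensor
  space through a toy lead field plus 1/f sensor noise.  These feed the full
  source-reconstruction / representative-signal / connectivity pipeline.
* **Feature level** -- participants x features tables with planted
  feature-pain correlations, site location/scale distortions, and age
  effects.  These feed the harmonisation, statistics, and predictive-model
  stages at realistic cohort sizes without paying the signal-level cost.

Every operation is fully deterministic given its seed.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.ndimage import gaussian_filter1d

from .datatypes import (
    BANDS,
    YEO7,
    BandSpec,
    CohortConfig,
    LeadField,
    SensorEpochs,
    SourceTruth,
)

__all__ = [
    "make_toy_leadfield",
    "simulate_network_sources",
    "simulate_sensor_recording",
    "simulate_feature_cohort",
    "simulate_signal_cohort",
    "connectivity_feature_names",
    "epochs_from_continuous",
    "default_signal_effects",
]

# Chronic-back-pain fraction per site, mirroring the eight-cohort layout
# (two German sites, Brisbane, two Otago sites, Boulder, Haifa, Seattle).
_CBP_FRACTION = (74 / 119, 21 / 63, 1.0, 1.0, 1.0, 1.0, 0.0, 48 / 123)

# Log-envelope standard deviation of the log-normal envelope model.
_SIGMA_LOG = 0.8
# Time constant (s) of the latent envelope dynamics (Gaussian smoothing sd).
_ENV_TAU_S = 0.5


def connectivity_feature_names(
    bands: tuple[str, ...] = ("theta", "alpha", "beta"),
    networks: tuple[str, ...] = YEO7,
) -> list[str]:
    """Canonical 63-column layout: ``{band}_{netA}-{netB}`` over the 21
    unordered network pairs per band."""
    pairs = list(itertools.combinations(networks, 2))
    return [f"{band}_{a}-{b}" for band in bands for a, b in pairs]


# ---------------------------------------------------------------------------
# Toy lead field
# ---------------------------------------------------------------------------

def make_toy_leadfield(
    n_sensors: int,
    n_parcels: int,
    n_networks: int,
    seed: int,
    free_orientation: bool = False,
) -> LeadField:
    """Smooth, full-row-rank toy forward model.

    Parcels and sensors are laid out on concentric rings; each parcel
    projects a Gaussian spatial gain profile onto the sensors so that
    neighbouring parcels map to overlapping sensor patterns.  Parcels are
    assigned to networks in balanced contiguous blocks.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    if n_parcels < n_networks:
        raise ValueError(
            f"n_parcels ({n_parcels}) must be >= n_networks ({n_networks})"
        )
    if n_sensors < n_parcels:
        raise ValueError(
            f"cannot have rank {n_parcels}: n_sensors ({n_sensors}) < "
            f"n_parcels ({n_parcels})"
        )
    rng = np.random.default_rng(seed)
    parcel_angle = 2 * np.pi * np.arange(n_parcels) / n_parcels
    sensor_angle = 2 * np.pi * np.arange(n_sensors) / n_sensors
    # angular distance on the ring
    d = np.abs(parcel_angle[:, None] - sensor_angle[None, :])
    d = np.minimum(d, 2 * np.pi - d)
    width = 2 * np.pi / n_parcels
    base = np.exp(-0.5 * (d / width) ** 2)
    jitter = 0.05 * rng.standard_normal((n_parcels, n_sensors))
    mat = base + jitter
    if free_orientation:
        # three nearly-orthogonal gain patterns per parcel; the first is the
        # dominant (radial) one
        mats = np.empty((n_parcels, n_sensors, 3))
        mats[:, :, 0] = mat
        for k in (1, 2):
            rolled = np.roll(base, k, axis=1)
            mats[:, :, k] = 0.5 * rolled + 0.05 * rng.standard_normal(
                (n_parcels, n_sensors)
            )
        full = mats
        rank = np.linalg.matrix_rank(mats[:, :, 0])
    else:
        full = mat
        rank = np.linalg.matrix_rank(mat)
    if rank < n_parcels:
        raise ValueError(
            f"constructed lead field is rank deficient: rank {rank} < "
            f"n_parcels {n_parcels}"
        )
    labels = np.floor(np.arange(n_parcels) * n_networks / n_parcels).astype(int)
    coords = np.stack([np.cos(parcel_angle), np.sin(parcel_angle)], axis=1)
    names = YEO7[:n_networks] if n_networks <= len(YEO7) else tuple(
        f"net{i}" for i in range(n_networks)
    )
    return LeadField(full, labels, parcel_coords=coords, network_names=names)


# ---------------------------------------------------------------------------
# Band-limited sources with calibrated envelope correlations
# ---------------------------------------------------------------------------

def _fir_bandpass(fs: float, lo: float, hi: float, transition: float = 2.0) -> np.ndarray:
    """Linear-phase FIR band-pass (Hamming), ~53 dB stopband, given
    transition width in Hz."""
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def _bandlimited_noise(n_signals: int, n: int, fs: float, band: BandSpec,
                       rng: np.random.Generator) -> np.ndarray:
    taps = _fir_bandpass(fs, band.lo, band.hi)
    x = rng.standard_normal((n_signals, n + 2 * len(taps)))
    y = signal.filtfilt(taps, [1.0], x, axis=1)[:, len(taps):len(taps) + n]
    return y / y.std(axis=1, keepdims=True)


def _lognormal_corr(latent: np.ndarray | float, sigma: float = _SIGMA_LOG):
    """Pearson correlation of two log-normal envelopes exp(sigma*g) whose
    standard-normal latents have correlation ``latent``."""
    return np.expm1(sigma**2 * np.asarray(latent)) / np.expm1(sigma**2)


def _correlated_envelopes(latent_corr: np.ndarray, n: int, fs: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Log-normal envelopes from a Gaussian copula with the given latent
    instantaneous correlation; slow dynamics via Gaussian smoothing."""
    k = latent_corr.shape[0]
    try:
        chol = np.linalg.cholesky(latent_corr + 1e-10 * np.eye(k))
    except np.linalg.LinAlgError:
        raise ValueError(
            "calibrated latent correlation matrix is not positive "
            "semi-definite; shrink the envelope correlation target toward "
            "the identity"
        )
    g = chol @ rng.standard_normal((k, n))
    g = gaussian_filter1d(g, sigma=_ENV_TAU_S * fs, axis=1, mode="wrap")
    g -= g.mean(axis=1, keepdims=True)
    g /= g.std(axis=1, keepdims=True)
    return np.exp(_SIGMA_LOG * g)


def _measure_aec(x: np.ndarray, y: np.ndarray, fs: float) -> float:
    # local import: connectivity is downstream but the helper is stateless
    from .connectivity import envelope_correlation

    return envelope_correlation(x, y, fs)


#: Latent-correlation grid of the calibration curve.
_CAL_LATENTS = np.array(
    [-0.95, -0.6, -0.3, 0.0, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.95, 1.0]
)
_CAL_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _calibration_curve(
    band: BandSpec, fs: float, duration_s: float = 300.0, n_rep: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone empirical map latent correlation -> measured envelope
    correlation for this band, averaged over ``n_rep`` independent signal
    pairs per grid point.  Cached per (band, fs); the internal seed is a
    fixed function of the key so the curve (and hence every downstream
    simulation) is deterministic.
    """
    key = (round(band.lo, 3), round(band.hi, 3), round(fs, 3))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    seed = int(np.abs(np.sum(np.array(key) * [7919, 104729, 1299709])).astype(np.int64) % (2**31))
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    emp = np.empty(len(_CAL_LATENTS))
    for gi, l0 in enumerate(_CAL_LATENTS):
        if l0 == 0.0:
            emp[gi] = 0.0
            continue
        # n_rep independent pairs simulated jointly (block-diagonal latent)
        k = 2 * n_rep
        latent = np.eye(k)
        for rep in range(n_rep):
            latent[2 * rep, 2 * rep + 1] = latent[2 * rep + 1, 2 * rep] = l0
        s = _correlated_envelopes(latent, n, fs, rng) * _bandlimited_noise(
            k, n, fs, band, rng
        )
        emp[gi] = np.mean(
            [_measure_aec(s[2 * rep], s[2 * rep + 1], fs) for rep in range(n_rep)]
        )
    emp = np.maximum.accumulate(emp)
    _CAL_CACHE[key] = (_CAL_LATENTS.copy(), emp)
    return _CAL_CACHE[key]


def _invert_calibration(band: BandSpec, fs: float, target: float) -> float:
    """Latent correlation achieving the target envelope correlation, by
    monotone root finding on the interpolated calibration curve."""
    from scipy.interpolate import PchipInterpolator

    lat, emp = _calibration_curve(band, fs)
    if target > emp[-1] or target < emp[0]:
        raise ValueError(
            f"envelope correlation target {target:.3f} is outside the "
            f"attainable range [{emp[0]:.2f}, {emp[-1]:.2f}] for band "
            f"{band.name}; shrink the target toward the identity"
        )
    curve = PchipInterpolator(lat, emp)
    return float(optimize.brentq(lambda l: curve(l) - target, lat[0], lat[-1], xtol=1e-10))


def simulate_network_sources(
    envelope_corr_target: np.ndarray,
    band: str | BandSpec,
    duration_s: float,
    fs: float,
    seed: int,
    parcel_labels: np.ndarray | None = None,
    parcel_noise: float = 0.5,
    psd_fix: bool = False,
) -> SourceTruth:
    """Band-limited network sources whose pairwise Hilbert-envelope
    correlations are calibrated to ``envelope_corr_target``.

    Carriers are band-pass filtered white noise; envelopes are log-normal,
    driven by a Gaussian copula whose latent correlation is found per pair
    by monotone 1-D root finding so that the measured envelope correlation
    approaches the target.  Parcel signals are the parent network signal
    plus local band-limited noise of relative amplitude ``parcel_noise``.
    """
    if isinstance(band, str):
        band = BandSpec(band, *BANDS[band])
    C = np.asarray(envelope_corr_target, dtype=float)
    k = C.shape[0]
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("target must be symmetric with unit diagonal")
    rng = np.random.default_rng(seed)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            latent[i, j] = latent[j, i] = _invert_calibration(band, fs, C[i, j])
    if np.linalg.eigvalsh(latent).min() < -1e-8:
        if not psd_fix:
            raise ValueError(
                "calibrated latent correlation matrix is not positive "
                "semi-definite; shrink the target toward the identity"
            )
        # nearest-PSD repair: clip eigenvalues, restore the unit diagonal
        vals, vecs = np.linalg.eigh(latent)
        latent = (vecs * np.maximum(vals, 1e-6)) @ vecs.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)

    n = int(duration_s * fs)
    env = _correlated_envelopes(latent, n, fs, rng)
    car = _bandlimited_noise(k, n, fs, band, rng)
    net = env * car
    net /= net.std(axis=1, keepdims=True)

    if parcel_labels is None:
        parcel_labels = np.arange(k)
    parcel_labels = np.asarray(parcel_labels, dtype=int)
    local = _bandlimited_noise(len(parcel_labels), n, fs, band, rng)
    parcels = net[parcel_labels] + parcel_noise * local

    return SourceTruth(
        network_signals=net,
        parcel_signals=parcels,
        parcel_labels=parcel_labels,
        envelope_corr_target=C,
        band=band.name,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# Sensor-space forward model
# ---------------------------------------------------------------------------

def _one_over_f_noise(n_channels: int, n: int, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Spatially white sensor noise with a 1/f amplitude spectrum
    (flat below 1 Hz)."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1 / fs)
    amp = 1.0 / np.maximum(f, 1.0)
    noise = np.fft.irfft(spec * amp, n=n, axis=1)
    return noise / noise.std()


def epochs_from_continuous(
    continuous: np.ndarray,
    fs: float,
    epoch_len_s: float = 2.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Cut channels x samples into epochs x channels x samples with the
    given fractional overlap; only complete epochs are kept."""
    n_samp = int(round(fs * epoch_len_s))
    hop = int(round(n_samp * (1 - overlap)))
    total = continuous.shape[1]
    if total < n_samp:
        return np.empty((0, continuous.shape[0], n_samp))
    onsets = range(0, total - n_samp + 1, hop)
    return np.stack([continuous[:, o:o + n_samp] for o in onsets])


def simulate_sensor_recording(
    truth: SourceTruth | np.ndarray,
    leadfield: LeadField,
    snr_db: float,
    seed: int,
    fs: float | None = None,
    epoch_len_s: float = 2.0,
    overlap: float = 0.5,
) -> SensorEpochs:
    """Project parcel signals to sensors and add 1/f noise at a given SNR.

    ``truth`` may be a single SourceTruth or a raw parcels x samples array
    (e.g., the sum of several band-specific source sets) with ``fs`` given.
    The continuous sensor record is segmented into 2 s epochs with 50 %
    overlap; all epochs are flagged clean.
    """
    if isinstance(truth, SourceTruth):
        parcels, fs = truth.parcel_signals, truth.fs
    else:
        parcels = np.asarray(truth, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a raw parcel array")
    if parcels.shape[0] != leadfield.n_parcels:
        raise ValueError(
            f"parcel count mismatch: signals {parcels.shape[0]} vs "
            f"lead field {leadfield.n_parcels}"
        )
    gain = leadfield.matrix[:, :, 0] if leadfield.free_orientation else leadfield.matrix
    proj = gain.T @ parcels  # sensors x samples
    rng = np.random.default_rng(seed)
    noise = _one_over_f_noise(proj.shape[0], proj.shape[1], fs, rng)
    p_sig = float(np.mean(proj**2))
    p_noise = p_sig / 10 ** (snr_db / 10)
    sensors = proj + np.sqrt(p_noise) * noise

    data = epochs_from_continuous(sensors, fs, epoch_len_s, overlap)
    n_samp = int(round(fs * epoch_len_s))
    hop = int(round(n_samp * (1 - overlap)))
    return SensorEpochs(
        data=data,
        fs=fs,
        channel_names=[f"ch{i:03d}" for i in range(sensors.shape[0])],
        clean_flags=np.ones(data.shape[0], dtype=bool),
        epoch_len_s=epoch_len_s,
        overlap=overlap,
        continuous=sensors,
        onsets=np.arange(data.shape[0]) * hop,
    )


# ---------------------------------------------------------------------------
# Feature-level cohort generator
# ---------------------------------------------------------------------------

def simulate_feature_cohort(
    config: CohortConfig,
    feature_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participants x features table with planted pain associations.

    Features are latent standard normals.  Univariate effects plant a
    correlation rho between a feature and the latent pain score through a
    one-factor model; the multivariate mode makes the latent pain score a
    noisy linear readout of ``n_informative`` features with total signal
    R^2 as requested.  Age slopes, then per-site additive/multiplicative
    distortions, are applied afterwards.  Pain intensity is reported on the
    0-10 NRS by affine clip-and-round of the latent score.
    """
    if feature_names is None:
        feature_names = connectivity_feature_names()
    p = len(feature_names)
    names_idx = {n: i for i, n in enumerate(feature_names)}
    for name, _ in config.planted_effects:
        if name not in names_idx:
            raise ValueError(f"planted feature {name!r} not in the feature layout")
    for name in config.age_effect:
        if name not in names_idx:
            raise ValueError(f"age-effect feature {name!r} not in the feature layout")

    rng = np.random.default_rng(config.seed)
    n_total = int(sum(config.n_per_site))
    site = np.repeat(np.arange(config.n_sites), config.n_per_site)

    if config.multivariate_effect is not None:
        n_inf, r2 = config.multivariate_effect
        if not 0 <= r2 < 1:
            raise ValueError("multivariate R^2 must be in [0, 1)")
        X = rng.standard_normal((n_total, p))
        informative = np.linspace(0, p - 1, n_inf).round().astype(int)
        signal_part = X[:, informative].sum(axis=1) / np.sqrt(n_inf)
        pain_z = np.sqrt(r2) * signal_part + np.sqrt(1 - r2) * rng.standard_normal(n_total)
    else:
        pain_z = rng.standard_normal(n_total)
        X = rng.standard_normal((n_total, p))
        rho = np.zeros(p)
        for name, r in config.planted_effects:
            rho[names_idx[name]] = r
        # one-factor construction keeps the joint correlation matrix PSD
        X = pain_z[:, None] * rho[None, :] + np.sqrt(1 - rho**2)[None, :] * X

    age = np.clip(rng.normal(50.0, 12.0, n_total), 20.0, 80.0)
    age_z = (age - age.mean()) / age.std()
    for name, slope in config.age_effect.items():
        X[:, names_idx[name]] += slope * age_z

    shift = (np.asarray(config.site_shift, float) if config.site_shift is not None
             else rng.normal(0.0, 0.4, config.n_sites))
    scale = (np.asarray(config.site_scale, float) if config.site_scale is not None
             else np.exp(rng.normal(0.0, 0.15, config.n_sites)))
    X = X * scale[site][:, None] + shift[site][:, None]

    pain = np.clip(np.round(5.0 + 1.8 * pain_z), 0, 10).astype(int)
    cbp_frac = list(_CBP_FRACTION) + [0.66] * max(0, config.n_sites - len(_CBP_FRACTION))
    diagnosis = np.where(
        rng.random(n_total) < np.asarray(cbp_frac)[site], "CBP", "OTHER"
    )

    pid = [f"sub-{i:04d}" for i in range(n_total)]
    features = pd.DataFrame(X, columns=feature_names, index=pd.Index(pid, name="participant_id"))
    meta = pd.DataFrame(
        {
            "site": [f"site{s}" for s in site],
            "age": age,
            "pain_intensity": pain,
            "diagnosis": diagnosis,
        },
        index=features.index,
    )
    return features, meta


# ---------------------------------------------------------------------------
# Signal-level cohort generator
# ---------------------------------------------------------------------------

def default_signal_effects(networks: tuple[str, ...] = YEO7) -> dict:
    """Planted pain effects on the envelope-correlation targets.

    Positive theta-band coupling-pain slopes, strongest for limbic (LN)
    pairs, plus a distributed pattern of smaller positive and negative
    slopes at alpha and beta frequencies.
    """
    idx = {n: i for i, n in enumerate(networks)}
    eff: dict[str, dict[tuple[int, int], float]] = {"theta": {}, "alpha": {}, "beta": {}}
    if "LN" in idx:
        for other in networks:
            if other != "LN":
                pair = tuple(sorted((idx["LN"], idx[other])))
                eff["theta"][pair] = 0.12
    if "SN" in idx and "SMN" in idx:
        eff["theta"][tuple(sorted((idx["SN"], idx["SMN"])))] = 0.10
    # weaker distributed alpha/beta pattern: theta carries most of the
    # signal, the other bands contribute complementary information
    pairs = list(itertools.combinations(range(len(networks)), 2))
    for k, pair in enumerate(pairs[::4]):
        eff["alpha"][pair] = -0.04 if k % 2 == 0 else 0.03
    for k, pair in enumerate(pairs[1::4]):
        eff["beta"][pair] = 0.04 if k % 2 == 0 else -0.03
    return eff


def simulate_signal_cohort(
    n_participants: int,
    leadfield: LeadField,
    seed: int,
    duration_s: float = 64.0,
    fs: float = 250.0,
    snr_db: float = 3.0,
    baseline_coupling: float = 0.3,
    effects: dict | None = None,
    parcel_noise: float = 0.5,
    bands: dict[str, tuple[float, float]] | None = None,
) -> Iterator[tuple[dict, SensorEpochs]]:
    """Yield per-participant broadband sensor recordings whose band-specific
    network envelope couplings depend on a latent pain score.

    The broadband parcel signal is the sum of three band-limited source
    sets (theta, alpha, beta).  Per band, the envelope-correlation target is
    ``baseline_coupling`` plus planted slopes times the participant's latent
    pain score, clipped to the attainable range.
    """
    bands = BANDS if bands is None else bands
    if effects is None:
        effects = default_signal_effects(
            leadfield.network_names or YEO7[: leadfield.n_networks]
        )
    k = leadfield.n_networks
    rng = np.random.default_rng(seed)
    for i in range(n_participants):
        pain_z = float(rng.standard_normal())
        age = float(np.clip(rng.normal(50, 12), 20, 80))
        parcel_sum = None
        for band_name in bands:
            C = np.full((k, k), baseline_coupling)
            np.fill_diagonal(C, 1.0)
            for (a, b), slope in effects.get(band_name, {}).items():
                val = np.clip(baseline_coupling + slope * pain_z, 0.02, 0.7)
                C[a, b] = C[b, a] = val
            truth = simulate_network_sources(
                C,
                BandSpec(band_name, *bands[band_name]),
                duration_s,
                fs,
                seed=int(rng.integers(2**31)),
                parcel_labels=leadfield.network_labels,
                parcel_noise=parcel_noise,
                psd_fix=True,
            )
            parcel_sum = (truth.parcel_signals if parcel_sum is None
                          else parcel_sum + truth.parcel_signals)
        rec = simulate_sensor_recording(
            parcel_sum, leadfield, snr_db, seed=int(rng.integers(2**31)), fs=fs
        )
        pain = int(np.clip(np.round(5.0 + 1.8 * pain_z), 0, 10))
        meta = {
            "participant_id": f"sub-{i:04d}",
            "site": "sim",
            "age": age,
            "pain_intensity": pain,
            "pain_z": pain_z,
            "diagnosis": "CBP",
        }
        yield meta, rec
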