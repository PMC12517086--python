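"""Epoch selection, band-pass filtering, and standard sensor-level features.

The standard features are the band-averaged global absolute power in the
theta, alpha, and beta bands and two variants of the peak alpha frequency
(PAF): the centre of gravity and the local maximum of the power spectral
density in the alpha band.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .datatypes import BANDS, BandSpec, SensorEpochs

__all__ = [
    "ParticipantExclusionError",
    "select_epochs",
    "bandpass",
    "psd_welch",
    "global_band_power",
    "peak_alpha_frequency",
    "standard_features",
]

#: Epochs required per participant for inclusion.
N_EPOCHS_REQUIRED = 192


class ParticipantExclusionError(ValueError):
    """Raised when a recording has too few clean epochs; the caller is
    expected to exclude the participant."""


def select_epochs(rec: SensorEpochs, n_required: int = N_EPOCHS_REQUIRED) -> SensorEpochs:
    """Return the earliest ``n_required`` epochs flagged clean, in order."""
    idx = np.flatnonzero(rec.clean_flags)
    if len(idx) < n_required:
        raise ParticipantExclusionError(
            f"only {len(idx)} clean epochs available, {n_required} required; "
            "participant does not meet the minimum epoch number requirement"
        )
    keep = idx[:n_required]
    return dataclasses.replace(
        rec,
        data=rec.data[keep],
        clean_flags=rec.clean_flags[keep],
        continuous=rec.continuous,
        onsets=rec.onsets[keep] if rec.onsets is not None else None,
    )


def _fir_taps(band: BandSpec, fs: float, transition: float = 2.0) -> np.ndarray:
    # Hamming-window FIR: ~53 dB stopband, transition width 3.3/numtaps * fs
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    return signal.firwin(numtaps, [band.lo, band.hi], pass_zero=False, fs=fs)


def bandpass(epochs: SensorEpochs, band: BandSpec, transition: float = 2.0) -> SensorEpochs:
    """Zero-phase FIR band-pass filtering.

    When the epochs were cut from a retained continuous record, the record
    is filtered once and re-epoched (no per-epoch edge effects).  Otherwise
    each epoch is filtered independently, which requires epochs at least
    three filter lengths long.
    """
    if band.hi > epochs.fs / 2:
        raise ValueError(f"band [{band.lo}, {band.hi}) exceeds Nyquist {epochs.fs / 2}")
    taps = _fir_taps(band, epochs.fs, transition)
    if epochs.continuous is not None:
        filtered = signal.filtfilt(taps, [1.0], epochs.continuous, axis=1)
        n_samp = epochs.n_samples
        if epochs.onsets is not None:
            data = np.stack([filtered[:, o:o + n_samp] for o in epochs.onsets])
        else:
            from .synthetic import epochs_from_continuous

            data = epochs_from_continuous(
                filtered, epochs.fs, epochs.epoch_len_s, epochs.overlap
            )[: epochs.n_epochs]
        return dataclasses.replace(
            epochs, data=data, band=band.name, continuous=filtered
        )
    if epochs.n_samples <= 3 * len(taps):
        raise ValueError(
            f"epochs of {epochs.n_samples} samples are too short for a "
            f"{len(taps)}-tap zero-phase filter; retain the continuous "
            "record (SensorEpochs.continuous) to use concatenated filtering"
        )
    data = signal.filtfilt(taps, [1.0], epochs.data, axis=2)
    return dataclasses.replace(epochs, data=data, band=band.name, continuous=None)


def psd_welch(epochs: SensorEpochs) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with one Hann-windowed segment per epoch.

    Returns (freqs, psd) with psd of shape channels x freqs, averaged over
    epochs (density scaling, one-sided).
    """
    if epochs.n_epochs < 1:
        raise ValueError("at least one epoch required")
    freqs, p = signal.periodogram(
        epochs.data, fs=epochs.fs, window="hann", axis=2, scaling="density"
    )
    return freqs, p.mean(axis=0)


def global_band_power(epochs: SensorEpochs, band: BandSpec) -> float:
    """Mean PSD within the band, averaged over in-band frequencies and over
    all channels (absolute power density)."""
    freqs, psd = psd_welch(epochs)
    mask = band.contains(freqs)
    if not mask.any():
        raise ValueError(f"no PSD frequencies inside [{band.lo}, {band.hi})")
    return float(psd[:, mask].mean())


def peak_alpha_frequency(
    freqs: np.ndarray,
    psd: np.ndarray,
    method: str = "cog",
    band: BandSpec | None = None,
) -> float:
    """Peak alpha frequency from a PSD.

    ``cog`` is the centre of gravity sum(f*P)/sum(P) over the alpha band;
    ``localmax`` is the frequency of the highest local maximum strictly
    inside the band (NaN when no interior local maximum exists).  ``psd``
    may be channels x freqs (averaged over channels first) or 1-D.
    """
    band = band or BandSpec("alpha", *BANDS["alpha"])
    psd = np.asarray(psd, dtype=float)
    if psd.ndim == 2:
        psd = psd.mean(axis=0)
    mask = band.contains(np.asarray(freqs))
    f, p = np.asarray(freqs)[mask], psd[mask]
    if len(f) == 0:
        raise ValueError("PSD does not cover the alpha band")
    if not np.any(p > 0):
        raise ValueError("all-zero PSD in the alpha band")
    if method == "cog":
        return float(np.average(f, weights=p))
    if method == "localmax":
        # strict interior local maxima on the in-band grid
        interior = np.flatnonzero((p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])) + 1
        if len(interior) == 0:
            return float("nan")
        return float(f[interior[np.argmax(p[interior])]])
    raise ValueError(f"unknown PAF method {method!r}")


def standard_features(
    epochs: SensorEpochs,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """The five standard sensor-level features: three global band powers and
    the two PAF variants."""
    bands = BANDS if bands is None else bands
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        out[f"power_{name}"] = global_band_power(epochs, BandSpec(name, lo, hi))
    freqs, psd = psd_welch(epochs)
    alpha = BandSpec("alpha", *bands.get("alpha", BANDS["alpha"]))
    out["paf_cog"] = peak_alpha_frequency(freqs, psd, "cog", alpha)
    out["paf_localmax"] = peak_alpha_frequency(freqs, psd, "localmax", alpha)
    return out
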