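"""Surface-EMG fatigue indices.

Per epoch and per analysis band (20-100 Hz and 100-150 Hz) three classical
indices are computed:

* **RMS** -- root mean square of the band-filtered time signal (amplitude,
  microvolts);
* **MPF** -- mean power frequency, the power-weighted mean of frequency over
  the band:  MPF = (integral of f*P(f) df) / (integral of P(f) df);
* **MF**  -- median frequency, the smallest grid frequency at which the
  cumulative band power reaches half the total band power.

A downward shift of MPF/MF is the standard spectral signature of muscle
fatigue.  Spectra come from Welch's method (1 s Hann windows, 50% overlap,
~1 Hz resolution), the field default for surface EMG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import Epochs, ParameterError


class FeatureError(ValueError):
    """Feature undefined for the given input (empty signal, zero band power)."""


@dataclass
class Spectrum:
    """One-sided power spectral density on a regular frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise FeatureError("freqs and power must be matching 1-D arrays")
        if np.any(np.diff(self.freqs) <= 0):
            raise FeatureError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise FeatureError("power density must be nonnegative")

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freqs >= lo) & (self.freqs <= hi)


def rms(x: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise FeatureError("RMS of an empty signal is undefined")
    return float(np.sqrt(np.mean(x**2)))


def welch_psd(x: np.ndarray, rate: float, win_s: float = 1.0, overlap: float = 0.5) -> Spectrum:
    """Welch PSD with Hann windows of ``win_s`` seconds and fractional overlap."""
    x = np.asarray(x, dtype=float)
    nper = int(round(win_s * rate))
    if x.size < nper:
        raise ParameterError(f"signal ({x.size} samples) shorter than window ({nper})")
    f, p = sps.welch(
        x, fs=rate, window="hann", nperseg=nper, noverlap=int(round(nper * overlap))
    )
    return Spectrum(freqs=f, power=p)


def mpf(spec: Spectrum, band: tuple[float, float]) -> float:
    """Power-weighted mean frequency within ``band``."""
    m = spec.band_slice(band)
    p = spec.power[m]
    if not np.any(m) or p.sum() <= 0:
        raise FeatureError(f"no spectral power in band {band}")
    return float(np.sum(spec.freqs[m] * p) / np.sum(p))


def mf(spec: Spectrum, band: tuple[float, float]) -> float:
    """Median frequency: smallest grid frequency whose cumulative band power
    reaches half the total band power (deterministic left tie-break)."""
    m = spec.band_slice(band)
    p = spec.power[m]
    if not np.any(m) or p.sum() <= 0:
        raise FeatureError(f"no spectral power in band {band}")
    csum = np.cumsum(p)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return float(spec.freqs[m][idx])


def emg_feature_table(
    ep: Epochs,
    bands=((20.0, 100.0), (100.0, 150.0)),
    emg_label: str | None = None,
    win_s: float = 1.0,
) -> pd.DataFrame:
    """One row per kept epoch x band with RMS (band-filtered time signal) and
    MPF/MF (Welch spectrum of the raw epoch, integrated over the band).

    Returns a DataFrame with columns
    ``subject, condition, state, epoch, band_lo, band_hi, rms, mpf, mf``.
    """
    if emg_label is None:
        emg_idx = [i for i, k in enumerate(ep.kinds) if k == "EMG"]
        if not emg_idx:
            raise KeyError("no EMG channel in epochs")
        emg_label = ep.labels[emg_idx[0]]
    ch = ep.channel_index(emg_label)
    meta = ep.meta

    rows = []
    for lo, hi in bands:
        if hi >= ep.rate / 2:
            raise ParameterError(f"band edge {hi} Hz >= Nyquist {ep.rate / 2} Hz")
        # band-filter each epoch independently (rows of the 2-D block)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=ep.rate, output="sos")
        filt = sps.sosfiltfilt(sos, ep.data[:, ch, :], axis=1)
        for j in range(ep.n_epochs):
            spec = welch_psd(ep.data[j, ch], ep.rate, win_s=win_s)
            rows.append(
                {
                    "subject": meta.get("subject", ""),
                    "condition": meta.get("condition", ""),
                    "state": meta.get("state", ""),
                    "epoch": int(ep.kept_indices[j]),
                    "band_lo": lo,
                    "band_hi": hi,
                    "rms": rms(filt[j]),
                    "mpf": mpf(spec, (lo, hi)),
                    "mf": mf(spec, (lo, hi)),
                }
            )
    return pd.DataFrame(rows)
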