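"""Signal cleaning chain.

EEG path: band-pass 1-100 Hz -> notch 48-52 and 98-102 Hz -> resample to
500 Hz -> re-reference to the bilateral mastoids (M1, M2) -> cut into 2 s
epochs -> reject bad epochs.  EMG path: band-pass 20-150 Hz (applied as a
cascade, i.e. doubled effective order) -> resample -> epoch.

All filters are 4th-order Butterworth run forward-backward (``filtfilt``), so
they are zero-phase: instantaneous phase downstream (PLV) is not biased by
filter delay.  Manual epoch vetting is replaced by a deterministic rule:
an epoch is dropped when its peak absolute amplitude exceeds a threshold or
any channel's RMS is an outlier (z-score across epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dataio import Recording


class ParameterError(ValueError):
    """Filter band or epoch parameter incompatible with the data."""


class PipelineError(RuntimeError):
    """A stage could not produce usable output (e.g. every epoch rejected)."""


@dataclass
class Epochs:
    """Segmented data: ``(n_epochs, n_channels, n_samples)``."""

    data: np.ndarray
    rate: float
    epoch_length: float
    labels: list[str]
    kinds: list[str]
    kept_indices: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        if self.data.ndim != 3:
            raise ParameterError("epochs data must be 3-D")
        if self.data.shape[2] != int(round(self.rate * self.epoch_length)):
            raise ParameterError(
                f"samples per epoch {self.data.shape[2]} != rate*length "
                f"{self.rate * self.epoch_length}"
            )
        if np.any(np.diff(self.kept_indices) <= 0):
            raise ParameterError("kept_indices must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None


def _provenance(rec: Recording, op: str, **params) -> dict:
    meta = dict(rec.meta)
    chain = list(meta.get("chain", []))
    chain.append({"op": op, **params})
    meta["chain"] = chain
    return meta


def bandpass(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass.

    ``order`` is the one-way filter order; forward-backward application
    doubles the effective magnitude roll-off.
    """
    nyq = rec.rate / 2.0
    if not 0 < lo < hi:
        raise ParameterError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ParameterError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out, meta=_provenance(rec, "bandpass", lo=lo, hi=hi, order=order))


def notch(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop over ``(lo, hi)`` Hz."""
    nyq = rec.rate / 2.0
    if not 0 < lo < hi or hi >= nyq:
        raise ParameterError(f"notch band ({lo}, {hi}) outside (0, {nyq})")
    sos = sps.butter(order, [lo, hi], btype="bandstop", fs=rec.rate, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out, meta=_provenance(rec, "notch", lo=lo, hi=hi, order=order))


def resample(rec: Recording, new_rate: float = 500.0) -> Recording:
    """Polyphase down-sampling; upsampling is refused (the pipeline never needs it)."""
    if new_rate > rec.rate:
        raise ParameterError(f"upsampling {rec.rate} -> {new_rate} Hz refused")
    if new_rate == rec.rate:
        return rec.copy_with(meta=_provenance(rec, "resample", new_rate=new_rate))
    from fractions import Fraction

    frac = Fraction(new_rate / rec.rate).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(
        data=out, rate=new_rate, meta=_provenance(rec, "resample", new_rate=new_rate)
    )


def rereference(rec: Recording, ref_labels: tuple[str, str] = ("M1", "M2")) -> Recording:
    """Subtract the mastoid mean from every EEG channel; EMG/REF untouched."""
    missing = [l for l in ref_labels if l not in rec.labels]
    if missing:
        raise KeyError(f"reference channels missing: {missing}")
    ref = np.mean([rec.get(l) for l in ref_labels], axis=0)
    out = rec.data.copy()
    for i, kind in enumerate(rec.kinds):
        if kind == "EEG" and rec.labels[i] not in ref_labels:
            out[i] = out[i] - ref
    return rec.copy_with(data=out, meta=_provenance(rec, "rereference", refs=list(ref_labels)))


def epoch(rec: Recording, length: float = 2.0) -> Epochs:
    """Cut into consecutive non-overlapping epochs; trailing remainder dropped."""
    if length <= 0:
        raise ParameterError(f"epoch length must be > 0, got {length}")
    spe = int(round(rec.rate * length))
    n_ep = rec.n_samples // spe
    if n_ep == 0:
        raise PipelineError(
            f"recording of {rec.duration:.2f} s shorter than one {length} s epoch"
        )
    cut = rec.data[:, : n_ep * spe]
    data = cut.reshape(rec.n_channels, n_ep, spe).transpose(1, 0, 2)
    return Epochs(
        data=data.copy(),
        rate=rec.rate,
        epoch_length=length,
        labels=list(rec.labels),
        kinds=list(rec.kinds),
        kept_indices=np.arange(n_ep),
        meta=_provenance(rec, "epoch", length=length),
    )


def reject_epochs(ep: Epochs, abs_uv: float = 150.0, z_max: float = 5.0) -> Epochs:
    """Drop epochs by peak amplitude or per-channel RMS z-score across epochs.

    An epoch is rejected when any EEG/EMG sample exceeds ``abs_uv`` microvolts
    in magnitude, or when any channel's RMS is more than ``z_max`` standard
    deviations from that channel's mean RMS across epochs.
    """
    if ep.n_epochs == 0:
        raise PipelineError("no epochs to vet")
    peaks = np.max(np.abs(ep.data), axis=(1, 2))
    bad = peaks > abs_uv
    rms = np.sqrt(np.mean(ep.data**2, axis=2))  # (epochs, channels)
    mu = rms.mean(axis=0)
    sd = rms.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (rms - mu) / sd, 0.0)
    bad |= np.any(np.abs(z) > z_max, axis=1)
    keep = ~bad
    if not np.any(keep):
        raise PipelineError(
            f"all {ep.n_epochs} epochs rejected (abs_uv={abs_uv}, z_max={z_max}); "
            f"peak amplitudes {peaks.min():.1f}-{peaks.max():.1f} uV"
        )
    meta = dict(ep.meta)
    meta["n_rejected"] = int(bad.sum())
    return Epochs(
        data=ep.data[keep].copy(),
        rate=ep.rate,
        epoch_length=ep.epoch_length,
        labels=list(ep.labels),
        kinds=list(ep.kinds),
        kept_indices=ep.kept_indices[keep],
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Fixed chains
# ---------------------------------------------------------------------------

def preprocess_eeg(
    rec: Recording,
    eeg_band: tuple[float, float] = (1.0, 100.0),
    notch_bands=((48.0, 52.0), (98.0, 102.0)),
    target_rate: float = 500.0,
    ref_labels: tuple[str, str] = ("M1", "M2"),
    epoch_length: float = 2.0,
    reject_abs_uv: float = 150.0,
    reject_z_max: float = 5.0,
    order: int = 4,
) -> Epochs:
    """Full EEG chain: bandpass -> notches -> resample -> rereference -> epoch -> reject."""
    out = bandpass(rec, *eeg_band, order=order)
    for lo, hi in notch_bands:
        out = notch(out, lo, hi, order=order)
    out = resample(out, target_rate)
    out = rereference(out, ref_labels)
    ep = epoch(out, epoch_length)
    return reject_epochs(ep, abs_uv=reject_abs_uv, z_max=reject_z_max)


def preprocess_emg(
    rec: Recording,
    emg_band: tuple[float, float] = (20.0, 150.0),
    target_rate: float = 500.0,
    epoch_length: float = 2.0,
    order: int = 4,
) -> Epochs:
    """EMG chain: 20-150 Hz band-pass applied twice (cascade), resample, epoch.

    The cascade is realized as a single zero-phase pass with doubled order,
    which has the same magnitude response as two identical passes.
    """
    out = bandpass(rec, *emg_band, order=2 * order)
    out = resample(out, target_rate)
    return epoch(out, epoch_length)
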