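"""Phase-locking value (PLV) connectivity between sensorimotor ROIs.

PLV between two band-limited signals is the modulus of the time-averaged unit
phasor of their instantaneous phase difference,

    PLV = | mean_t exp(i (phi_x(t) - phi_y(t))) |  in [0, 1],

with phases from the Hilbert analytic signal.  The 13 regions of interest are
sensorimotor Brodmann areas (BA1,2,3,4,5,6,8 left; BA1,2,4,5,6,8 right --
right BA3 has no entry in the scout template this layout mirrors, so 13 rather
than 14).  Each BA is represented by its nearest 10-10 scalp channels, a
sensor-space proxy for source scouts; the map is data, replaceable via JSON.

Estimation: channels are band-filtered, phases extracted per 2 s epoch, the
PLV computed within each epoch over samples and averaged across epochs (the
epoch-then-average estimator avoids phase discontinuities at epoch seams);
an ROI-pair value is the mean over all cross-ROI channel pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .dataio import DEFAULT_BANDS
from .preprocess import Epochs, ParameterError

#: ROI order used everywhere: 7 left BAs then 6 right BAs (no right BA3).
ROI_NAMES: tuple[str, ...] = (
    "BA1_L", "BA2_L", "BA3_L", "BA4_L", "BA5_L", "BA6_L", "BA8_L",
    "BA1_R", "BA2_R", "BA4_R", "BA5_R", "BA6_R", "BA8_R",
)

#: Default sensor-space proxy: each Brodmann area -> nearest 10-10 channels.
DEFAULT_ROI_MAP: dict[str, tuple[str, ...]] = {
    "BA1_L": ("C3", "CP3"),
    "BA2_L": ("C3", "CP3"),
    "BA3_L": ("C3", "CP3"),
    "BA4_L": ("C3", "C1"),
    "BA5_L": ("CP1", "CPz"),
    "BA6_L": ("FC3", "FCz"),
    "BA8_L": ("F3", "AF3"),
    "BA1_R": ("C4", "CP4"),
    "BA2_R": ("C4", "CP4"),
    "BA4_R": ("C4", "C2"),
    "BA5_R": ("CP2", "CPz"),
    "BA6_R": ("FC4", "FCz"),
    "BA8_R": ("F4", "AF4"),
}

LEFT_ROIS = tuple(r for r in ROI_NAMES if r.endswith("_L"))
RIGHT_ROIS = tuple(r for r in ROI_NAMES if r.endswith("_R"))


class PhaseError(ValueError):
    """Instantaneous phase undefined (constant signal)."""


@dataclass
class RoiMap:
    """Ordered ROI -> channel-labels mapping (13 sensorimotor Brodmann areas)."""

    mapping: dict

    def __post_init__(self) -> None:
        self.mapping = {k: tuple(v) for k, v in self.mapping.items()}
        if list(self.mapping) != list(ROI_NAMES):
            raise ValueError(
                f"ROI map must cover exactly {list(ROI_NAMES)} in order, "
                f"got {list(self.mapping)}"
            )
        for roi, chans in self.mapping.items():
            if len(chans) == 0:
                raise ValueError(f"ROI {roi} maps to no channels")

    @classmethod
    def default(cls) -> "RoiMap":
        return cls(dict(DEFAULT_ROI_MAP))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiMap":
        return cls(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({k: list(v) for k, v in self.mapping.items()}, indent=1))

    @property
    def names(self) -> list[str]:
        return list(self.mapping)

    def channels(self) -> list[str]:
        """All distinct channels used, in first-appearance order."""
        seen: list[str] = []
        for chans in self.mapping.values():
            for c in chans:
                if c not in seen:
                    seen.append(c)
        return seen


def analytic_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) via the Hilbert analytic signal.

    The input is assumed already band-limited; a constant signal has no
    defined phase and is refused.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim < 1 or x.shape[-1] < 2:
        raise PhaseError("need at least 2 samples")
    if np.allclose(x, x[..., :1]):
        raise PhaseError("constant signal has undefined instantaneous phase")
    return np.angle(sps.hilbert(x, axis=-1))


def plv_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLV of two phase series: modulus of the mean unit phasor of their difference."""
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError(f"phase series shapes differ: {phase_x.shape} vs {phase_y.shape}")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


def _band_phases(ep: Epochs, channels: list[str], band: tuple[float, float],
                 order: int = 4) -> np.ndarray:
    """Band-filter the requested channels and return per-epoch phases.

    Returns an array ``(n_epochs, n_channels, n_samples)`` of instantaneous
    phase.  Filtering runs over the whole epoch block per channel.
    """
    lo, hi = band
    nyq = ep.rate / 2.0
    if hi >= nyq:
        raise ParameterError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    idx = [ep.channel_index(c) for c in channels]
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=ep.rate, output="sos")
    filt = sps.sosfiltfilt(sos, ep.data[:, idx, :], axis=2)
    return np.angle(sps.hilbert(filt, axis=2))


def plv_matrix(
    ep: Epochs,
    roi_map: RoiMap | None = None,
    band: tuple[float, float] | str = "alpha",
    order: int = 4,
) -> np.ndarray:
    """Symmetric 13x13 ROI PLV matrix (unit diagonal) for one band.

    Per epoch, PLV is computed over samples for every cross-ROI channel pair;
    pair values are averaged across epochs, then across channel pairs within
    each ROI pair.
    """
    if roi_map is None:
        roi_map = RoiMap.default()
    if isinstance(band, str):
        band = DEFAULT_BANDS[band]
    if ep.n_epochs == 0:
        raise ParameterError("no epochs")

    channels = roi_map.channels()
    phases = _band_phases(ep, channels, band, order=order)  # (E, C, S)
    ch_pos = {c: i for i, c in enumerate(channels)}

    # channel-level PLV for all channel pairs at once:
    # mean over samples of exp(i phi), cross-spectrum style
    z = np.exp(1j * phases)  # (E, C, S)
    n_s = z.shape[2]
    # pairwise mean phasor per epoch: (E, C, C)
    cross = np.einsum("ecs,eds->ecd", z, np.conj(z)) / n_s
    ch_plv = np.abs(cross).mean(axis=0)  # averaged across epochs

    names = roi_map.names
    n = len(names)
    out = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            vals = [
                ch_plv[ch_pos[ca], ch_pos[cb]]
                for ca in roi_map.mapping[names[a]]
                for cb in roi_map.mapping[names[b]]
                if ca != cb
            ]
            if not vals:  # ROIs sharing all channels: perfect locking by construction
                vals = [1.0]
            out[a, b] = out[b, a] = float(np.mean(vals))
    return np.clip(out, 0.0, 1.0)
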