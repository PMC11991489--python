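"""Recordings on disk and run configuration.

The pipeline's raw currency is the :class:`Recording`: a channels x samples
matrix in microvolts with a sampling rate, unique channel labels (10-10 names
for scalp EEG, ``EMG_L``/``EMG_R`` for the bipolar muscle channel, ``M1``/``M2``
for the mastoid references) and per-channel kind tags, plus free-form study
metadata (subject id, sleep condition, motor state).

Two interchange formats are supported:

* **EDF** (European Data Format, 16-bit) -- the universal biosignal exchange
  format.  A minimal single-record-per-second codec is implemented here;
  values survive a round trip to within the 16-bit quantization step of the
  stored physical range.
* **CSV + JSON sidecar** -- human-readable fixtures: channels as rows with a
  header row of labels, and a ``<stem>.json`` sidecar holding
  ``{rate, labels, kinds, meta}``.  Round trips are exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("myocortex")

CHANNEL_KINDS = ("EEG", "EMG", "REF")

#: Conditions and motor states used throughout the study layout.
SLEEP_CONDITIONS = ("good", "poor")
MOTOR_STATES = ("rest", "left_contraction", "right_contraction")


class FormatError(ValueError):
    """Malformed file or header (duplicate labels, bad shapes...)."""


class DataError(ValueError):
    """Non-finite or otherwise unusable sample data."""


@dataclass
class Recording:
    """Multichannel biosignal block in microvolts.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    rate
        Sampling rate in Hz, > 0.
    labels
        Unique channel names, one per row of ``data``.
    kinds
        Per-channel tag in ``{"EEG", "EMG", "REF"}``.
    meta
        Study metadata (subject, condition, state, provenance ...).
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    kinds: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"data must be 2-D (channels x samples), got {self.data.ndim}-D")
        self.labels = list(self.labels)
        self.kinds = list(self.kinds)
        if self.rate <= 0:
            raise FormatError(f"rate must be positive, got {self.rate}")
        n_ch = self.data.shape[0]
        if len(self.labels) != n_ch or len(self.kinds) != n_ch:
            raise FormatError(
                f"channel bookkeeping mismatch: {n_ch} rows, "
                f"{len(self.labels)} labels, {len(self.kinds)} kinds"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate channel labels: {dupes}")
        bad = sorted(set(self.kinds) - set(CHANNEL_KINDS))
        if bad:
            raise FormatError(f"unknown channel kinds: {bad}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains non-finite samples")

    # -- convenience -----------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        return self.data[self.channel_index(label)]

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        idx = [self.channel_index(l) for l in labels]
        return Recording(
            data=self.data[idx].copy(),
            rate=self.rate,
            labels=[self.labels[i] for i in idx],
            kinds=[self.kinds[i] for i in idx],
            meta=dict(self.meta),
        )

    def copy_with(self, data: np.ndarray | None = None, **changes) -> "Recording":
        kw = dict(
            data=self.data.copy() if data is None else data,
            rate=self.rate,
            labels=list(self.labels),
            kinds=list(self.kinds),
            meta=dict(self.meta),
        )
        kw.update(changes)
        return Recording(**kw)


# ---------------------------------------------------------------------------
# EDF codec (16-bit, one data record per second)
# ---------------------------------------------------------------------------

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def edf_quantization_step(physical_min: float, physical_max: float) -> float:
    """Size of one 16-bit step for the stored physical range."""
    return (physical_max - physical_min) / (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN)


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a minimal 16-bit EDF file.

    The sampling rate must be a positive integer (samples per 1 s data
    record).  Trailing samples that do not fill a whole record are zero-padded
    and the true sample count is recorded in the reserved header field so a
    round trip restores the exact length.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9 or rate <= 0:
        raise FormatError(f"EDF writer requires an integer rate, got {rate}")
    spr = int(round(rate))  # samples per record (1 s records)
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / spr))

    # physical range per channel, padded so constant channels stay encodable
    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    span = pmax - pmin
    pad = np.where(span > 0, span * 1e-3, 1.0)
    pmin = pmin - pad
    pmax = pmax + pad

    header = b""
    header += _edf_field("0", 8)  # version
    header += _edf_field("myocortex synthetic subject", 80)
    header += _edf_field("myocortex recording", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 * (1 + n_ch)), 8)
    header += _edf_field(f"nsamples={n_samp}", 44)  # reserved: true length
    header += _edf_field(str(n_rec), 8)
    header += _edf_field("1", 8)  # record duration, s
    header += _edf_field(str(n_ch), 4)

    header += b"".join(_edf_field(l, 16) for l in rec.labels)
    header += b"".join(_edf_field(k, 80) for k in rec.kinds)  # transducer field carries kind
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmin)
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmax)
    header += b"".join(_edf_field(str(_EDF_DIGITAL_MIN), 8) for _ in range(n_ch))
    header += b"".join(_edf_field(str(_EDF_DIGITAL_MAX), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_edf_field(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    # reread the physical bounds exactly as a reader will parse them, so the
    # digitization uses the same gains the decoder applies
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    gain = (pmax_r - pmin_r) / (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN)

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = rec.data
    dig = np.rint((padded - pmin_r[:, None]) / gain[:, None] + _EDF_DIGITAL_MIN)
    dig = np.clip(dig, _EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())

    # JSON sidecar keeps metadata that EDF's fixed header cannot hold
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"meta": rec.meta}, indent=1))
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (or any plain 16-bit EDF)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")

    def fld(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        header_bytes = int(fld(184, 8))
        reserved = fld(192, 44)
        n_rec = int(fld(236, 8))
        rec_dur = float(fld(244, 8))
        n_ch = int(fld(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable EDF header ({exc})") from exc
    if n_ch < 1 or n_rec < 0 or rec_dur <= 0:
        raise FormatError(f"{path}: implausible EDF header")

    off = 256

    def sig_fields(width: int) -> list[str]:
        nonlocal off
        out = [raw[off + i * width : off + (i + 1) * width].decode("ascii", errors="replace").strip()
               for i in range(n_ch)]
        off += n_ch * width
        return out

    labels = sig_fields(16)
    kinds = sig_fields(80)
    sig_fields(8)  # units
    pmin = np.array([float(v) for v in sig_fields(8)])
    pmax = np.array([float(v) for v in sig_fields(8)])
    dmin = np.array([float(v) for v in sig_fields(8)])
    dmax = np.array([float(v) for v in sig_fields(8)])
    sig_fields(80)  # prefiltering
    spr = [int(v) for v in sig_fields(8)]
    sig_fields(32)

    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"{path}: duplicate channel labels {dupes}")
    if len(set(spr)) != 1:
        raise FormatError(f"{path}: per-channel rates differ; unsupported")
    spr0 = spr[0]
    rate = spr0 / rec_dur

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_rec * n_ch * spr0
    if body.size < expected:
        raise FormatError(f"{path}: body too short ({body.size} < {expected} samples)")
    body = body[:expected].reshape(n_rec, n_ch, spr0)
    data = body.transpose(1, 0, 2).reshape(n_ch, n_rec * spr0).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]

    if reserved.startswith("nsamples="):
        true_n = int(reserved.split("=", 1)[1])
        data = data[:, :true_n]

    if not all(k in CHANNEL_KINDS for k in kinds):
        kinds = ["EMG" if l.upper().startswith("EMG") else "EEG" for l in labels]

    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text()).get("meta", {})
    return Recording(data=data, rate=rate, labels=labels, kinds=kinds, meta=meta)


# ---------------------------------------------------------------------------
# CSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_csv(rec: Recording, path: str | Path) -> Path:
    """Write channels-as-rows CSV plus a ``<stem>.json`` sidecar. Exact round trip."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(rec.labels) + "\n")
        for row in rec.data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"rate": rec.rate, "labels": rec.labels, "kinds": rec.kinds, "meta": rec.meta},
            indent=1,
        )
    )
    return path


def read_csv(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar.name}")
    side = json.loads(sidecar.read_text())
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    data = data.T if data.shape[0] != len(header) else data
    # rows in file are written one channel per line; loadtxt keeps that layout
    if header != list(side["labels"]):
        raise FormatError(f"{path}: CSV header disagrees with sidecar labels")
    return Recording(
        data=data,
        rate=float(side["rate"]),
        labels=list(side["labels"]),
        kinds=list(side["kinds"]),
        meta=side.get("meta", {}),
    )


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a Recording from EDF or CSV(+JSON sidecar), inferring by suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or ("edf" if path.suffix.lower() == ".edf" else "csv")).lower()
    if fmt == "edf":
        rec = read_edf(path)
    elif fmt == "csv":
        rec = read_csv(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if rec.n_channels < 2:
        raise FormatError(f"{path}: fewer than 2 channels")
    return rec


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = (format or ("edf" if path.suffix.lower() == ".edf" else "csv")).lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "edf":
        return write_edf(rec, path)
    if fmt == "csv":
        return write_csv(rec, path)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Conventional EEG band partition; the beta edge at 13 Hz anchors delta/theta/alpha.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma1": (30.0, 60.0),
    "gamma2": (60.0, 100.0),
}


@dataclass
class RunConfig:
    """All pipeline knobs, with the study's analysis settings as defaults."""

    bands: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BANDS.items()})
    eeg_band: tuple = (1.0, 100.0)
    emg_band: tuple = (20.0, 150.0)
    notch_bands: tuple = ((48.0, 52.0), (98.0, 102.0))
    filter_order: int = 4
    target_rate: float = 500.0
    reference_labels: tuple = ("M1", "M2")
    epoch_length: float = 2.0
    reject_abs_uv: float = 150.0
    reject_z_max: float = 5.0
    emg_feature_bands: tuple = ((20.0, 100.0), (100.0, 150.0))
    sparsity_min: float = 0.22
    sparsity_max: float = 0.29
    sparsity_step: float = 0.01
    n_random: int = 1000
    n_perm: int = 2000
    edge_alpha: float = 0.05
    comp_alpha: float = 0.05
    fdr_q: float = 0.05
    pdc_variant: str = "H"
    pdc_segment_s: float = 180.0
    pdc_max_order: int = 20
    #: relative white-noise floor added before MVAR fitting; zero-phase
    #: filtering leaves the joint series spectrally hollow, and a small
    #: measurement-noise floor keeps the least-squares fit stable
    pdc_noise_floor: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    def sparsity_levels(self) -> np.ndarray:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return np.round(self.sparsity_min + self.sparsity_step * np.arange(n), 10)

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Per-stage substream of the master seed (stable across runs)."""
        tag = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "big")
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(tag,))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config, filling unset keys with the study defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
    if overrides:
        raw.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise FormatError(f"unknown config keys: {unknown}")
    if "bands" in raw:
        raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
    for key in ("notch_bands", "emg_feature_bands"):
        if key in raw:
            raw[key] = tuple(tuple(b) for b in raw[key])
    for key in ("eeg_band", "emg_band", "reference_labels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def validate_config(cfg: RunConfig, nyquist: float | None = None) -> list[str]:
    """Return a list of human-readable violations (empty when valid)."""
    v: list[str] = []
    if cfg.epoch_length <= 0:
        v.append(f"epoch_length must be > 0, got {cfg.epoch_length}")
    for name, (lo, hi) in cfg.bands.items():
        if lo >= hi:
            v.append(f"band {name!r}: lo {lo} >= hi {hi}")
        if nyquist is not None and hi >= nyquist:
            v.append(f"band {name!r}: hi {hi} >= Nyquist {nyquist}")
    for pair_name, (lo, hi) in (("eeg_band", cfg.eeg_band), ("emg_band", cfg.emg_band)):
        if lo >= hi:
            v.append(f"{pair_name}: lo {lo} >= hi {hi}")
    for lo, hi in cfg.notch_bands:
        if lo >= hi:
            v.append(f"notch band ({lo}, {hi}): lo >= hi")
    for s in (cfg.sparsity_min, cfg.sparsity_max):
        if not 0 < s < 1:
            v.append(f"sparsity {s} outside (0, 1)")
    if cfg.sparsity_step <= 0:
        v.append(f"sparsity_step must be > 0, got {cfg.sparsity_step}")
    if cfg.sparsity_min > cfg.sparsity_max:
        v.append("sparsity_min > sparsity_max")
    for key in ("n_random", "n_perm", "filter_order", "pdc_max_order"):
        if getattr(cfg, key) < 1:
            v.append(f"{key} must be >= 1, got {getattr(cfg, key)}")
    for key in ("edge_alpha", "comp_alpha", "fdr_q"):
        if not 0 < getattr(cfg, key) < 1:
            v.append(f"{key} must lie in (0, 1), got {getattr(cfg, key)}")
    if not 0 <= cfg.pdc_noise_floor < 1:
        v.append(f"pdc_noise_floor must lie in [0, 1), got {cfg.pdc_noise_floor}")
    if cfg.pdc_variant not in ("H", "Abar"):
        v.append(f"pdc_variant must be 'H' or 'Abar', got {cfg.pdc_variant!r}")
    if cfg.target_rate <= 0:
        v.append(f"target_rate must be > 0, got {cfg.target_rate}")
    if cfg.pdc_segment_s <= 0:
        v.append(f"pdc_segment_s must be > 0, got {cfg.pdc_segment_s}")
    return v
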