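"""Synthetic study generator.

No public recordings exist for the study design this pipeline targets, so
every stage is exercised on surrogates with known ground truth:

* :func:`gen_phase_coupled_pair` -- two narrow-band oscillations whose
  instantaneous phase difference is iid von Mises with concentration kappa.
  The population PLV is then the Bessel ratio I1(kappa)/I0(kappa), an exact
  analytic oracle.  Because iid per-sample phase jitter is broadband, Hilbert
  phase extraction cannot recover it exactly; the generator therefore returns
  the ground-truth phase series alongside the signals, and oracle checks
  measure PLV on those phases.
* :func:`gen_mvar_data` -- simulation of a stable MVAR process, the
  well-posed ground truth for MVAR fitting and PDC recovery.
* :func:`gen_emg_surrogate` -- Gaussian noise spectrally shaped inside
  20-150 Hz so its band power centroid (MPF) sits at a requested frequency.
* :func:`gen_study` -- a full mock study: subjects x {good, poor} sleep x
  {rest, left, right contraction}, 28 EEG + 2 mastoid + 1 EMG channels at
  1000 Hz, with three injected condition effects mirroring the contrasts the
  pipeline is meant to detect:

  (i)   reduced interhemispheric alpha PLV (left BA1-4 channels vs right
        BA1,2,4,5 channels) in the sleep-deprived resting state;
  (ii)  a lowered EMG spectral centroid (hence lower high-band MF) for the
        left-biceps contraction after deprivation;
  (iii) increased right-cortex -> left-EMG directed (MVAR) coupling and
        decreased EMG -> contralateral-cortex coupling in the deprived
        left-biceps contraction, concentrated in the gamma1 range (~45 Hz).

  All injected magnitudes are recorded in a :class:`GroundTruth` object.

Interhemispheric PLV is implanted with *slow* (0.5-3 Hz band) Gaussian phase
jitter on an alpha carrier: for Gaussian phase jitter of total variance s2
between two channels, the population PLV is exp(-s2/2), and the jitter is
narrow-band enough for the filter -> Hilbert chain to track it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .dataio import MOTOR_STATES, SLEEP_CONDITIONS, Recording, write_recording
from .pdc_mvar import companion_spectral_radius

EEG_LABELS: tuple[str, ...] = (
    "C3", "C4", "C1", "C2", "CP3", "CP4", "CP1", "CP2", "CPz",
    "FC3", "FC4", "FCz", "F3", "F4", "AF3", "AF4",
    "Fp1", "Fp2", "Fz", "Cz", "Pz", "P3", "P4", "O1", "O2", "T7", "T8", "F7",
)
REF_LABELS: tuple[str, ...] = ("M1", "M2")

#: Channels carrying injected effect (i): left BA1-4 proxies vs right BA1,2,4,5
#: proxies (midline CPz excluded so the jitter stays lateralized).
LEFT_TARGET_CHANNELS = ("C3", "CP3", "C1")
RIGHT_TARGET_CHANNELS = ("C4", "CP4", "C2", "CP2")

#: All channels that receive the shared alpha carrier (the ROI-map channels).
ALPHA_CHANNELS = (
    "C3", "C4", "C1", "C2", "CP3", "CP4", "CP1", "CP2", "CPz",
    "FC3", "FC4", "FCz", "F3", "F4", "AF3", "AF4",
)


class SynthError(ValueError):
    pass


def expected_plv_von_mises(kappa: float) -> float:
    """Population PLV for an iid von Mises phase difference: I1(kappa)/I0(kappa)."""
    from scipy.special import i0e, i1e

    if kappa < 0:
        raise SynthError(f"kappa must be >= 0, got {kappa}")
    return float(i1e(kappa) / i0e(kappa))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                rate: float, std: float) -> np.ndarray:
    """1/f-power noise, per-channel std equal to ``std``."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, f[1] if f.size > 1 else 1.0)), 0.0)
    x = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * std


def _slow_jitter(rng: np.random.Generator, n_samples: int, rate: float,
                 std: float, band=(0.5, 3.0)) -> np.ndarray:
    """Zero-mean Gaussian phase jitter band-limited to ``band`` Hz, std ``std``."""
    if std == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    sos = sps.butter(2, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / x.std() * std


def gen_phase_coupled_pair(
    n_samples: int,
    rate: float = 500.0,
    carrier_f: float = 10.0,
    kappa: float = 2.0,
    seed: int | np.random.SeedSequence | None = 0,
    amplitude: float = 10.0,
    noise_std: float = 0.0,
    return_phases: bool = False,
):
    """Two oscillations with an iid von Mises(0, kappa) phase difference.

    Returns a 2-channel :class:`~myocortex.dataio.Recording`; with
    ``return_phases=True`` also the ground-truth phase arrays ``(phi_x,
    phi_y)`` whose PLV converges to I1(kappa)/I0(kappa).
    """
    if kappa < 0:
        raise SynthError(f"kappa must be >= 0, got {kappa}")
    if carrier_f >= rate / 2:
        raise SynthError(f"carrier {carrier_f} Hz >= Nyquist {rate / 2} Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate
    phi_x = 2 * np.pi * carrier_f * t
    delta = rng.vonmises(0.0, kappa, size=n_samples)
    phi_y = phi_x - delta
    data = np.vstack([amplitude * np.cos(phi_x), amplitude * np.cos(phi_y)])
    if noise_std > 0:
        data = data + rng.standard_normal(data.shape) * noise_std
    rec = Recording(
        data=data, rate=rate, labels=["ch1", "ch2"], kinds=["EEG", "EEG"],
        meta={"kappa": kappa, "carrier_f": carrier_f,
              "expected_plv": expected_plv_von_mises(kappa)},
    )
    if return_phases:
        return rec, (phi_x, np.angle(np.exp(1j * phi_y)))
    return rec


def gen_mvar_data(
    coefs: np.ndarray,
    noise_cov: np.ndarray | None = None,
    n_samples: int = 10_000,
    rate: float = 500.0,
    seed: int | np.random.SeedSequence | None = 0,
    burn_in: int = 1000,
    labels: list | None = None,
) -> Recording:
    """Simulate a stable MVAR process; refuses unstable coefficient sets."""
    coefs = np.asarray(coefs, dtype=float)
    if coefs.ndim == 2:
        coefs = coefs[None, :, :]
    p, n, _ = coefs.shape
    radius = companion_spectral_radius(coefs)
    if radius >= 1.0:
        raise SynthError(
            f"unstable MVAR: companion spectral radius {radius:.4f} >= 1"
        )
    if noise_cov is None:
        noise_cov = np.eye(n)
    noise_cov = np.asarray(noise_cov, dtype=float)
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    e = rng.multivariate_normal(np.zeros(n), noise_cov, size=total).T
    x = np.zeros((n, total))
    for t in range(p, total):
        acc = e[:, t].copy()
        for k in range(p):
            acc += coefs[k] @ x[:, t - k - 1]
        x[:, t] = acc
    if labels is None:
        labels = [f"ch{i + 1}" for i in range(n)]
    return Recording(
        data=x[:, burn_in:], rate=rate, labels=labels, kinds=["EEG"] * n,
        meta={"mvar_order": p, "companion_radius": radius},
    )


def _emg_shape(freqs: np.ndarray, center: float, width: float,
               band: tuple[float, float]) -> np.ndarray:
    a = np.exp(-0.5 * ((freqs - center) / width) ** 2)
    a[(freqs < band[0]) | (freqs > band[1])] = 0.0
    return a


def _solve_emg_center(centroid_f: float, band: tuple[float, float], width: float,
                      rate: float, n: int) -> float:
    """Bisection on the Gaussian center so the truncated-shape power centroid
    lands on ``centroid_f``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)

    def centroid(center: float) -> float:
        p = _emg_shape(freqs, center, width, band) ** 2
        return float(np.sum(freqs * p) / np.sum(p))

    lo, hi = band[0] - 200.0, band[1] + 200.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if centroid(mid) < centroid_f:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_emg_surrogate(
    rate: float = 1000.0,
    duration: float = 10.0,
    band: tuple[float, float] = (20.0, 150.0),
    centroid_f: float = 85.0,
    seed: int | np.random.SeedSequence | None = 0,
    rms_uv: float = 40.0,
    width: float = 30.0,
    label: str = "EMG_L",
) -> Recording:
    """Gaussian noise shaped so the in-band PSD centroid equals ``centroid_f``.

    The shaping amplitude is a Gaussian bump truncated to ``band``, with its
    center solved by bisection so the *population* MPF matches the request;
    a Welch estimate on a few seconds of signal lands within ~2 Hz.
    """
    if not band[0] <= centroid_f <= band[1]:
        raise SynthError(f"centroid {centroid_f} Hz outside band {band}")
    n = int(round(rate * duration))
    rng = np.random.default_rng(seed)
    center = _solve_emg_center(centroid_f, band, width, rate, n)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = _emg_shape(freqs, center, width, band)
    spec = np.fft.rfft(rng.standard_normal(n)) * shape
    x = np.fft.irfft(spec, n=n)
    x = x / np.sqrt(np.mean(x**2)) * rms_uv
    return Recording(
        data=x[None, :], rate=rate, labels=[label], kinds=["EMG"],
        meta={"centroid_f": centroid_f, "band": list(band)},
    )


# ---------------------------------------------------------------------------
# Full mock study
# ---------------------------------------------------------------------------

@dataclass
class StudyEffects:
    """Config-exposed magnitudes of the three injected condition effects.

    Phase-jitter standard deviations are radians; for Gaussian jitter the
    induced pairwise PLV factor is ``exp(-(sd_x^2 + sd_y^2)/2)``.
    """

    #: baseline per-channel slow phase jitter (both conditions, radians)
    base_jitter_sd: float = 0.4
    #: extra jitter on the right-target channels in the deprived resting state
    deprived_rest_jitter_sd: float = 1.0
    #: EMG spectral centroid (Hz): all conditions except the deprived left contraction
    emg_centroid_good: float = 95.0
    #: EMG centroid for the deprived left-biceps contraction (fatigue downshift)
    emg_centroid_poor_left: float = 82.0
    #: between-subject SD of the centroid (Hz)
    emg_centroid_subject_sd: float = 2.0
    #: cortex -> EMG lag-1 MVAR coupling, well-rested / deprived.  The loop
    #: gain (product of the two directions) must stay small for stability of
    #: the near-resonant oscillator pair.
    cortex_to_emg_good: float = 0.02
    cortex_to_emg_poor: float = 0.25
    #: EMG -> contralateral-cortex lag-1 MVAR coupling, well-rested / deprived
    emg_to_cortex_good: float = 0.25
    emg_to_cortex_poor: float = 0.02
    #: gamma1 resonance of the corticomuscular trio (Hz) and pole radius
    trio_resonance_f: float = 45.0
    trio_pole_radius: float = 0.90
    #: amplitude scales (microvolts)
    alpha_amp: float = 20.0
    pink_std: float = 10.0
    mastoid_std: float = 2.0
    trio_cortex_amp: float = 12.0
    trio_emg_amp: float = 25.0
    emg_rms: float = 40.0

    @classmethod
    def zeroed(cls) -> "StudyEffects":
        """No condition differences: the null study for calibration runs."""
        return cls(
            deprived_rest_jitter_sd=0.0,
            emg_centroid_poor_left=95.0,
            cortex_to_emg_poor=0.02,
            emg_to_cortex_poor=0.25,
        )


def _trio_coefs(effects: StudyEffects, rate: float, condition: str, state: str) -> np.ndarray:
    """MVAR(2) coefficients for the (C3, C4, EMG) trio of one recording.

    Channel order: 0 = C3 (left cortex), 1 = C4 (right cortex), 2 = EMG.
    The deprived left contraction raises C4->EMG and lowers EMG->C4.
    """
    r = effects.trio_pole_radius
    a1_diag = 2 * r * np.cos(2 * np.pi * effects.trio_resonance_f / rate)
    a1 = np.diag([a1_diag] * 3)
    a2 = np.diag([-(r**2)] * 3)
    deprived = condition == "poor"
    if state == "left_contraction":
        down = effects.cortex_to_emg_poor if deprived else effects.cortex_to_emg_good
        up = effects.emg_to_cortex_poor if deprived else effects.emg_to_cortex_good
        a1[2, 1] = down  # C4 -> EMG (contralateral drive of the left biceps)
        a1[1, 2] = up    # EMG -> C4 feedback
        a1[2, 0] = 0.05  # small ipsilateral C3 -> EMG
    elif state == "right_contraction":
        a1[2, 0] = effects.cortex_to_emg_good  # C3 -> EMG
        a1[0, 2] = effects.emg_to_cortex_good  # EMG -> C3 feedback
        a1[2, 1] = 0.05  # small ipsilateral C4 -> EMG (no feedback loop)
    return np.stack([a1, a2])


@dataclass
class GroundTruth:
    """Everything that was injected, for parameter-recovery tests."""

    effects: StudyEffects
    trio_coefs: dict = field(default_factory=dict)  # (condition, state) -> (2,3,3) list
    plv_target_pairs: list = field(default_factory=list)
    emg_centroids: dict = field(default_factory=dict)  # (condition, state) -> Hz

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": dataclasses.asdict(self.effects),
            "trio_coefs": {f"{c}/{s}": np.asarray(v).tolist()
                           for (c, s), v in self.trio_coefs.items()},
            "plv_target_pairs": self.plv_target_pairs,
            "emg_centroids": {f"{c}/{s}": v for (c, s), v in self.emg_centroids.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class StudySet:
    """In-memory mock study: (subject, condition, state) -> Recording."""

    recordings: dict
    ground_truth: GroundTruth
    rate: float
    duration_s: float

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.recordings})

    def get(self, subject: str, condition: str, state: str) -> Recording:
        return self.recordings[(subject, condition, state)]

    def write(self, out_dir: str | Path, overwrite: bool = False, fmt: str = "edf") -> Path:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
        for (subj, cond, state), rec in self.recordings.items():
            path = out_dir / subj / cond / f"{state}.{fmt}"
            write_recording(rec, path, format=fmt)
        self.ground_truth.to_json(out_dir / "ground_truth.json")
        return out_dir


def _emg_label_for(state: str) -> str:
    return "EMG_R" if state == "right_contraction" else "EMG_L"


def gen_study(
    n_subjects: int = 35,
    seed: int | np.random.SeedSequence | None = 0,
    effects: StudyEffects | None = None,
    duration_s: float = 180.0,
    rate: float = 1000.0,
    alpha_f: float = 10.0,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> StudySet:
    """Generate the full mock study (optionally also writing it to disk).

    Every recording has 31 channels (28 EEG + M1/M2 + one bipolar EMG) at
    ``rate`` Hz.  Determinism: the same ``seed`` reproduces the dataset
    exactly; per-recording streams are spawned from one SeedSequence.
    """
    if n_subjects < 2:
        raise SynthError("need at least 2 subjects")
    effects = effects if effects is not None else StudyEffects()
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n = int(round(rate * duration_s))
    t = np.arange(n) / rate

    truth = GroundTruth(effects=effects)
    truth.plv_target_pairs = [
        [lc, rc] for lc in LEFT_TARGET_CHANNELS for rc in RIGHT_TARGET_CHANNELS
    ]
    recordings: dict = {}

    subj_seqs = seq.spawn(n_subjects)
    for si in range(n_subjects):
        subj = f"sub-{si + 1:02d}"
        subj_rng = np.random.default_rng(subj_seqs[si])
        subj_alpha_f = alpha_f + subj_rng.uniform(-0.5, 0.5)
        subj_centroid_shift = subj_rng.normal(0.0, effects.emg_centroid_subject_sd)
        rec_seqs = subj_seqs[si].spawn(len(SLEEP_CONDITIONS) * len(MOTOR_STATES))
        for ci, cond in enumerate(SLEEP_CONDITIONS):
            for sti, state in enumerate(MOTOR_STATES):
                rng = np.random.default_rng(rec_seqs[ci * len(MOTOR_STATES) + sti])
                emg_label = _emg_label_for(state)
                labels = list(EEG_LABELS) + list(REF_LABELS) + [emg_label]
                kinds = ["EEG"] * len(EEG_LABELS) + ["REF"] * 2 + ["EMG"]
                data = np.zeros((len(labels), n))

                # --- EEG: pink background everywhere
                data[: len(EEG_LABELS) + 2] = _pink_noise(
                    rng, len(EEG_LABELS) + 2, n, rate,
                    std=effects.pink_std,
                )
                data[len(EEG_LABELS):len(EEG_LABELS) + 2] *= (
                    effects.mastoid_std / effects.pink_std
                )

                # --- shared alpha carrier with per-channel slow jitter
                theta = 2 * np.pi * subj_alpha_f * t
                deprived_rest = cond == "poor" and state == "rest"
                for ch in ALPHA_CHANNELS:
                    idx = labels.index(ch)
                    jit = _slow_jitter(rng, n, rate, effects.base_jitter_sd)
                    if deprived_rest and ch in RIGHT_TARGET_CHANNELS:
                        jit = jit + _slow_jitter(
                            rng, n, rate, effects.deprived_rest_jitter_sd
                        )
                    data[idx] += effects.alpha_amp * np.cos(theta + jit)

                # --- EMG channel: shaped noise with condition-dependent centroid
                poor_left = cond == "poor" and state == "left_contraction"
                base_centroid = (
                    effects.emg_centroid_poor_left if poor_left
                    else effects.emg_centroid_good
                )
                centroid = float(np.clip(base_centroid + subj_centroid_shift, 25.0, 145.0))
                emg = gen_emg_surrogate(
                    rate=rate, duration=duration_s, centroid_f=centroid,
                    seed=rng.integers(2**31), rms_uv=effects.emg_rms, label=emg_label,
                )
                data[-1] = emg.data[0]
                truth.emg_centroids[(cond, state)] = base_centroid

                # --- corticomuscular MVAR trio during contractions
                if state != "rest":
                    coefs = _trio_coefs(effects, rate, cond, state)
                    truth.trio_coefs[(cond, state)] = coefs
                    trio = gen_mvar_data(
                        coefs, n_samples=n, rate=rate,
                        seed=rng.integers(2**31), burn_in=500,
                    ).data
                    trio = trio / trio.std(axis=1, keepdims=True)
                    data[labels.index("C3")] += effects.trio_cortex_amp * trio[0]
                    data[labels.index("C4")] += effects.trio_cortex_amp * trio[1]
                    data[-1] += effects.trio_emg_amp * trio[2]

                recordings[(subj, cond, state)] = Recording(
                    data=data, rate=rate, labels=labels, kinds=kinds,
                    meta={"subject": subj, "condition": cond, "state": state},
                )

    study = StudySet(recordings=recordings, ground_truth=truth,
                     rate=rate, duration_s=duration_s)
    if out_dir is not None:
        study.write(out_dir, overwrite=overwrite)
    return study
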