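"""End-to-end orchestration over a study dataset.

Stages: (simulate) -> preprocess -> emg features -> plv -> graph metrics ->
nbs -> pdc -> contrasts -> report.  Each stage consumes the previous stage's
in-memory product, writes plain CSV/JSON artifacts under the configured
output directory, and emits a :class:`StageReport`.  All randomness derives
from per-stage substreams of the master seed in :class:`RunConfig`.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import graphnet, plv as plv_mod, stats
from . import pdc_mvar as pdc_mod
from .dataio import MOTOR_STATES, SLEEP_CONDITIONS, Recording, RunConfig, read_recording
from .preprocess import preprocess_eeg, preprocess_emg
from .synth import StudySet, _emg_label_for, gen_study


@dataclass
class StageReport:
    stage: str
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    elapsed_s: float = 0.0

    def as_dict(self) -> dict:
        return {
            "stage": self.stage, "inputs": self.inputs, "outputs": self.outputs,
            "parameters": self.parameters, "warnings": self.warnings,
            "elapsed_s": round(self.elapsed_s, 3),
        }


class _Timer:
    def __init__(self, report: StageReport):
        self.report = report

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self.report

    def __exit__(self, *exc):
        self.report.elapsed_s = time.perf_counter() - self.t0
        return False


def load_dataset(dataset_dir: str | Path) -> dict:
    """Read a subject/condition/state tree of recordings."""
    dataset_dir = Path(dataset_dir)
    recs: dict = {}
    subjects = sorted(p.name for p in dataset_dir.iterdir() if p.is_dir())
    if not subjects:
        raise FileNotFoundError(f"no subject directories under {dataset_dir}")
    for subj in subjects:
        for cond in SLEEP_CONDITIONS:
            for state in MOTOR_STATES:
                hits = sorted((dataset_dir / subj / cond).glob(f"{state}.*"))
                hits = [h for h in hits if h.suffix in (".edf", ".csv")]
                if not hits:
                    raise FileNotFoundError(
                        f"missing recording {subj}/{cond}/{state} under {dataset_dir}"
                    )
                recs[(subj, cond, state)] = read_recording(hits[0])
    return recs


def preprocess_stage(recordings: dict, cfg: RunConfig) -> tuple[dict, StageReport]:
    """Split each recording into its EEG and EMG cleaned epoch blocks."""
    rep = StageReport("preprocess", parameters={
        "eeg_band": cfg.eeg_band, "emg_band": cfg.emg_band,
        "notch_bands": cfg.notch_bands, "target_rate": cfg.target_rate,
        "epoch_length": cfg.epoch_length,
    })
    out: dict = {}
    with _Timer(rep):
        for key, rec in recordings.items():
            eeg_labels = [l for l, k in zip(rec.labels, rec.kinds) if k in ("EEG", "REF")]
            emg_labels = [l for l, k in zip(rec.labels, rec.kinds) if k == "EMG"]
            eeg = preprocess_eeg(
                rec.pick(eeg_labels),
                eeg_band=cfg.eeg_band, notch_bands=cfg.notch_bands,
                target_rate=cfg.target_rate, ref_labels=cfg.reference_labels,
                epoch_length=cfg.epoch_length, reject_abs_uv=cfg.reject_abs_uv,
                reject_z_max=cfg.reject_z_max, order=cfg.filter_order,
            )
            emg = None
            if emg_labels:
                emg = preprocess_emg(
                    _pick_single(rec, emg_labels[0]),
                    emg_band=cfg.emg_band, target_rate=cfg.target_rate,
                    epoch_length=cfg.epoch_length, order=cfg.filter_order,
                )
            if eeg.meta.get("n_rejected", 0):
                rep.warnings.append(f"{key}: rejected {eeg.meta['n_rejected']} epochs")
            out[key] = {"eeg": eeg, "emg": emg}
            rep.inputs.append("/".join(key))
    return out, rep


def _pick_single(rec: Recording, label: str) -> Recording:
    i = rec.channel_index(label)
    return Recording(
        data=rec.data[[i]].copy(), rate=rec.rate, labels=[label],
        kinds=[rec.kinds[i]], meta=dict(rec.meta),
    )


def emg_stage(preprocessed: dict, cfg: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, StageReport]:
    rep = StageReport("emg_features", parameters={"bands": cfg.emg_feature_bands})
    frames = []
    with _Timer(rep):
        for key, pair in preprocessed.items():
            if pair["emg"] is None:
                continue
            frames.append(emg_mod.emg_feature_table(pair["emg"], bands=cfg.emg_feature_bands))
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        path = out_dir / "emg_features.csv"
        table.to_csv(path, index=False)
        rep.outputs.append(str(path))
    return table, rep


def plv_stage(preprocessed: dict, cfg: RunConfig, out_dir: Path,
              bands: tuple[str, ...] = ("alpha",)) -> tuple[dict, StageReport]:
    """13x13 PLV matrix per recording per requested band."""
    rep = StageReport("plv", parameters={"bands": bands})
    roi_map = plv_mod.RoiMap.default()
    matrices: dict = {}
    with _Timer(rep):
        mat_dir = out_dir / "plv"
        mat_dir.mkdir(parents=True, exist_ok=True)
        for key, pair in preprocessed.items():
            for band in bands:
                m = plv_mod.plv_matrix(pair["eeg"], roi_map, band=band,
                                       order=cfg.filter_order)
                matrices[key + (band,)] = m
                path = mat_dir / ("_".join(key) + f"_{band}.csv")
                pd.DataFrame(m, index=roi_map.names, columns=roi_map.names).to_csv(path)
        rep.outputs.append(str(mat_dir))
        roi_map.to_json(mat_dir / "roi_map.json")
    return matrices, rep


def graph_stage(matrices: dict, cfg: RunConfig, out_dir: Path,
                n_random: int | None = None) -> tuple[pd.DataFrame, StageReport]:
    n_random = cfg.n_random if n_random is None else n_random
    rep = StageReport("graph_metrics", parameters={
        "sparsity": list(cfg.sparsity_levels()), "n_random": n_random,
    })
    rows = []
    with _Timer(rep):
        seq = cfg.stage_seed("graph")
        children = seq.spawn(len(matrices))
        for (key, child) in zip(sorted(matrices), children):
            *rec_key, band = key
            res = graphnet.metrics_over_sparsity(
                matrices[key], sparsities=cfg.sparsity_levels(),
                n_random=n_random, seed=child,
            )
            for lv in res["levels"]:
                rows.append({"subject": rec_key[0], "condition": rec_key[1],
                             "state": rec_key[2], "band": band, **lv})
            rows.append({"subject": rec_key[0], "condition": rec_key[1],
                         "state": rec_key[2], "band": band, "sparsity": "mean",
                         **res["aggregate"]})
        table = pd.DataFrame(rows)
        path = out_dir / "graph_metrics.csv"
        table.to_csv(path, index=False)
        rep.outputs.append(str(path))
    return table, rep


def nbs_stage(matrices: dict, cfg: RunConfig, out_dir: Path,
              band: str = "alpha") -> tuple[dict, StageReport]:
    """Deprived vs well-rested NBS per motor state on the given band."""
    rep = StageReport("nbs", parameters={
        "n_perm": cfg.n_perm, "edge_alpha": cfg.edge_alpha,
        "comp_alpha": cfg.comp_alpha, "band": band,
    })
    results: dict = {}
    roi_names = list(plv_mod.ROI_NAMES)
    with _Timer(rep):
        subjects = sorted({k[0] for k in matrices if k[3] == band})
        seq = cfg.stage_seed("nbs")
        children = seq.spawn(len(MOTOR_STATES))
        payload = {}
        for state, child in zip(MOTOR_STATES, children):
            stack_poor = np.stack([matrices[(s, "poor", state, band)] for s in subjects])
            stack_good = np.stack([matrices[(s, "good", state, band)] for s in subjects])
            res = stats.nbs_paired(
                stack_poor, stack_good, edge_alpha=cfg.edge_alpha,
                comp_alpha=cfg.comp_alpha, n_perm=cfg.n_perm, seed=child,
            )
            results[state] = res
            payload[state] = {
                "components": [
                    {"edges": [[roi_names[i], roi_names[j]] for i, j in comp],
                     "size": len(comp), "p": float(p)}
                    for comp, p in zip(res.components, res.component_p)
                ],
                "n_perm": res.n_perm,
            }
        path = out_dir / f"nbs_{band}.json"
        path.write_text(json.dumps(payload, indent=1))
        rep.outputs.append(str(path))
    return results, rep


def pdc_stage(recordings: dict, cfg: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, StageReport]:
    """Fit the (C3, C4, EMG) MVAR per subject x condition x contraction state
    and average PDC within beta/gamma1/gamma2."""
    rep = StageReport("pdc", parameters={
        "variant": cfg.pdc_variant, "segment_s": cfg.pdc_segment_s,
        "max_order": cfg.pdc_max_order,
    })
    rows = []
    with _Timer(rep):
        freqs = np.arange(1.0, 100.5, 0.5)
        rng = np.random.default_rng(cfg.stage_seed("pdcn"))
        for (subj, cond, state), rec in sorted(recordings.items()):
            if state == "rest":
                continue
            emg_label = _emg_label_for(state)
            if emg_label not in rec.labels:
                continue
            joint = _joint_continuous(rec, cfg, emg_label)
            n_seg = int(round(cfg.pdc_segment_s * cfg.target_rate))
            seg = joint[:, :n_seg] if joint.shape[1] >= n_seg else joint
            if cfg.pdc_noise_floor > 0:
                seg = seg + rng.standard_normal(seg.shape) * (
                    seg.std(axis=1, keepdims=True) * cfg.pdc_noise_floor
                )
            model = pdc_mod.fit_mvar(seg, rate=cfg.target_rate,
                                     max_order=cfg.pdc_max_order,
                                     labels=["C3", "C4", "EMG"])
            if not model.stable:
                rep.warnings.append(f"{subj}/{cond}/{state}: unstable MVAR fit")
                continue
            spec = pdc_mod.pdc(model, freqs, variant=cfg.pdc_variant)
            for band_name, band in pdc_mod.CONTRAST_BANDS.items():
                bp = pdc_mod.band_pdc(spec, band)
                for src, tgt in pdc_mod.CONTRAST_PAIRS:
                    si = ["C3", "C4", "EMG"].index(src)
                    ti = ["C3", "C4", "EMG"].index(tgt)
                    rows.append({
                        "subject": subj, "condition": cond, "state": state,
                        "source": src, "target": tgt, "band": band_name,
                        "value": float(bp[ti, si]),
                    })
        table = pd.DataFrame(rows)
        path = out_dir / "pdc_band_values.csv"
        table.to_csv(path, index=False)
        rep.outputs.append(str(path))
    return table, rep


def _joint_continuous(rec: Recording, cfg: RunConfig, emg_label: str) -> np.ndarray:
    """Continuous cleaned (C3, C4, EMG) block at the target rate (no epoching)."""
    from .preprocess import bandpass, notch, rereference, resample

    eeg_labels = [l for l, k in zip(rec.labels, rec.kinds) if k in ("EEG", "REF")]
    eeg = bandpass(rec.pick(eeg_labels), *cfg.eeg_band, order=cfg.filter_order)
    for lo, hi in cfg.notch_bands:
        eeg = notch(eeg, lo, hi, order=cfg.filter_order)
    eeg = resample(eeg, cfg.target_rate)
    eeg = rereference(eeg, cfg.reference_labels)
    emg = bandpass(_pick_single(rec, emg_label), *cfg.emg_band, order=2 * cfg.filter_order)
    emg = resample(emg, cfg.target_rate)
    n = min(eeg.n_samples, emg.n_samples)
    return np.vstack([eeg.get("C3")[:n], eeg.get("C4")[:n], emg.data[0, :n]])


def contrast_stage(pdc_table: pd.DataFrame, cfg: RunConfig, out_dir: Path,
                   state: str = "left_contraction") -> tuple[pd.DataFrame, StageReport]:
    """Deprived-vs-rested paired contrast of band PDC (BH-FDR over the family)."""
    rep = StageReport("pdc_contrast", parameters={"q": cfg.fdr_q, "state": state})
    with _Timer(rep):
        sel = pdc_table[pdc_table.state == state]
        poor = sel[sel.condition == "poor"]
        good = sel[sel.condition == "good"]
        # subjects must be matched; drop any with a failed fit in one condition
        common = sorted(set(poor.subject) & set(good.subject))
        dropped = sorted((set(poor.subject) | set(good.subject)) - set(common))
        if dropped:
            rep.warnings.append(f"unmatched subjects dropped: {dropped}")
        table = pdc_mod.pdc_contrast(
            poor[poor.subject.isin(common)], good[good.subject.isin(common)],
            q=cfg.fdr_q,
        )
        path = out_dir / f"pdc_contrast_{state}.csv"
        table.to_csv(path, index=False)
        rep.outputs.append(str(path))
    return table, rep


def run_all(
    cfg: RunConfig,
    dataset_dir: str | Path | None = None,
    study: StudySet | None = None,
    simulate: dict | None = None,
    plv_bands: tuple[str, ...] = ("alpha",),
    graph_n_random: int | None = None,
) -> dict:
    """Execute the full pipeline; returns the summary (also written as JSON).

    Exactly one data source must be given: an on-disk ``dataset_dir``, an
    in-memory ``study``, or ``simulate`` (kwargs for :func:`gen_study`).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: list[StageReport] = []

    if sum(x is not None for x in (dataset_dir, study, simulate)) != 1:
        raise ValueError("provide exactly one of dataset_dir, study, simulate")
    if simulate is not None:
        rep = StageReport("simulate", parameters=dict(simulate))
        with _Timer(rep):
            simulate.setdefault("seed", cfg.seed)
            study = gen_study(**simulate)
        reports.append(rep)
        recordings = study.recordings
    elif study is not None:
        recordings = study.recordings
    else:
        recordings = load_dataset(dataset_dir)

    preprocessed, rep = preprocess_stage(recordings, cfg)
    reports.append(rep)
    emg_table, rep = emg_stage(preprocessed, cfg, out_dir)
    reports.append(rep)
    matrices, rep = plv_stage(preprocessed, cfg, out_dir, bands=plv_bands)
    reports.append(rep)
    graph_table, rep = graph_stage(matrices, cfg, out_dir, n_random=graph_n_random)
    reports.append(rep)
    nbs_results, rep = nbs_stage(matrices, cfg, out_dir, band=plv_bands[0])
    reports.append(rep)
    pdc_table, rep = pdc_stage(recordings, cfg, out_dir)
    reports.append(rep)
    contrasts, rep = contrast_stage(pdc_table, cfg, out_dir)
    reports.append(rep)

    summary = {
        "n_recordings": len(recordings),
        "stages": [r.as_dict() for r in reports],
        "nbs_significant": {
            state: [len(c) for c in res.significant_components()]
            for state, res in nbs_results.items()
        },
        "pdc_significant": contrasts[contrasts.significant][
            ["source", "target", "band", "direction"]
        ].to_dict("records"),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return {
        "summary": summary, "emg_table": emg_table, "matrices": matrices,
        "graph_table": graph_table, "nbs": nbs_results, "pdc_table": pdc_table,
        "contrasts": contrasts, "reports": reports,
    }
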