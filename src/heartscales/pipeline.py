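"""End-to-end orchestration: simulate -> preprocess -> ACW/HEP -> cluster ->
metrics -> inference, from a single JSON-round-trippable config.

Each stage writes its outputs under the run directory and a provenance
record (parameters, seeds, package versions, output hashes) is written at
the end.  Re-running with an identical config reproduces identical numeric
outputs; per-stage seeds are derived deterministically from the master
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acw import ChannelScalarMap, heartbeat_acw, maps_to_matrix
from .behav import group_table, hrv_metrics, mean_distance_index
from .cluster import build_adjacency, permutation_cluster_test
from .hep import extract_hep_epochs, hep_modulation, reject_artifact_trials
from .inference import behavioural_regression
from .io import (ConfigError, bandpass_resample, detect_rpeaks,
                 read_events_tsv, read_recording, rereference_average,
                 write_events_tsv, write_recording)
from .montage import read_montage_tsv
from .synth import CohortSpec, write_cohort

__all__ = ["RunConfig", "run_pipeline"]

_STAGE_SEEDS = {"simulate": 101, "cluster": 505, "infer": 707}


@dataclass
class RunConfig:
    """Parameters of one pipeline run (JSON round-trippable)."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    input_dir: str | None = None  # used when simulate=False
    ecg_channel: str = "ECG"
    filter_low: float = 0.5
    filter_high: float = 30.0
    fs_out: float = 256.0
    acw_window: float = 3.0
    hep_reject_z: float = 2.5
    hep_window: tuple = (0.200, 0.500)
    cluster_alpha: float = 0.025
    cluster_min_size: int = 5
    n_perm: int = 5000
    outcomes: tuple = ("mmse", "ifs", "minisea_total", "minisea_emotion")
    bootstrap_B: int = 5000
    stages: tuple = ("simulate", "preprocess", "acw", "hep", "cluster",
                     "metrics", "infer")

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 1009 + _STAGE_SEEDS.get(stage, 1)) & 0x7FFFFFFF

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        cfg = cls(**d)
        for key in ("hep_window", "outcomes", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)

    spec = CohortSpec(**{"seed": config.stage_seed("simulate"),
                         **config.cohort})
    if "simulate" in stages and config.simulate:
        sim_dir = out / "sim"
        write_cohort(spec, sim_dir)
        data_dir = sim_dir
    else:
        if not config.input_dir:
            raise ConfigError("input_dir required when simulation is off")
        data_dir = Path(config.input_dir)
        if not (data_dir / "manifest.json").exists():
            raise ConfigError(f"no manifest.json in {data_dir}")
    manifest = json.loads((data_dir / "manifest.json").read_text())
    mont_labels, mont_pos = read_montage_tsv(data_dir / "montage.tsv")

    # ----- preprocess ------------------------------------------------------
    clean_dir = out / "clean"
    if "preprocess" in stages:
        clean_dir.mkdir(exist_ok=True)
        for entry in manifest["recordings"]:
            rec = read_recording(data_dir / entry["raw"],
                                 subject=entry["subject"],
                                 condition=entry["condition"])
            if config.ecg_channel not in rec.labels:
                raise ConfigError(
                    f"ECG channel {config.ecg_channel!r} not found in "
                    f"{entry['raw']} (channels: {rec.labels[:4]}...)")
            ecg_trace = rec.get_channel(config.ecg_channel)
            rpeaks = detect_rpeaks(ecg_trace, rec.fs)
            eeg_idx = [i for i, lab in enumerate(rec.labels)
                       if lab != config.ecg_channel]
            from .io import Recording
            eeg = Recording(
                data=rec.data[eeg_idx], fs=rec.fs,
                labels=[rec.labels[i] for i in eeg_idx],
                positions=None if rec.positions is None
                else rec.positions[eeg_idx],
                subject=rec.subject, condition=rec.condition,
                block_bounds=rec.block_bounds)
            eeg = bandpass_resample(eeg, config.filter_low,
                                    config.filter_high, config.fs_out)
            eeg = rereference_average(eeg)
            stem = f"{entry['subject']}_{entry['condition']}"
            write_recording(eeg, clean_dir / f"{stem}_clean.fif")
            trains = {"rpeak_detected": rpeaks}
            ev_path = data_dir / entry["events"]
            if ev_path.exists():
                trains.update(read_events_tsv(ev_path))
            write_events_tsv(clean_dir / f"{stem}_events.tsv", trains)

    def _clean(entry):
        stem = f"{entry['subject']}_{entry['condition']}"
        rec = read_recording(clean_dir / f"{stem}_clean.fif",
                             subject=entry["subject"],
                             condition=entry["condition"])
        trains = read_events_tsv(clean_dir / f"{stem}_events.tsv")
        return rec, trains

    # ----- ACW maps --------------------------------------------------------
    if "acw" in stages:
        maps = []
        for entry in manifest["recordings"]:
            rec, trains = _clean(entry)
            rp = trains["rpeak_detected"]
            maps.append(heartbeat_acw(rec, rp, window=config.acw_window))
        ChannelScalarMap.concat_frames(maps).to_csv(
            out / "acw_maps.csv", index=False)

    # ----- HEP -------------------------------------------------------------
    if "hep" in stages:
        rows = []
        for entry in manifest["recordings"]:
            rec, trains = _clean(entry)
            ep = extract_hep_epochs(rec, trains["rpeak_detected"])
            ep = reject_artifact_trials(ep, z=config.hep_reject_z)
            rows.append({
                "subject": entry["subject"],
                "condition": entry["condition"],
                "hep_modulation_uV": hep_modulation(
                    ep, window=tuple(config.hep_window)),
                "n_kept": ep.n_kept,
                "n_rejected": ep.n_epochs - ep.n_kept,
            })
        pd.DataFrame(rows).to_csv(out / "hep_summary.csv", index=False)

    # ----- cluster contrasts ----------------------------------------------
    behav = pd.read_csv(data_dir / "behaviour.csv")
    control = behav["diagnosis"].iloc[0] if "diagnosis" in behav else None
    groups = list(dict.fromkeys(behav["diagnosis"]))
    cluster_members: dict[str, list[str]] = {}
    if "cluster" in stages:
        acw_df = pd.read_csv(out / "acw_maps.csv")
        eeg_labels = [lab for lab in mont_labels if lab != config.ecg_channel]
        adj = build_adjacency(
            np.array([mont_pos[mont_labels.index(l)] for l in eeg_labels]),
            eeg_labels)
        report = {}
        for patient in groups[1:]:
            for condition in sorted(acw_df["condition"].unique()):
                sub_df = acw_df[acw_df["condition"] == condition]
                mats = {}
                for g in (patient, groups[0]):
                    subs = behav.loc[behav["diagnosis"] == g, "subject"]
                    mlist = []
                    for s in subs:
                        block = sub_df[sub_df["subject"] == s]
                        if block.empty:
                            continue
                        block = block.set_index("channel")
                        mlist.append(ChannelScalarMap(
                            labels=eeg_labels,
                            values=block.loc[eeg_labels, "acw50_s"]
                            .to_numpy(float),
                            subject=s, condition=condition))
                    mats[g], _ = maps_to_matrix(mlist, eeg_labels)
                res = permutation_cluster_test(
                    mats[patient], mats[groups[0]], adj,
                    n_perm=config.n_perm,
                    seed=config.stage_seed("cluster"),
                    alpha=config.cluster_alpha,
                    min_size=config.cluster_min_size)
                key = f"{patient}_vs_{groups[0]}/{condition}"
                report[key] = [c.to_dict() for c in res]
                sig = [c for c in res if c.significant]
                if condition == "interoception" and sig:
                    cluster_members[patient] = sig[0].members
        (out / "clusters.json").write_text(json.dumps(report, indent=1))

    # ----- behavioural / physiological metrics -----------------------------
    if "metrics" in stages:
        rows = []
        for entry in manifest["recordings"]:
            if entry["condition"] != "interoception":
                continue
            _, trains = _clean(entry)
            rp = trains["rpeak_detected"]
            rr_mean, sdnn = hrv_metrics(rp)
            row = {"subject": entry["subject"], "rr_mean_ms": rr_mean,
                   "sdnn_ms": sdnn}
            if "tap" in trains and len(trains["tap"]) >= 3:
                row["mdi"] = mean_distance_index(trains["tap"], rp)
            rows.append(row)
        metrics = pd.DataFrame(rows)
        subjects = behav.merge(metrics, on="subject", how="left")

        acw_path = out / "acw_maps.csv"
        if acw_path.exists():
            acw_df = pd.read_csv(acw_path)
            inter = acw_df[acw_df["condition"] == "interoception"]
            means = []
            for patient in groups[1:]:
                members = cluster_members.get(patient)
                sel = inter if members is None else \
                    inter[inter["channel"].isin(members)]
                cm = sel.groupby("subject")["acw50_s"].mean() \
                    .rename(f"acw_cluster_mean")
                means.append(cm)
            if means:
                cm = means[0]
                subjects = subjects.merge(cm, on="subject", how="left")
        hep_path = out / "hep_summary.csv"
        if hep_path.exists():
            hep_df = pd.read_csv(hep_path)
            hep_int = hep_df[hep_df["condition"] == "interoception"][
                ["subject", "hep_modulation_uV"]].rename(
                columns={"hep_modulation_uV": "hep_modulation"})
            subjects = subjects.merge(hep_int, on="subject", how="left")
        subjects.to_csv(out / "subjects.csv", index=False)
        numeric = [c for c in ("age", "education", "mmse", "ifs",
                               "minisea_total", "minisea_emotion",
                               "minisea_fauxpas", "mdi", "rr_mean_ms",
                               "sdnn_ms") if c in subjects.columns]
        tabs = []
        for patient in groups[1:]:
            t = group_table(subjects, "diagnosis", groups[0], patient,
                            numeric)
            t.insert(0, "contrast", f"{patient}_vs_{groups[0]}")
            tabs.append(t)
        pd.concat(tabs, ignore_index=True).to_csv(
            out / "group_stats.csv", index=False)

    # ----- inference -------------------------------------------------------
    if "infer" in stages:
        subjects = pd.read_csv(out / "subjects.csv")
        frames = []
        for patient in groups[1:]:
            tandem = subjects[subjects["diagnosis"].isin(
                [groups[0], patient])].copy()
            preds = [c for c in ("diagnosis", "acw_cluster_mean", "age",
                                 "sex", "education", "site")
                     if c in tandem.columns and tandem[c].notna().any()]
            for outcome in config.outcomes:
                if outcome not in tandem.columns:
                    continue
                fit = behavioural_regression(
                    tandem, outcome, predictors=preds,
                    B=config.bootstrap_B, seed=config.stage_seed("infer"))
                df = fit.to_frame().reset_index(names="predictor")
                df.insert(0, "contrast", f"{patient}_vs_{groups[0]}")
                df["model_F"] = fit.f_stat
                df["model_p"] = fit.f_p
                df["r2"] = fit.r2
                df["n"] = fit.n
                frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "regressions.csv", index=False)

    # ----- provenance ------------------------------------------------------
    prov = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
            if p.name != "provenance.json"
        },
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    return out
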