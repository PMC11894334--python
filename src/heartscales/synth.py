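"""Synthetic cohorts with known ground truth.

Every downstream stage of the package is testable without real patient data:
this module generates multichannel EEG with controllable intrinsic
timescales, ECG with a known R-peak train, keyboard-tap trains with
controllable accuracy, and a behavioural table with group effects and
missingness.

Signal model
------------
Each EEG channel is an Ornstein-Uhlenbeck (OU) process with timescale
``tau(channel, group, condition)`` plus additive white measurement noise at a
stated SNR.  The OU autocorrelation is ``exp(-lag/tau)``, so the
continuous-limit ACW-50 has the closed form ``tau * ln 2`` - an analytic
oracle for the timescale estimators.  A patient-group effect is injected by
adding ``tau_effect`` on a chosen electrode set during the interoception
condition only, mimicking a spatially localised slowing of dynamics.

RR intervals are i.i.d. Gaussian (mean ``60/mean_hr`` s, SD ``sdnn``)
truncated at 0.3 s; SDNN is the only heart-rate-variability quantity used
downstream, so no autonomic spectral structure is modelled.

All generators are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import ConfigError, EventTrain, Recording, write_events_tsv, write_recording
from .montage import biosemi_montage, write_montage_tsv

__all__ = [
    "CohortSpec",
    "subject_ids",
    "simulate_eeg",
    "simulate_ecg",
    "simulate_taps",
    "simulate_behavioural_table",
    "simulate_acw_maps",
    "write_cohort",
    "SCORE_RANGES",
    "REFERENCE_SCORES",
]

# score name -> (min, max) of the scale
SCORE_RANGES = {
    "mmse": (0.0, 30.0),
    "ifs": (0.0, 30.0),
    "minisea_emotion": (0.0, 15.0),
    "minisea_fauxpas": (0.0, 15.0),
}

# healthy-control score means and SDs the behavioural generator is centred
# on (typical values for elderly dementia-study control cohorts)
REFERENCE_SCORES = {
    "mmse": (28.0, 1.2),
    "ifs": (22.5, 3.5),
    "minisea_emotion": (12.0, 1.5),
    "minisea_fauxpas": (13.0, 1.9),
}

_DEFAULT_BEHAV_EFFECTS = {
    "mmse": -2.8,
    "ifs": -4.9,
    "minisea_emotion": -1.6,
    "minisea_fauxpas": -1.5,
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    The defaults emulate the study conditions the package targets: two
    groups (healthy controls vs one patient group), two task conditions of
    two 2-minute blocks each, 128-channel EEG at 256 Hz, a background OU
    timescale of 50 ms with a 50 ms patient slowing on a parietal electrode
    patch during interoception, ~70 bpm heart rate with 50 ms SDNN, and
    Table-1-like behavioural scores with mild missingness.
    """

    n_per_group: int = 20
    groups: tuple[str, ...] = ("HC", "bvFTD")
    conditions: tuple[str, ...] = ("interoception", "exteroception")
    n_channels: int = 128
    fs: float = 256.0
    block_duration: float = 120.0
    n_blocks: int = 2
    tau_background: float = 0.05
    tau_effect: float = 0.05
    effect_electrodes: tuple[str, ...] = ()
    channel_tau_jitter: float = 0.10
    subject_tau_jitter: float = 0.10
    snr_db: float = 20.0
    eeg_rms_uv: float = 20.0
    mean_hr: float = 70.0
    sdnn: float = 0.05
    tap_noise: float = 0.15
    tap_latency: float = 0.2
    tap_miss_rate: float = 0.1
    behav_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_BEHAV_EFFECTS))
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if len(self.groups) < 2:
            raise ConfigError("need a control group and >= 1 patient group")
        if not 30 <= self.mean_hr <= 180:
            raise ConfigError("mean_hr must be in [30, 180] bpm")
        if self.sdnn < 0:
            raise ConfigError("sdnn must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0 <= self.tap_miss_rate < 1:
            raise ConfigError("tap_miss_rate must be in [0, 1)")
        if self.fs <= 2 * 30.0:
            raise ConfigError("fs must exceed twice the upper filter edge")
        labels, pos = biosemi_montage(self.n_channels)
        self._labels = labels
        self._positions = pos
        if not self.effect_electrodes:
            # default patch: the 8 electrodes nearest the cap centroid-most
            # parietal sensor (first label), guaranteed inside the montage
            from .montage import great_circle_distance

            d = great_circle_distance(pos)[0]
            patch = np.argsort(d)[:8]
            self.effect_electrodes = tuple(labels[i] for i in patch)
        missing = set(self.effect_electrodes) - set(labels)
        if missing:
            raise ConfigError(
                f"effect electrodes not in montage: {sorted(missing)}")
        for score, shift in self.behav_effects.items():
            if score not in SCORE_RANGES:
                raise ConfigError(f"unknown behavioural score {score!r}")
            lo, hi = SCORE_RANGES[score]
            mean = REFERENCE_SCORES[score][0] + shift
            if not lo <= mean <= hi:
                raise ConfigError(
                    f"behavioural effect for {score!r} pushes the group mean "
                    f"({mean:.1f}) outside [{lo}, {hi}]")

    # -- identity helpers ---------------------------------------------------
    @property
    def montage(self) -> tuple[list[str], np.ndarray]:
        return self._labels, self._positions

    @property
    def duration(self) -> float:
        return self.n_blocks * self.block_duration

    def subject_group(self, subject: str) -> str:
        for g in self.groups:
            if subject.startswith(f"sub-{g}-"):
                return g
        raise ConfigError(f"unknown subject {subject!r}")

    def _subject_index(self, subject: str) -> int:
        g = self.subject_group(subject)
        i = int(subject.rsplit("-", 1)[1])
        if not 0 <= i < self.n_per_group:
            raise ConfigError(f"unknown subject {subject!r}")
        return list(self.groups).index(g) * self.n_per_group + i

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic per-stream generator derived from the spec seed."""
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, *stream])


def subject_ids(spec: CohortSpec) -> list[str]:
    return [
        f"sub-{g}-{i:02d}" for g in spec.groups for i in range(spec.n_per_group)
    ]


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _ou_ar1(rng: np.random.Generator, phi: np.ndarray, n: int) -> np.ndarray:
    """Stationary unit-variance AR(1) rows with per-row coefficient phi."""
    m = phi.size
    eps = rng.standard_normal((m, n))
    out = np.empty((m, n))
    x0 = rng.standard_normal(m)  # stationary start
    innov_sd = np.sqrt(1.0 - phi ** 2)
    for j in range(m):
        out[j] = signal.lfilter(
            [innov_sd[j]], [1.0, -phi[j]], eps[j],
            zi=np.array([phi[j] * x0[j]]))[0]
    return out


def channel_tau(spec: CohortSpec, subject: str, condition: str) -> np.ndarray:
    """Ground-truth OU timescale per channel for one subject x condition."""
    if condition not in spec.conditions:
        raise ConfigError(f"unknown condition {condition!r}")
    group = spec.subject_group(subject)
    labels, _ = spec.montage
    # per-channel heterogeneity: fixed across subjects (a scalp map),
    # deterministic in the spec seed
    rng_ch = spec.rng(11)
    ch_factor = np.exp(rng_ch.normal(0.0, spec.channel_tau_jitter,
                                     len(labels)))
    rng_sub = spec.rng(12, spec._subject_index(subject))
    sub_factor = float(np.exp(rng_sub.normal(0.0, spec.subject_tau_jitter)))
    tau = spec.tau_background * ch_factor * sub_factor
    if group != spec.groups[0] and condition == "interoception":
        idx = [labels.index(ch) for ch in spec.effect_electrodes]
        tau[idx] = tau[idx] + spec.tau_effect
    return tau


def simulate_eeg(spec: CohortSpec, subject: str, condition: str) -> Recording:
    """Simulate one subject x condition multichannel EEG recording.

    Channels are OU processes with ground-truth timescales from
    :func:`channel_tau` plus white measurement noise at ``spec.snr_db``.
    Duration is ``n_blocks * block_duration``; block starts are recorded in
    ``Recording.block_bounds``.
    """
    tau = channel_tau(spec, subject, condition)
    labels, pos = spec.montage
    n = int(round(spec.duration * spec.fs))
    phi = np.exp(-1.0 / (spec.fs * tau))
    rng = spec.rng(
        13, spec._subject_index(subject), list(spec.conditions).index(condition))
    x = _ou_ar1(rng, phi, n) * spec.eeg_rms_uv
    noise_sd = spec.eeg_rms_uv * 10 ** (-spec.snr_db / 20.0)
    x += rng.normal(0.0, noise_sd, x.shape)
    bounds = [i * spec.block_duration for i in range(spec.n_blocks)]
    return Recording(
        data=x, fs=spec.fs, labels=list(labels), positions=pos.copy(),
        subject=subject, condition=condition, block_bounds=bounds)


# ---------------------------------------------------------------------------
# ECG and taps
# ---------------------------------------------------------------------------

def _qrs_template(t: np.ndarray) -> np.ndarray:
    """PQRST-like waveform (microvolts) centred on the R peak at t=0."""

    def g(mu, sd, amp):
        return amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)

    return (
        g(-0.20, 0.040, 80.0)     # P
        + g(-0.030, 0.010, -150.0)  # Q
        + g(0.0, 0.012, 1000.0)     # R
        + g(0.030, 0.010, -200.0)   # S
        + g(0.25, 0.060, 200.0)     # T
    )


def simulate_ecg(spec: CohortSpec, subject: str,
                 duration: float | None = None
                 ) -> tuple[Recording, EventTrain]:
    """Simulate a single-channel ECG and return it with the true R-peak train.

    RR intervals are i.i.d. Gaussian(60/mean_hr, sdnn) truncated below at
    0.3 s; the waveform is a PQRST template train plus baseline wander and
    white noise.  The truth train enables oracle tests of R-peak detection.
    """
    if duration is None:
        duration = spec.duration
    rng = spec.rng(21, spec._subject_index(subject))
    mean_rr = 60.0 / spec.mean_hr
    beats = [0.5 * mean_rr]
    while beats[-1] < duration:
        rr = max(0.3, mean_rr + (rng.normal(0.0, spec.sdnn) if spec.sdnn > 0
                                 else 0.0))
        beats.append(beats[-1] + rr)
    truth = np.array([b for b in beats if b < duration])

    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs
    wave = np.zeros(n)
    half = 0.45  # template support (s) either side of the R peak
    for b in truth:
        lo = max(0, int((b - half) * spec.fs))
        hi = min(n, int((b + half) * spec.fs) + 1)
        wave[lo:hi] += _qrs_template(t[lo:hi] - b)
    wave += 50.0 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    wave += rng.normal(0.0, 10.0, n)
    rec = Recording(
        data=wave[None, :], fs=spec.fs, labels=["ECG"],
        positions=np.full((1, 3), np.nan), subject=subject,
        condition="ecg",
        block_bounds=[i * spec.block_duration for i in range(spec.n_blocks)])
    return rec, EventTrain(truth, kind="rpeak")


def simulate_taps(truth_beats: EventTrain, tap_noise: float,
                  miss_rate: float, seed, latency: float = 0.2
                  ) -> EventTrain:
    """Simulate keyboard taps locked to heartbeats.

    Each retained beat (misses are Bernoulli ``miss_rate``) emits one tap at
    ``beat + latency + N(0, tap_noise)``.  The output is sorted and made
    strictly increasing by dropping jittered collisions.
    """
    if not 0 <= miss_rate < 1:
        raise ConfigError("miss_rate must be in [0, 1)")
    if tap_noise < 0:
        raise ConfigError("tap_noise must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    beats = truth_beats.times
    keep = rng.random(beats.size) >= miss_rate
    taps = beats[keep] + latency
    if tap_noise > 0:
        taps = taps + rng.normal(0.0, tap_noise, taps.size)
    taps = np.sort(taps)
    if taps.size:
        strict = np.concatenate([[True], np.diff(taps) > 0])
        taps = taps[strict]
    return EventTrain(taps, kind="tap")


# ---------------------------------------------------------------------------
# behavioural table
# ---------------------------------------------------------------------------

def simulate_behavioural_table(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the cohort's demographic + neuropsychology table.

    Scores are Gaussian with group-specific means (healthy-control
    reference minus ``behav_effects`` for patient groups), clipped to each
    scale's range; ``missing_rate`` of cognitive cells are set missing
    completely at random.  Demographics are balanced across groups by
    construction (same age/education distributions, alternating sex and
    site).
    """
    rng = spec.rng(31)
    rows = []
    for g in spec.groups:
        for i in range(spec.n_per_group):
            rows.append({
                "subject": f"sub-{g}-{i:02d}",
                "diagnosis": g,
                "age": float(np.clip(rng.normal(68.0, 9.0), 40, 95)),
                "sex": "M" if i % 2 == 0 else "F",
                "education": float(np.clip(rng.normal(14.0, 4.0), 3, 25)),
                "site": f"site{(i // 2) % 2}",
            })
    df = pd.DataFrame(rows)
    control = spec.groups[0]
    for score, (hc_mean, sd) in REFERENCE_SCORES.items():
        shift = spec.behav_effects.get(score, _DEFAULT_BEHAV_EFFECTS[score])
        lo, hi = SCORE_RANGES[score]
        means = np.where(df["diagnosis"] == control, hc_mean, hc_mean + shift)
        df[score] = np.clip(rng.normal(means, sd), lo, hi)
    df["minisea_total"] = df["minisea_emotion"] + df["minisea_fauxpas"]
    if spec.missing_rate > 0:
        cog = list(SCORE_RANGES) + ["minisea_total"]
        mask = rng.random((len(df), len(cog))) < spec.missing_rate
        for j, col in enumerate(cog):
            df.loc[mask[:, j], col] = np.nan
    return df


# ---------------------------------------------------------------------------
# scalar ACW maps (ground-truth level)
# ---------------------------------------------------------------------------

def simulate_acw_maps(n_per_group: int, tau_by_group: dict[str, np.ndarray],
                      seed, positions: np.ndarray | None = None,
                      subject_sd: float = 0.1, electrode_sd: float = 0.05,
                      field_sd: float = 0.2, field_scale: float = 0.5
                      ) -> dict[str, np.ndarray]:
    """Draw per-subject ACW-50 electrode maps from the ground-truth model.

    A subject's map is ``tau_group * ln 2`` scaled by three lognormal
    factors: a global subject-level factor (log-SD ``subject_sd``, a
    fast/slow-brain scaling), a spatially smooth per-subject field (log-SD
    ``field_sd``, squared-exponential covariance with great-circle length
    scale ``field_scale`` radians - the scalar-map analogue of volume-
    conducted spatial correlation, which is what gives cluster nulls their
    activity), and independent per-electrode noise (log-SD
    ``electrode_sd``).  ``positions`` defaults to an evenly subsampled
    Biosemi cap matching the tau map length.

    This is the scalar-map-level counterpart of the full EEG generator,
    used for large-replicate calibration studies where simulating and
    re-estimating full EEG for every cohort would be wasteful.

    Returns ``{group: (n_per_group, n_electrodes) array}`` of ACW-50 in
    seconds.
    """
    from .montage import great_circle_distance

    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    n_elec = len(next(iter(tau_by_group.values())))
    if positions is None:
        _, positions = biosemi_montage(n_elec)
    chol = None
    if field_sd > 0:
        dist = great_circle_distance(positions)
        cov = field_sd ** 2 * np.exp(-((dist / field_scale) ** 2))
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_elec))
    out = {}
    for g, tau in tau_by_group.items():
        tau = np.asarray(tau, float)
        base = tau * np.log(2.0)
        sub = np.exp(rng.normal(0.0, subject_sd, (n_per_group, 1)))
        if chol is not None:
            field = np.exp((chol @ rng.standard_normal(
                (n_elec, n_per_group))).T)
        else:
            field = 1.0
        elec = np.exp(rng.normal(0.0, electrode_sd, (n_per_group, tau.size)))
        out[g] = base[None, :] * sub * field * elec
    return out


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(spec: CohortSpec, outdir) -> dict:
    """Write a full synthetic cohort to disk.

    Layout: one FIF file per subject x condition (EEG + ECG channel), an
    events TSV per subject x condition (R-peak truth, taps, block starts),
    a cohort-level behavioural CSV, the montage TSV and a JSON ground-truth
    sidecar.  Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels, pos = spec.montage
    write_montage_tsv(outdir / "montage.tsv", labels, pos)
    behav = simulate_behavioural_table(spec)
    behav.to_csv(outdir / "behaviour.csv", index=False)

    manifest = {"spec": _spec_dict(spec), "recordings": []}
    truth_tau = {}
    for subject in subject_ids(spec):
        ecg, truth = simulate_ecg(spec, subject)
        for condition in spec.conditions:
            eeg = simulate_eeg(spec, subject, condition)
            combined = Recording(
                data=np.vstack([eeg.data, ecg.data]),
                fs=spec.fs,
                labels=list(eeg.labels) + ["ECG"],
                positions=np.vstack([eeg.positions, np.full((1, 3), np.nan)]),
                subject=subject, condition=condition,
                block_bounds=eeg.block_bounds)
            stem = f"{subject}_{condition}"
            write_recording(combined, outdir / f"{stem}_raw.fif")
            taps = simulate_taps(
                truth, spec.tap_noise, spec.tap_miss_rate,
                spec.rng(22, spec._subject_index(subject),
                         list(spec.conditions).index(condition)),
                latency=spec.tap_latency)
            blocks = EventTrain(
                np.array([i * spec.block_duration
                          for i in range(spec.n_blocks)]) + 1e-9,
                kind="block_start")
            write_events_tsv(outdir / f"{stem}_events.tsv",
                             {"rpeak": truth, "tap": taps,
                              "block_start": blocks})
            truth_tau[f"{subject}/{condition}"] = \
                channel_tau(spec, subject, condition).tolist()
            manifest["recordings"].append(
                {"subject": subject, "condition": condition,
                 "raw": f"{stem}_raw.fif", "events": f"{stem}_events.tsv"})
    truth = {
        "channel_labels": labels,
        "tau_s": truth_tau,
        "effect_electrodes": list(spec.effect_electrodes),
        "acw50_closed_form": "tau * ln 2",
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _spec_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d.pop("_labels", None)
    d.pop("_positions", None)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
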