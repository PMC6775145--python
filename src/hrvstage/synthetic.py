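"""Synthetic whole-night cohort generator.

Nights are produced in three stages:

1. a semi-Markov hypnogram over (W, R, N1N2, N3) with gamma dwell times and
   a transition matrix that favours the W -> N1N2 -> N3 -> N1N2 -> R cycle
   with sparse awakenings; default dwell/transition parameters are tuned so
   the realized sleep statistics resemble a clinical cohort (sleep
   efficiency ~81%; of sleep time, ~67% N1/N2, ~14-16% N3, ~18% REM);
2. an instantaneous RR(t) signal with stage-dependent mean, Mayer-band
   (~0.1 Hz) and respiratory (~0.25 Hz) modulations plus white noise; beat
   times come from integral pulse frequency modulation (a beat fires each
   time the integral of 1/RR(t) crosses an integer), stage boundaries are
   smoothed over 15 s;
3. independent simulated annotators that relabel each epoch with a stage-
   adjacent confusion at a configurable error rate, yielding soft labels.

The whole cohort is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .io import (Hypnogram, IBISeries, RecordingMeta, SoftLabelMatrix,
                 STAGES, STAGE_INDEX, write_hypnogram, write_metadata,
                 write_rr_file)

_SIM_GRID_HZ = 4.0
_EPOCHS_PER_MIN = 2


@dataclass(frozen=True)
class StageProfile:
    mean_rr_ms: float
    rr_sd_ms: float
    lf_amp_ms: float
    hf_amp_ms: float
    mean_bout_min: float
    bout_shape: float
    lf_freq_hz: float = 0.1
    resp_freq_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0 or self.rr_sd_ms < 0:
            raise ValueError("invalid stage profile")
        if self.lf_amp_ms < 0 or self.hf_amp_ms < 0:
            raise ValueError("amplitudes must be non-negative")


#: Default autonomic profiles: heart rate decreases and respiratory sinus
#: arrhythmia (HF amplitude) increases with sleep depth; Mayer-band (LF)
#: modulation is strongest in wake.
DEFAULT_PROFILES: dict[str, StageProfile] = {
    "W": StageProfile(850.0, 35.0, 40.0, 10.0, mean_bout_min=7.0, bout_shape=0.8),
    "R": StageProfile(900.0, 30.0, 35.0, 15.0, mean_bout_min=7.0, bout_shape=2.0),
    "N1N2": StageProfile(1000.0, 25.0, 25.0, 30.0, mean_bout_min=9.0, bout_shape=2.0),
    "N3": StageProfile(1080.0, 20.0, 15.0, 45.0, mean_bout_min=6.0, bout_shape=2.0),
}

#: Stage-to-stage transition probabilities (no self-transitions).
DEFAULT_TRANSITIONS: dict[str, dict[str, float]] = {
    "W": {"N1N2": 1.0},
    "N1N2": {"N3": 0.35, "R": 0.35, "W": 0.30},
    "N3": {"N1N2": 0.85, "W": 0.15},
    "R": {"N1N2": 0.70, "W": 0.30},
}


@dataclass
class SimConfig:
    n_participants: int = 4
    nights_per_participant: int = 2
    tib_hours: float = 8.0
    n_annotators: int = 2
    annotator_error_rate: float = 0.15
    seed: int = 0
    profiles: dict[str, StageProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    transitions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITIONS.items()})
    #: Informational targets (fractions of total sleep time / of time in bed)
    target_mix: dict[str, float] = field(default_factory=lambda: {
        "N1N2": 0.67, "N3": 0.14, "R": 0.18, "SE": 0.81})

    @property
    def n_epochs(self) -> int:
        return int(self.tib_hours * 60 * _EPOCHS_PER_MIN)


# ---------------------------------------------------------------------------


def simulate_hypnogram(config: SimConfig, seed: int) -> Hypnogram:
    """Semi-Markov hypnogram: gamma dwell times, initial state W."""
    if config.tib_hours < 1:
        raise ValueError("time in bed must be at least 1 h")
    rng = np.random.default_rng(seed)
    n_target = config.n_epochs
    stages: list[str] = []
    state = "W"
    while len(stages) < n_target:
        prof = config.profiles[state]
        dur_min = rng.gamma(prof.bout_shape, prof.mean_bout_min / prof.bout_shape)
        n_ep = max(1, int(round(dur_min * _EPOCHS_PER_MIN)))
        stages.extend([state] * n_ep)
        nxt = config.transitions[state]
        names = sorted(nxt)
        probs = np.array([nxt[k] for k in names])
        state = names[rng.choice(len(names), p=probs / probs.sum())]
    return Hypnogram(np.array(stages[:n_target], dtype=object))


def simulate_ibi(hypnogram: Hypnogram, profiles: dict[str, StageProfile],
                 seed: int) -> IBISeries:
    """Stage-conditioned IBI series via integral pulse frequency modulation."""
    rng = np.random.default_rng(seed)
    n_ep = len(hypnogram)
    duration = n_ep * 30.0
    grid = np.arange(0.0, duration, 1.0 / _SIM_GRID_HZ)
    ep_idx = np.minimum((grid // 30.0).astype(int), n_ep - 1)

    def stage_param(attr: str) -> np.ndarray:
        per_ep = np.array([getattr(profiles[s], attr) for s in hypnogram.stages])
        sig = per_ep[ep_idx]
        k = int(15 * _SIM_GRID_HZ)  # 15-s boundary smoothing
        kernel = np.ones(k) / k
        return np.convolve(sig, kernel, mode="same")

    mean_rr = stage_param("mean_rr_ms")
    lf_amp = stage_param("lf_amp_ms")
    hf_amp = stage_param("hf_amp_ms")
    sd = stage_param("rr_sd_ms")
    lf_f = profiles["W"].lf_freq_hz
    hf_f = profiles["W"].resp_freq_hz
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    rr_ms = (mean_rr
             + lf_amp * np.sin(2 * np.pi * lf_f * grid + phi1)
             + hf_amp * np.sin(2 * np.pi * hf_f * grid + phi2)
             + sd * rng.standard_normal(grid.size))
    rr_s = np.maximum(rr_ms, 300.0) / 1000.0
    beats = _kernels.ipfm_beats(grid, rr_s, 0.0)
    beats = beats[beats < duration]
    rr_out = np.empty(beats.size)
    rr_out[0] = beats[0] * 1000.0
    rr_out[1:] = np.diff(beats) * 1000.0
    return IBISeries(beats, rr_out, np.ones(beats.size, bool),
                     duration_s=duration)


#: On an annotator error, the drawn stage prefers hypnogram-adjacent ones.
_CONFUSION_TARGETS = {
    "W": ("N1N2",),
    "N1N2": ("W", "N3", "R"),
    "N3": ("N1N2",),
    "R": ("N1N2",),
}


def simulate_annotators(hypnogram: Hypnogram, n_annotators: int,
                        error_rate: float, seed: int) -> SoftLabelMatrix:
    """Independent relabelling per annotator; fractions per epoch."""
    if n_annotators < 1:
        raise ValueError("need at least one annotator")
    rng = np.random.default_rng(seed)
    n_ep = len(hypnogram)
    counts = np.zeros((n_ep, 4))
    for _ in range(n_annotators):
        for i, true_stage in enumerate(hypnogram.stages):
            if rng.random() < error_rate:
                targets = _CONFUSION_TARGETS[true_stage]
                lab = targets[rng.integers(len(targets))]
            else:
                lab = true_stage
            counts[i, STAGE_INDEX[lab]] += 1
    return SoftLabelMatrix(counts / n_annotators)


def annotations_from_soft(soft: SoftLabelMatrix, n_annotators: int,
                          seed: int) -> np.ndarray:
    """Expand a soft-label matrix back into per-annotator label columns.

    Column assignment is arbitrary but deterministic; fractions round-trip.
    """
    rng = np.random.default_rng(seed)
    n_ep = len(soft)
    out = np.empty((n_ep, n_annotators), dtype=object)
    for i in range(n_ep):
        labels: list[str] = []
        counts = np.round(soft.fractions[i] * n_annotators).astype(int)
        for ci, c in enumerate(counts):
            labels.extend([STAGES[ci]] * c)
        rng.shuffle(labels)
        out[i] = labels
    return out


# ---------------------------------------------------------------------------
# Cohort assembly

_GROUPS = ("healthy", "apnea", "insomnia", "parkinson", "plmd")
_GROUP_P = (195 / 292, 51 / 292, 26 / 292, 15 / 292, 5 / 292)


@dataclass
class SimulatedNight:
    meta: RecordingMeta
    hypnogram: Hypnogram           # ground-truth stages
    series: IBISeries
    soft_labels: SoftLabelMatrix
    consensus: Hypnogram           # argmax of annotator fractions


def simulate_cohort(config: SimConfig) -> list[SimulatedNight]:
    """Generate the full in-memory cohort, a pure function of the config."""
    rng = np.random.default_rng(config.seed)
    nights: list[SimulatedNight] = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:03d}"
        age = float(np.clip(rng.normal(51.5, 17.3), 20.0, 90.0))
        bmi = float(np.clip(rng.normal(25.6, 4.5), 16.5, 43.3))
        sex = "F" if rng.random() < 0.43 else "M"
        group = _GROUPS[rng.choice(len(_GROUPS), p=_GROUP_P)]
        for n in range(config.nights_per_participant):
            rid = f"{pid}_N{n + 1}"
            s_hyp, s_ibi, s_ann = (int(x) for x in
                                   rng.integers(0, 2**31 - 1, size=3))
            hyp = simulate_hypnogram(config, s_hyp)
            series = simulate_ibi(hyp, config.profiles, s_ibi)
            series.recording_id = rid
            soft = simulate_annotators(hyp, config.n_annotators,
                                       config.annotator_error_rate, s_ann)
            meta = RecordingMeta(rid, pid, age=age, sex=sex, bmi=bmi, group=group)
            nights.append(SimulatedNight(meta, hyp, series, soft, soft.consensus()))
    return nights


def _config_hash(config: SimConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_cohort(config: SimConfig, out_dir: str | Path) -> Path:
    """Write the cohort to disk: RR files, hypnograms, metadata, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nights = simulate_cohort(config)
    manifest_rows = []
    metas = []
    ann_rng = np.random.default_rng(config.seed + 1)
    for night in nights:
        rid = night.meta.recording_id
        rr_path = out / f"{rid}_rr.csv"
        hyp_path = out / f"{rid}_hypnogram.csv"
        write_rr_file(night.series, rr_path)
        ann = annotations_from_soft(night.soft_labels, config.n_annotators,
                                    int(ann_rng.integers(0, 2**31 - 1)))
        write_hypnogram(hyp_path, ann)
        metas.append(night.meta)
        manifest_rows.append({"recording_id": rid,
                              "participant_id": night.meta.participant_id,
                              "rr_file": rr_path.name,
                              "hypnogram_file": hyp_path.name})
    write_metadata(metas, out / "metadata.csv")
    manifest = pd.DataFrame(manifest_rows)
    manifest["seed"] = config.seed
    manifest["config_hash"] = _config_hash(config)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out
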