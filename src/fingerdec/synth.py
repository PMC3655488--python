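"""Synthetic multichannel EEG sessions with a cued finger-movement protocol.

Each session mimics a single-subject recording: 250 Hz sampling, 6 s trials
(2 s blank rest, 2 s fixation, 2 s cued movement of one of five fingers of
the right hand), 80 trials per finger by default, on a schematic EEG net
with region-tagged channels.

Spectral phenomena emulated (all effect sizes are free parameters with
ground truth retained):

* 1/f^x background noise on every channel, with a per-trial lognormal
  global amplitude factor (slow arousal/impedance drift);
* narrowband alpha (8-12 Hz) and beta (13-30 Hz) rhythms realised as
  band-pass-filtered noise (realistic peak width), strongest over parietal
  (alpha) and motor (beta) regions, with per-trial amplitude waxing/waning;
* during the cued-movement window: (i) a broadband white-noise power
  increase spatially weighted by the moved finger's somatotopic profile,
  and (ii) multiplicative alpha/beta desynchronization (ERD) on
  motor-region channels, finger-modulated, both ramping in over the first
  0.5 s of the cue (movement preparation);
* optional 60 Hz line noise.

Adjacent fingers get overlapping spatial profiles, so misclassifications
should concentrate on neighbouring fingers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal

from .preprocess import FINGER_ORDER, Recording

REGIONS = ("left-motor", "right-motor", "parietal", "frontal", "other")

#: region-specific resting rhythm amplitudes (µV), posterior-dominant alpha
DEFAULT_ALPHA_AMP = {
    "parietal": 6.0,
    "left-motor": 4.0,
    "right-motor": 4.0,
    "frontal": 1.5,
    "other": 1.0,
}
DEFAULT_BETA_AMP = {
    "parietal": 1.5,
    "left-motor": 3.0,
    "right-motor": 3.0,
    "frontal": 0.8,
    "other": 0.5,
}


@dataclass
class Montage:
    """Schematic sensor layout with region tags and a decoding subset."""

    channel_ids: list[str]
    positions: np.ndarray  # (n, 2) unitless head coordinates
    region_tags: list[str]
    selected: np.ndarray  # bool per channel

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if len(self.positions) != len(self.channel_ids):
            raise ValueError("positions must match channel_ids")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def region_indices(self, region: str) -> np.ndarray:
        return np.flatnonzero([t == region for t in self.region_tags])

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def make_montage(n_channels: int, seed: int = 0) -> Montage:
    """Build a schematic montage with all five regions represented.

    Channels are laid out along per-region arcs inside a unit head circle;
    the decoding subset covers posterior-frontal, motor and parietal
    regions (the regions over posterior frontal, motor and parietal
    cortices used for feature extraction).
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels to cover all regions")
    rng = np.random.default_rng(seed)

    def share(frac: float, minimum: int) -> int:
        return max(minimum, int(round(frac * n_channels)))

    counts = {
        "left-motor": share(0.18, 2),
        "right-motor": share(0.18, 2),
        "parietal": share(0.18, 2),
        "frontal": share(0.16, 1),
    }
    counts["other"] = n_channels - sum(counts.values())
    if counts["other"] < 0:  # tiny montages: shrink 'frontal' then motor
        counts["frontal"] = max(1, counts["frontal"] + counts["other"])
        counts["other"] = n_channels - sum(v for k, v in counts.items() if k != "other")
        counts["other"] = max(0, counts["other"])

    # arc endpoints per region (start, end) in head coordinates
    arcs = {
        "left-motor": ((-0.65, -0.15), (-0.15, 0.25)),
        "right-motor": ((0.15, 0.25), (0.65, -0.15)),
        "parietal": ((-0.35, -0.55), (0.35, -0.55)),
        "frontal": ((-0.45, 0.55), (0.45, 0.55)),
        "other": ((-0.85, -0.35), (0.85, -0.35)),
    }
    ids, pos, tags, sel = [], [], [], []
    for region in REGIONS:
        k = counts[region]
        if k == 0:
            continue
        (x0, y0), (x1, y1) = arcs[region]
        t = np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.5])
        xy = np.stack([x0 + (x1 - x0) * t, y0 + (y1 - y0) * t], axis=1)
        xy += rng.normal(0.0, 0.02, size=xy.shape)  # cosmetic jitter only
        if region == "frontal":
            # posterior third of the frontal row joins the decoding subset
            n_sel = max(1, int(round(0.3 * k)))
            region_sel = [i < n_sel for i in range(k)]
            xy[:n_sel, 1] -= 0.15  # posterior-frontal sits closer to motor
        else:
            region_sel = [region in ("left-motor", "right-motor", "parietal")] * k
        for i in range(k):
            ids.append(f"E{len(ids) + 1:03d}")
            pos.append(xy[i])
            tags.append(region)
            sel.append(region_sel[i])
    return Montage(ids, np.asarray(pos), tags, np.asarray(sel))


def default_spatial_weights(montage: Montage) -> np.ndarray:
    """Somatotopic finger-effect weights, fingers x channels in [0, 1].

    Finger representations are Gaussian bumps along the contralateral
    (left) motor strip, with overlapping profiles for adjacent fingers;
    parietal channels carry an attenuated copy and the ipsilateral motor
    strip a faint one.
    """
    n = montage.n_channels
    w = np.zeros((len(FINGER_ORDER), n))
    centers = (np.arange(5) + 0.5) / 5.0
    sigma = 0.18

    def arc_coord(idx: np.ndarray) -> np.ndarray:
        if len(idx) == 1:
            return np.array([0.5])
        p = montage.positions[idx]
        d = p - p[0]
        axis = p[-1] - p[0]
        t = d @ axis / (axis @ axis)
        t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
        return t

    for region, scale in (("left-motor", 1.0), ("parietal", 0.45), ("right-motor", 0.15)):
        idx = montage.region_indices(region)
        if len(idx) == 0:
            continue
        t = arc_coord(idx)
        for f, cf in enumerate(centers):
            w[f, idx] = scale * np.exp(-((t - cf) ** 2) / (2 * sigma**2))
    return w


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the standard study conditions."""

    n_channels: int = 64
    fs: float = 250.0
    trial_len: float = 6.0
    n_trials_per_finger: int = 80
    n_fingers: int = 5
    broadband_gain: float = 2.0
    erd_depth_alpha: float = 0.5
    erd_depth_beta: float = 0.35
    spatial_weights: Optional[np.ndarray] = None
    background_exponent: float = 1.0
    line_noise_amp: float = 0.0
    seed: int = 0
    # background/rhythm scales (µV) and per-trial lognormal variability (ln-sd)
    background_std: float = 8.0
    white_std: float = 2.0
    amp_jitter_sd: float = 0.3
    alpha_jitter_sd: float = 0.6
    beta_jitter_sd: float = 0.5
    alpha_amp: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA_AMP))
    beta_amp: dict = field(default_factory=lambda: dict(DEFAULT_BETA_AMP))
    movement_onset_s: float = 4.0
    ramp_s: float = 0.5

    def validate(self) -> None:
        if self.n_fingers != 5:
            raise ValueError("protocol is fixed at 5 fingers")
        n = self.trial_len * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_len x fs must be an integer sample count")
        if not (0 <= self.erd_depth_alpha < 1 and 0 <= self.erd_depth_beta < 1):
            raise ValueError("ERD depths must lie in [0, 1)")
        if self.broadband_gain <= 0:
            raise ValueError("broadband_gain must be positive")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_len * self.fs))

    @property
    def n_trials(self) -> int:
        return self.n_fingers * self.n_trials_per_finger


@dataclass
class GroundTruth:
    """Effect parameters actually used, kept for recovery tests."""

    labels: np.ndarray  # finger name per trial
    spatial_weights: np.ndarray  # fingers x channels
    broadband_gain: float
    erd_depth_alpha: float
    erd_depth_beta: float
    movement_window_s: tuple[float, float]
    ramp_s: float


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)  # relative frequency; shape only
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _narrowband(rng: np.random.Generator, n: int, lo: float, hi: float, fs: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def simulate_session(
    cfg: SimulationConfig, montage: Montage
) -> tuple[Recording, GroundTruth]:
    """Generate one continuous session; identical seed => identical output."""
    cfg.validate()
    if montage.n_channels != cfg.n_channels:
        raise ValueError(
            f"montage has {montage.n_channels} channels, config expects {cfg.n_channels}"
        )
    rng = np.random.default_rng(cfg.seed)
    n_trials, spt, fs = cfg.n_trials, cfg.samples_per_trial, cfg.fs
    n_total = n_trials * spt

    labels = np.repeat(np.asarray(FINGER_ORDER), cfg.n_trials_per_finger)
    rng.shuffle(labels)
    finger_idx = np.array([FINGER_ORDER.index(l) for l in labels])

    w = cfg.spatial_weights if cfg.spatial_weights is not None else default_spatial_weights(montage)
    w = np.asarray(w, dtype=float)
    if w.shape != (cfg.n_fingers, cfg.n_channels):
        raise ValueError("spatial_weights must be fingers x channels")

    # per-trial lognormal amplitude factors, shared across channels
    amp_j = np.exp(rng.normal(0.0, cfg.amp_jitter_sd, n_trials))
    alpha_j = np.exp(rng.normal(0.0, cfg.alpha_jitter_sd, n_trials))
    beta_j = np.exp(rng.normal(0.0, cfg.beta_jitter_sd, n_trials))

    # within-trial movement modulation: 0 until cue, linear ramp, then 1
    t_in = np.arange(spt) / fs
    ramp = np.clip((t_in - cfg.movement_onset_s) / cfg.ramp_s, 0.0, 1.0)
    ramp[t_in < cfg.movement_onset_s] = 0.0

    # per-channel finger ERD modulation: full strength on the motor strip,
    # finger-specific via the normalized somatotopic profile
    motor = np.array([t in ("left-motor", "right-motor") for t in montage.region_tags])
    w_max = np.maximum(w.max(axis=0), 1e-12)
    w_norm = w / w_max  # per-channel profile in [0, 1]

    erd_a = np.where(motor, cfg.erd_depth_alpha, 0.0)  # (channels,)
    erd_b = np.where(motor, cfg.erd_depth_beta, 0.0)

    out = np.empty((cfg.n_channels, n_total))
    line = cfg.line_noise_amp * np.sin(2 * np.pi * 60.0 * np.arange(n_total) / fs)

    for c in range(cfg.n_channels):
        region = montage.region_tags[c]
        bg = cfg.background_std * _one_over_f_noise(rng, n_total, cfg.background_exponent)
        alpha = cfg.alpha_amp[region] * _narrowband(rng, n_total, 8.0, 12.0, fs)
        beta = cfg.beta_amp[region] * _narrowband(rng, n_total, 13.0, 30.0, fs)
        white = cfg.white_std * rng.standard_normal(n_total)
        bb = rng.standard_normal(n_total)

        fi = finger_idx  # (trials,)
        # amplitude factors per (trial, sample-in-trial), flattened
        erd_mod_a = np.sqrt(1.0 - erd_a[c] * (0.4 + 0.6 * w_norm[fi, c])[:, None] * ramp)
        erd_mod_b = np.sqrt(1.0 - erd_b[c] * (0.4 + 0.6 * w_norm[fi, c])[:, None] * ramp)
        bb_mod = np.sqrt((cfg.broadband_gain - 1.0) * w[fi, c][:, None] * ramp)

        x = (
            bg
            + (alpha.reshape(n_trials, spt) * alpha_j[:, None] * erd_mod_a).ravel()
            + (beta.reshape(n_trials, spt) * beta_j[:, None] * erd_mod_b).ravel()
            + white
            + cfg.white_std * (bb.reshape(n_trials, spt) * bb_mod).ravel()
        )
        out[c] = x * np.repeat(amp_j, spt) + line

    events = [(int(i * spt), str(labels[i])) for i in range(n_trials)]
    rec = Recording(
        signal=out, fs=fs, events=events, channel_ids=list(montage.channel_ids), montage=montage
    )
    gt = GroundTruth(
        labels=labels,
        spatial_weights=w,
        broadband_gain=cfg.broadband_gain,
        erd_depth_alpha=cfg.erd_depth_alpha,
        erd_depth_beta=cfg.erd_depth_beta,
        movement_window_s=(cfg.movement_onset_s, cfg.trial_len),
        ramp_s=cfg.ramp_s,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# session I/O: delimited long-format table + JSON sidecar, npz convenience
# ---------------------------------------------------------------------------


def write_session_table(rec: Recording, path: str | Path) -> None:
    """Write (time, channel, value) long-format CSV + a JSON sidecar.

    The sidecar (``<path>.json``) carries fs, channel ids and trial events.
    Intended for small sessions / interchange; use npz for full sessions.
    """
    path = Path(path)
    ids = rec.channel_ids or [f"ch{i}" for i in range(rec.n_channels)]
    t = np.arange(rec.n_samples) / rec.fs
    with open(path, "w") as fh:
        fh.write("time,channel,value\n")
        for c, cid in enumerate(ids):
            for ti, v in zip(t, rec.signal[c]):
                fh.write(f"{ti:.6f},{cid},{v:.6f}\n")
    sidecar = {
        "fs": rec.fs,
        "channel_ids": ids,
        "events": [[int(o), l] for o, l in rec.events],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_session_table(path: str | Path) -> Recording:
    import pandas as pd

    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path)
    ids = sidecar["channel_ids"]
    sig = np.stack([df.loc[df["channel"] == cid, "value"].to_numpy() for cid in ids])
    return Recording(
        signal=sig,
        fs=float(sidecar["fs"]),
        events=[(int(o), str(l)) for o, l in sidecar["events"]],
        channel_ids=list(ids),
    )


def write_session_npz(rec: Recording, path: str | Path) -> None:
    onsets = np.array([o for o, _ in rec.events], dtype=np.int64)
    labels = np.array([l for _, l in rec.events])
    np.savez_compressed(
        path,
        signal=rec.signal,
        fs=rec.fs,
        onsets=onsets,
        labels=labels,
        channel_ids=np.array(rec.channel_ids or []),
    )


def read_session_npz(path: str | Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        events = [(int(o), str(l)) for o, l in zip(z["onsets"], z["labels"])]
        ids = [str(c) for c in z["channel_ids"]] or None
        return Recording(signal=z["signal"], fs=float(z["fs"]), events=events, channel_ids=ids)


def read_session_edf(path: str | Path) -> Recording:
    """Read a continuous EEG session from EDF via mne (optional dependency).

    Annotations are interpreted as trial-onset markers whose descriptions
    are the finger labels.
    """
    import mne  # local import: EDF support is optional

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sig = raw.get_data() * 1e6  # volts -> µV
    fs = float(raw.info["sfreq"])
    events = [
        (int(round(onset * fs)), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return Recording(signal=sig, fs=fs, events=events, channel_ids=list(raw.ch_names))


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. parsed YAML)."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    return SimulationConfig(**d)
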