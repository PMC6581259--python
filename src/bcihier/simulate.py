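"""Synthetic motor-imagery EEG sessions with plantable ground truth.

The generator emulates the statistical structure the pipeline assumes:
narrow-band neural sources (band-filtered Gaussian noise, not sinusoids, so
covariances look realistic) mixed into the channels through fixed
topographies, with event-related desynchronization (ERD) modelled as a
multiplicative power *attenuation* of a class's sources during that class's
imagery window.  Trials follow the standard cue template: rest in 0-2 s
(the NC interval), cue at 3 s, imagery sustained over 4-7 s, then a break
until the 9 s trial ends.  Background activity is 1/f ("pink") noise plus a
white floor; a single SNR scalar scales total source power against total
noise power and stands in for subject skill.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import IC_CLASSES, RawSession
from .preprocessing import bandpass

MU_BAND = (8.0, 12.0)
BETA_BAND = (18.0, 26.0)

#: Skill presets.  BCI skill shows up in three ways: how much of the signal
#: the class-relevant rhythms carry (snr), how deeply the subject modulates
#: them (erd/ers gains), and how consistently modulation happens from trial
#: to trial (reliability; on unreliable trials the gains stay at baseline).
#: Trial counts follow the competition subject templates (90 vs 60/class).
SKILL_PRESETS = {
    "expert": {"snr": 6.0, "erd_gain": 0.25, "ers_gain": 3.0,
               "modulation_reliability": 1.0, "n_trials_per_class": 90},
    "intermediate": {"snr": 1.5, "erd_gain": 0.45, "ers_gain": 1.8,
                     "modulation_reliability": 0.85,
                     "n_trials_per_class": 60},
    "novice": {"snr": 0.5, "erd_gain": 0.7, "ers_gain": 1.25,
               "modulation_reliability": 0.6, "n_trials_per_class": 60},
}


@dataclass
class SourceSpec:
    """One narrow-band source: where it projects, and how classes gate it."""

    topography: np.ndarray          # (n_channels,), non-zero
    band: tuple                     # (low, high) Hz
    baseline_power: float = 1.0
    class_gains: dict = field(default_factory=dict)  # label -> power factor

    def __post_init__(self):
        self.topography = np.asarray(self.topography, float)
        if not np.any(self.topography):
            raise ValueError("topography must be non-zero")
        if any(g < 0 for g in self.class_gains.values()):
            raise ValueError("class gains must be positive")


@dataclass
class SimConfig:
    n_channels: int = 60
    sfreq: float = 250.0
    n_trials_per_class: int = 90
    trial_length_s: float = 9.0
    ic_window: tuple = (4.0, 7.0)
    sources: list = None            # None -> default_sources()
    noise_pink: float = 1.0
    noise_white: float = 0.1        # ~ -20 dB relative to the pink part
    snr: float = 2.0
    erd_gain: float = 0.3
    ers_gain: float = 2.5
    modulation_reliability: float = 1.0   # P(trial actually modulated)
    orthogonal_topographies: bool = True
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        if self.ic_window[1] > self.trial_length_s:
            raise ValueError("imagery window exceeds the trial length")


@dataclass
class GroundTruth:
    trial_classes: list             # per trial
    mixing: np.ndarray              # (n_channels, n_sources)
    source_bands: list              # per source
    realized_gains: np.ndarray      # (n_sources, n_trials) power factors
    snr: float

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"trial_classes": list(self.trial_classes),
                       "mixing": self.mixing.tolist(),
                       "source_bands": [list(b) for b in self.source_bands],
                       "realized_gains": self.realized_gains.tolist(),
                       "snr": self.snr}, f)


def default_sources(n_channels: int, rng, erd_gain: float = 0.3,
                    ers_gain: float = 2.5, orthogonal: bool = True) -> list:
    """Two sources (mu + beta) per imagery class with distinct topographies.

    Each class gates its own pair during that class's imagery window with
    the textbook sensorimotor pattern: the mu source desynchronizes (power
    drops to ``erd_gain`` of baseline) while the beta source synchronizes
    (power rises by ``ers_gain``, the beta-rebound analogue).  Every other
    window, including the whole NC interval, stays at baseline.
    """
    n_src = 2 * len(IC_CLASSES)
    if orthogonal and n_channels >= n_src:
        a = np.linalg.qr(rng.standard_normal((n_channels, n_src)))[0]
    else:
        a = rng.standard_normal((n_channels, n_src))
        a /= np.linalg.norm(a, axis=0)
    sources = []
    for i, cls in enumerate(IC_CLASSES):
        for j, (band, gain) in enumerate(((MU_BAND, erd_gain),
                                          (BETA_BAND, ers_gain))):
            sources.append(SourceSpec(topography=a[:, 2 * i + j], band=band,
                                      baseline_power=1.0 if j == 0 else 0.6,
                                      class_gains={cls: gain}))
    return sources


def _pink_noise(rng, shape, n_samples, sfreq):
    white = rng.standard_normal(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    pink = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n_samples,
                        axis=-1)
    return pink / pink.std(axis=-1, keepdims=True)


def simulate_session(config: SimConfig):
    """Generate one session; returns (RawSession, GroundTruth).

    Bit-reproducible for a given config (one seeded generator drives trial
    order, topographies, source waveforms and noise).
    """
    rng = np.random.default_rng(config.seed)
    fs, L = config.sfreq, config.trial_length_s
    spt = int(round(L * fs))
    trial_classes = [c for c in IC_CLASSES
                     for _ in range(config.n_trials_per_class)]
    rng.shuffle(trial_classes)
    n_trials = len(trial_classes)
    n_samples = n_trials * spt

    sources = config.sources
    if sources is None:
        sources = default_sources(config.n_channels, rng,
                                  erd_gain=config.erd_gain,
                                  ers_gain=config.ers_gain,
                                  orthogonal=config.orthogonal_topographies)
    for s in sources:
        if s.band[1] >= fs / 2:
            raise ValueError(f"source band {s.band} reaches Nyquist")
        if len(s.topography) != config.n_channels:
            raise ValueError("topography length != n_channels")

    lo = int(np.floor(config.ic_window[0] * fs))
    hi = int(np.floor(config.ic_window[1] * fs))
    gains = np.ones((len(sources), n_trials))
    signal = np.zeros((config.n_channels, n_samples))
    for k, src in enumerate(sources):
        wave = bandpass(rng.standard_normal(n_samples), src.band, fs, order=4)
        wave /= wave.std()
        env = np.ones(n_samples)
        for t, cls in enumerate(trial_classes):
            g = src.class_gains.get(cls)
            if g is not None:
                # unskilled subjects fail to modulate on some trials
                if rng.random() >= config.modulation_reliability:
                    g = 1.0
                gains[k, t] = g
                env[t * spt + lo: t * spt + hi] = np.sqrt(g)
        signal += np.outer(src.topography,
                           np.sqrt(src.baseline_power) * wave * env)

    noise = (config.noise_pink
             * _pink_noise(rng, (config.n_channels,), n_samples, fs))
    noise += (config.noise_white
              * rng.standard_normal((config.n_channels, n_samples)))
    p_sig = np.mean(signal ** 2)
    p_noise = np.mean(noise ** 2)
    if p_sig > 0:
        signal *= np.sqrt(config.snr * p_noise / p_sig)
    signal = (signal + noise).astype(config.dtype)

    events = [(t * spt, cls) for t, cls in enumerate(trial_classes)]
    session = RawSession(
        signal=signal, sfreq=fs,
        channel_names=[f"ch{i + 1}" for i in range(config.n_channels)],
        events=events, subject_id=f"sim-snr{config.snr:g}")
    truth = GroundTruth(trial_classes=trial_classes,
                        mixing=np.stack([s.topography for s in sources],
                                        axis=1),
                        source_bands=[s.band for s in sources],
                        realized_gains=gains, snr=config.snr)
    return session, truth


def make_subject_suite(skill: str, seed: int = 0, n_channels: int = 60,
                       n_trials_per_class: int = None, **overrides):
    """Preset session for a subject skill level (expert/intermediate/novice).

    SNR maps skill to how separable the imagery classes are, reproducing the
    qualitative accuracy ordering between a well-trained subject, one with
    some practice and a complete beginner.  Trial counts follow the
    competition subject templates (90 vs 60 per class).
    """
    if skill not in SKILL_PRESETS:
        raise ValueError(f"unknown skill {skill!r}; "
                         f"choose from {sorted(SKILL_PRESETS)}")
    preset = dict(SKILL_PRESETS[skill])
    if n_trials_per_class is not None:
        preset["n_trials_per_class"] = n_trials_per_class
    preset.update(overrides)
    cfg = SimConfig(n_channels=n_channels, seed=seed, **preset)
    return simulate_session(cfg)
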