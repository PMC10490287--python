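"""Seeded synthetic EEG with known class structure and artifact ground truth.

The generator emulates the statistical shape of a multi-pilot flight-task
recording: four mental-state conditions (NE normal, CA channelized attention,
DA diverted attention, SS startle/surprise) with severe class imbalance
(NE near 80% of samples by default), class-conditional spatial covariance
across >= 20 channels, a 1/f background spectrum, and injected artifacts —
frontal blinks, high-frequency muscle bursts, large amplitude spikes
(> 700 uV peak-to-peak) and near-flat channels.

Design: each state's signal is a fixed linear mixture of spatially whitened
sources whose temporal spectrum is shaped to 1/f^a; the whitening makes the
spatial covariance of each state's background block equal the configured
class covariance exactly, up to a small white sensor noise floor.  Class covariances default to a shared (seeded, fixed) mixing
basis with class-specific source-power boosts, so states are separable by
covariance — the structure the tangent-space feature pipeline assumes — and
CA/DA/SS carry elevated mean power relative to NE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import check_spd
from .montage import Montage, make_montage
from .preprocess import STATES, EpochSet, RawRecording, write_recording

__all__ = [
    "ArtifactSpec",
    "SimConfig",
    "GroundTruth",
    "default_class_covariances",
    "make_montage",
    "simulate_recording",
    "write_simulation",
]

_MIXING_SEED = 715517  # fixed: default class covariances are config stable


@dataclass(frozen=True)
class ArtifactSpec:
    """Per-epoch artifact probabilities and amplitudes (uV).

    Rates are the probability that a given one-second epoch contains one event
    of that type.  ``spike_amplitude`` defaults above the 700 uV rejection
    threshold so injected spikes are unambiguous ground truth.
    """

    blink_rate: float = 0.15
    blink_amplitude: float = 120.0
    blink_duration: float = 0.3  # seconds
    muscle_rate: float = 0.05
    muscle_amplitude: float = 40.0
    spike_rate: float = 0.03
    spike_amplitude: float = 900.0
    flat_rate: float = 0.01

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(blink_rate=0, muscle_rate=0, spike_rate=0, flat_rate=0)


def default_class_covariances(n_channels: int = 20, scale: float = 150.0,
                              boost: float = 0.6) -> dict:
    """Class spatial covariances sharing one mixing basis.

    Each non-NE state boosts a disjoint block of sources by exp(boost); with
    block size b the Riemannian distance between any two states is at least
    sqrt(b) * boost (1.34 for the defaults), so classes are separable by
    covariance geometry alone.  ``scale`` (uV^2) sets the per-source variance.
    """
    rng = np.random.default_rng(_MIXING_SEED)
    A = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))[0]
    block = max(n_channels // 4, 1)
    covs = {}
    for k, state in enumerate(STATES):
        powers = np.ones(n_channels)
        if state != "NE":
            lo = (k - 1) * block
            powers[lo : lo + block] = np.exp(boost)
        covs[state] = (A * (powers * scale)) @ A.T
    return covs


@dataclass
class SimConfig:
    """Everything `simulate_recording` needs; same seed + config => bit-identical output."""

    n_channels: int = 20
    sample_rate: float = 256.0
    # seconds per state; defaults put ~80% of samples in NE
    class_durations: dict = field(
        default_factory=lambda: {"NE": 240.0, "CA": 20.0, "DA": 20.0, "SS": 20.0}
    )
    class_covariances: dict | None = None  # state -> SPD (uV^2); default shared-basis
    noise_exponent: float = 1.0  # 1/f^a slope of the background spectrum
    sensor_noise_uv: float = 1.0  # white noise floor, uV std
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def resolved_covariances(self) -> dict:
        covs = self.class_covariances
        if covs is None:
            covs = default_class_covariances(self.n_channels)
        for state, C in covs.items():
            C = np.asarray(C, dtype=float)
            if C.shape != (self.n_channels, self.n_channels):
                raise ValueError(f"covariance for {state} has shape {C.shape}")
            check_spd(C, f"class covariance {state}")
        return {s: np.asarray(covs[s], dtype=float) for s in covs}

    def validate(self) -> None:
        if self.n_channels < 4:
            raise ValueError("need at least 4 channels")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        bad = set(self.class_durations) - set(STATES)
        if bad:
            raise ValueError(f"unknown states: {bad}")
        if not self.class_durations:
            raise ValueError("class_durations is empty")
        self.resolved_covariances()


@dataclass
class GroundTruth:
    """What the generator knows: per-epoch states, artifact annotations and
    the exact blink activation time course."""

    epoch_labels: np.ndarray  # (n_epochs,)
    annotations: pd.DataFrame  # columns: epoch, kind, channels, onset_sample
    blink_trace: np.ndarray  # (n_samples,) blink kernel activation

    def artifact_epochs(self, kinds=None) -> np.ndarray:
        df = self.annotations
        if kinds is not None:
            df = df[df["kind"].isin(kinds)]
        return np.unique(df["epoch"].to_numpy())

    def clean_epochs(self) -> np.ndarray:
        n = len(self.epoch_labels)
        dirty = set(self.artifact_epochs().tolist())
        return np.array([e for e in range(n) if e not in dirty])


def _pink_noise(rng: np.random.Generator, n_sources: int, n_samples: int,
                exponent: float) -> np.ndarray:
    """Unit-variance Gaussian sources with a 1/f^exponent power spectrum."""
    white = rng.standard_normal((n_sources, n_samples))
    if exponent == 0:
        return white
    freqs = np.fft.rfftfreq(n_samples)
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = 0.0  # no DC
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return shaped


def _blink_kernel(n: int) -> np.ndarray:
    """Smooth positive transient: squared half-sine."""
    t = np.linspace(0.0, np.pi, n)
    return np.sin(t) ** 2


def simulate_recording(config: SimConfig) -> tuple[RawRecording, GroundTruth]:
    """Generate a labelled continuous recording plus its ground truth.

    One contiguous block per state (in NE/CA/DA/SS order, states with zero or
    missing duration skipped), each the configured number of seconds.
    Artifacts are injected on one-second epoch boundaries and annotated with
    type, affected channels and onset.
    """
    config.validate()
    covs = config.resolved_covariances()
    fs = config.sample_rate
    L = int(round(fs))  # samples per 1 s epoch
    montage = make_montage(config.n_channels)
    rng = np.random.default_rng(config.seed)
    spec = config.artifact_spec

    blocks, labels = [], []
    for state in STATES:
        dur = config.class_durations.get(state, 0.0)
        n = int(round(dur * fs))
        if n == 0:
            continue
        if state not in covs:
            raise ValueError(f"no covariance configured for state {state}")
        sources = _pink_noise(rng, config.n_channels, n, config.noise_exponent)
        # exact spatial whitening: 1/f temporal correlation leaves few
        # effective samples, so sample covariances converge slowly; whitening
        # the sources makes the block's empirical spatial covariance equal
        # the configured class covariance exactly
        sources = sources - sources.mean(axis=1, keepdims=True)
        C_s = sources @ sources.T / (n - 1)
        sources = np.linalg.solve(np.linalg.cholesky(C_s), sources)
        mix = np.linalg.cholesky(check_spd(covs[state]))
        block = mix @ sources
        if config.sensor_noise_uv > 0:
            block = block + config.sensor_noise_uv * rng.standard_normal(block.shape)
        blocks.append(block)
        labels.append(np.repeat(state, n))
    data = np.concatenate(blocks, axis=1)
    sample_labels = np.concatenate(labels)
    n_samples = data.shape[1]
    n_epochs = n_samples // L

    blink_trace = np.zeros(n_samples)
    frontal_w = montage.frontal_weights()
    frontal_idx = np.flatnonzero(frontal_w > 0.2)
    records = []

    blink_len = int(round(spec.blink_duration * fs))
    kernel = _blink_kernel(blink_len)
    for e in range(n_epochs):
        start = e * L
        if spec.blink_rate > 0 and rng.random() < spec.blink_rate:
            onset = start + rng.integers(0, max(L - blink_len, 1))
            blink_trace[onset : onset + blink_len] += kernel
            data[:, onset : onset + blink_len] += (
                spec.blink_amplitude * np.outer(frontal_w, kernel)
            )
            records.append((e, "blink", ";".join(
                montage.channel_names[i] for i in frontal_idx), onset - start))
        if spec.muscle_rate > 0 and rng.random() < spec.muscle_rate:
            dur = int(0.2 * fs)
            onset = start + rng.integers(0, max(L - dur, 1))
            chans = rng.choice(config.n_channels, size=min(3, config.n_channels),
                               replace=False)
            burst = rng.standard_normal((len(chans), dur))
            # crude high-pass: first difference emphasises high frequencies
            burst = np.diff(burst, axis=1, prepend=burst[:, :1])
            burst *= spec.muscle_amplitude / burst.std(axis=1, keepdims=True)
            window = np.hanning(dur)
            data[np.ix_(chans, range(onset, onset + dur))] += burst * window
            records.append((e, "muscle", ";".join(
                montage.channel_names[int(c)] for c in chans), onset - start))
        if spec.spike_rate > 0 and rng.random() < spec.spike_rate:
            ch = int(rng.integers(config.n_channels))
            width = max(int(0.02 * fs), 3)
            onset = start + rng.integers(0, max(L - 2 * width, 1))
            spike = spec.spike_amplitude * _blink_kernel(width)
            data[ch, onset : onset + width] += spike
            data[ch, onset + width : onset + 2 * width] -= 0.3 * spike
            records.append((e, "spike", montage.channel_names[ch], onset - start))
        if spec.flat_rate > 0 and rng.random() < spec.flat_rate:
            ch = int(rng.integers(config.n_channels))
            data[ch, start : start + L] = 0.05 * rng.standard_normal(L)
            records.append((e, "flat", montage.channel_names[ch], 0))

    epoch_labels = np.array(
        [pd.Series(sample_labels[e * L : (e + 1) * L]).mode().iloc[0]
         for e in range(n_epochs)]
    )
    annotations = pd.DataFrame(
        records, columns=["epoch", "kind", "channels", "onset_sample"]
    )
    rec = RawRecording(list(montage.channel_names), fs, data, sample_labels)
    return rec, GroundTruth(epoch_labels, annotations, blink_trace)


def simulate_epochs(config: SimConfig, montage: Montage | None = None
                    ) -> tuple[EpochSet, GroundTruth]:
    """Convenience: simulate and cut directly into labelled 1 s epochs."""
    from .preprocess import epoch_fixed

    rec, truth = simulate_recording(config)
    eps = epoch_fixed(rec, montage=montage or make_montage(config.n_channels))
    return eps, truth


def write_simulation(outdir, config: SimConfig) -> tuple[Path, Path, Path]:
    """Simulate and write recording CSV + metadata sidecar + annotation table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec, truth = simulate_recording(config)
    rec_path = outdir / "recording.csv"
    write_recording(
        rec_path,
        rec,
        metadata={
            "seed": int(config.seed),
            "noise_exponent": float(config.noise_exponent),
            "class_durations": {k: float(v) for k, v in config.class_durations.items()},
        },
    )
    ann_path = outdir / "annotations.csv"
    truth.annotations.to_csv(ann_path, index=False)
    labels_path = outdir / "epoch_labels.csv"
    pd.DataFrame({"epoch": np.arange(len(truth.epoch_labels)),
                  "state": truth.epoch_labels}).to_csv(labels_path, index=False)
    return rec_path, ann_path, labels_path
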