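"""Recording I/O and the deterministic front half of the cleaning pipeline.

Continuous recordings arrive as delimited text (one column per channel,
amplitudes in microvolts, plus a per-sample state label column) with a small
YAML sidecar naming the sample rate.  Preprocessing is: zero-phase FIR
band-pass (1-50 Hz), segmentation into one-second non-overlapping epochs
labelled by majority vote, a fixed peak-to-peak amplitude gate (epochs with
any channel exceeding 700 uV or any channel under 1 uV are dropped), and
seeded random undersampling to equalize the heavily imbalanced state classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .montage import Montage

logger = logging.getLogger(__name__)

STATES = ("NE", "CA", "DA", "SS")


class FormatError(ValueError):
    """Recording file does not match the declared layout."""


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts with per-sample labels."""

    channel_names: list
    sample_rate: float
    data: np.ndarray  # (n_channels, n_samples), uV
    labels: np.ndarray | None = None  # (n_samples,) of state strings

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples matching channel_names")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.data.shape[1],):
                raise ValueError("labels must have one entry per sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class EpochSet:
    """Fixed-length labelled epochs plus a provenance ledger.

    ``data`` holds only the currently kept epochs; ``flags`` is a DataFrame
    indexed by original epoch id recording every decision ever taken
    (kept / dropped / repaired, with a reason), so epochs removed by the
    amplitude gate or the repair stage stay accounted for.  ``epoch_ids``
    maps rows of ``data`` back to ``flags`` indices.
    """

    data: np.ndarray  # (n_kept, n_channels, n_times)
    labels: np.ndarray  # (n_kept,)
    channel_names: list
    sample_rate: float
    epoch_ids: np.ndarray = None  # original ids of kept epochs
    flags: pd.DataFrame = None
    montage: Montage | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x times")
        if len(self.labels) != len(self.data):
            raise ValueError("one label per epoch required")
        if self.epoch_ids is None:
            self.epoch_ids = np.arange(len(self.data))
        self.epoch_ids = np.asarray(self.epoch_ids)
        if self.flags is None:
            self.flags = pd.DataFrame(
                {"status": "kept", "reason": ""},
                index=pd.Index(self.epoch_ids, name="epoch"),
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, keep_mask: np.ndarray, reason: str, status: str = "dropped") -> "EpochSet":
        """New EpochSet keeping rows where ``keep_mask`` is True; the rest are
        marked ``status`` with ``reason`` in the provenance ledger."""
        keep_mask = np.asarray(keep_mask, dtype=bool)
        flags = self.flags.copy()
        removed = self.epoch_ids[~keep_mask]
        flags.loc[removed, "status"] = status
        flags.loc[removed, "reason"] = reason
        return replace(
            self,
            data=self.data[keep_mask],
            labels=self.labels[keep_mask],
            epoch_ids=self.epoch_ids[keep_mask],
            flags=flags,
        )


# ---------------------------------------------------------------------------
# recording I/O


def write_recording(path, rec: RawRecording, metadata: dict | None = None) -> None:
    """Write a recording as CSV (channels + label columns) with a YAML sidecar."""
    path = Path(path)
    cols = {name: rec.data[i] for i, name in enumerate(rec.channel_names)}
    if rec.labels is not None:
        cols["label"] = rec.labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    meta = {
        "sample_rate": float(rec.sample_rate),
        "channels": list(rec.channel_names),
        "units": "uV",
    }
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_recording(
    path,
    channel_names: list | None = None,
    label_column: str = "label",
    sample_rate: float | None = None,
) -> RawRecording:
    """Read a delimited-text recording.

    Layout comes either from the YAML sidecar written by `write_recording`
    (default) or from explicit ``channel_names`` / ``sample_rate`` arguments.
    Unknown columns are ignored with a warning; a missing declared column or a
    non-numeric amplitude raises `FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if channel_names is None or sample_rate is None:
        if not sidecar.exists():
            raise FormatError(
                f"no sidecar {sidecar.name}; pass channel_names and sample_rate"
            )
        meta = yaml.safe_load(sidecar.read_text())
        channel_names = channel_names or meta["channels"]
        sample_rate = sample_rate or meta["sample_rate"]
    df = pd.read_csv(path)
    missing = [c for c in channel_names if c not in df.columns]
    if missing:
        raise FormatError(f"declared channel columns missing: {missing}")
    has_labels = label_column in df.columns
    known = set(channel_names) | {label_column}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown columns: %s", extra)
    try:
        data = df[channel_names].to_numpy(dtype=float).T
    except ValueError as exc:
        for col in channel_names:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise FormatError(
                    f"non-numeric amplitude in column {col!r} at row {int(bad.idxmax())}"
                ) from exc
        raise FormatError(str(exc)) from exc
    labels = df[label_column].to_numpy() if has_labels else None
    return RawRecording(list(channel_names), float(sample_rate), data, labels)


# ---------------------------------------------------------------------------
# filtering / epoching / gating / balancing


def design_bandpass(low: float, high: float, sample_rate: float) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass FIR taps, order set by the transition
    width max(low, 2 Hz)."""
    nyq = sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq} Hz)")
    trans = max(low, 2.0)
    numtaps = int(np.ceil(3.3 * sample_rate / trans))  # Hamming transition rule
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase, type I
    return signal.firwin(
        numtaps, [low, high], pass_zero=False, fs=sample_rate, window="hamming"
    )


def bandpass_fir(rec: RawRecording, low: float = 1.0, high: float = 50.0) -> RawRecording:
    """Zero-phase band-pass filter (FIR applied forward and backward).

    Forward-backward application squares the magnitude response and cancels
    the phase, so epoch labels stay aligned with the signal.
    """
    taps = design_bandpass(low, high, rec.sample_rate)
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return replace(rec, data=filtered)


def epoch_fixed(
    rec: RawRecording,
    length: float = 1.0,
    montage: Montage | None = None,
) -> EpochSet:
    """Cut a labelled recording into fixed-length non-overlapping epochs.

    Each epoch takes the majority per-sample label within its window, ties
    broken toward the label that starts earlier in the window; a trailing
    partial window is discarded.
    """
    if rec.labels is None:
        raise ValueError("recording has no labels; epoching requires them")
    L = length * rec.sample_rate
    if abs(L - round(L)) > 1e-9:
        raise ValueError("length x sample_rate must be an integer")
    L = int(round(L))
    n_epochs = rec.n_samples // L
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    data = rec.data[:, : n_epochs * L].reshape(rec.n_channels, n_epochs, L)
    data = np.transpose(data, (1, 0, 2))
    labels = []
    for e in range(n_epochs):
        window = rec.labels[e * L : (e + 1) * L]
        vals, first_pos = np.unique(window, return_index=True)
        counts = np.array([(window == v).sum() for v in vals])
        best = counts == counts.max()
        labels.append(vals[best][np.argmin(first_pos[best])])
    return EpochSet(
        data=data,
        labels=np.asarray(labels),
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        montage=montage,
    )


def ptp_gate(eps: EpochSet, max_ptp: float = 700.0, min_ptp: float = 1.0) -> EpochSet:
    """Drop epochs with any channel's peak-to-peak above ``max_ptp`` or below
    ``min_ptp`` (microvolts); decisions are logged in the provenance ledger."""
    if len(eps) == 0:
        raise ValueError("empty EpochSet")
    if max_ptp <= min_ptp:
        raise ValueError("max_ptp must exceed min_ptp")
    ptp = eps.data.max(axis=2) - eps.data.min(axis=2)  # (epochs, channels)
    too_big = (ptp > max_ptp).any(axis=1)
    too_small = (ptp < min_ptp).any(axis=1)
    out = eps.subset(~too_big, f"ptp > {max_ptp} uV")
    # remaining flat epochs, relative to the already-reduced set
    flat_kept = too_small[~too_big]
    return out.subset(~flat_kept, f"ptp < {min_ptp} uV")


def undersample_balance(eps: EpochSet, seed: int) -> EpochSet:
    """Equalize class counts by seeded uniform undersampling to the minority
    class size, preserving the original epoch order."""
    counts = eps.class_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes to balance")
    if min(counts.values()) == 0:
        raise ValueError("a class has zero epochs")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(eps), dtype=bool)
    for cls in counts:
        idx = np.flatnonzero(eps.labels == cls)
        keep[rng.choice(idx, size=n_min, replace=False)] = True
    return eps.subset(keep, "undersampled for class balance")
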