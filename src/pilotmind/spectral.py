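"""Band-power summaries of epoched EEG.

Per channel, the power spectral density is estimated with Welch's method
(one segment per 1 s epoch, Hann window) and averaged over all epochs of the
requested mental state; band power is the PSD integrated over each of the
five canonical EEG bands and reported in dB (10*log10 of power in uV^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochSet

__all__ = ["BANDS", "BandPowerMap", "band_power"]

BANDS = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class BandPowerMap:
    """Per-channel, per-band power in dB plus the underlying mean PSD."""

    state: str
    table: pd.DataFrame  # channels x bands, dB
    freqs: np.ndarray
    psd: np.ndarray  # (channels, freqs) mean PSD, uV^2/Hz

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def band_power(eps: EpochSet, state: str, bands: dict | None = None) -> BandPowerMap:
    """Band-integrated Welch PSD, in dB, for epochs of one mental state.

    Raises
    ------
    ValueError
        If no epoch carries the requested label.
    """
    bands = bands or BANDS
    mask = np.asarray(eps.labels) == state
    if not mask.any():
        raise ValueError(f"no epochs labelled {state!r}")
    X = eps.data[mask]  # (n, channels, L)
    L = X.shape[2]
    freqs, psd = signal.welch(
        X, fs=eps.sample_rate, window="hann", nperseg=L, noverlap=0, axis=2
    )
    mean_psd = psd.mean(axis=0)  # (channels, freqs)
    df = freqs[1] - freqs[0]
    cols = {}
    for name, (lo, hi) in bands.items():
        # rectangle integration over bins in (lo, hi]; the detrended DC bin
        # belongs to no band, so adjacent bands partition the bins evenly
        sel = (freqs > lo) & (freqs <= hi)
        power = mean_psd[:, sel].sum(axis=1) * df
        with np.errstate(divide="ignore"):
            cols[name] = 10.0 * np.log10(power)
    table = pd.DataFrame(cols, index=list(eps.channel_names))
    return BandPowerMap(state=state, table=table, freqs=freqs, psd=mean_psd)
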