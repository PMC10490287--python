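"""Synthetic sensor montage: named channels at unit-sphere scalp positions.

The layout reuses standard 10-20 electrode names for the first twenty
channels (the generator's default headset always includes Fp1, which doubles
as the surrogate ocular channel during blink removal) and falls back to a
deterministic Fibonacci arrangement on the upper hemisphere for any extras.
Positions only need to support distance-weighted interpolation and
frontal-weighted artifact injection, not anatomical accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# approximate unit-sphere positions (x = right, y = anterior, z = up) for the
# twenty 10-20 sites used by default
_TEN_TWENTY = {
    "Fp1": (-0.31, 0.95, 0.05),
    "Fp2": (0.31, 0.95, 0.05),
    "F7": (-0.81, 0.59, 0.05),
    "F3": (-0.45, 0.55, 0.70),
    "Fz": (0.00, 0.58, 0.82),
    "F4": (0.45, 0.55, 0.70),
    "F8": (0.81, 0.59, 0.05),
    "T7": (-1.00, 0.00, 0.05),
    "C3": (-0.59, 0.00, 0.81),
    "Cz": (0.00, 0.00, 1.00),
    "C4": (0.59, 0.00, 0.81),
    "T8": (1.00, 0.00, 0.05),
    "P7": (-0.81, -0.59, 0.05),
    "P3": (-0.45, -0.55, 0.70),
    "Pz": (0.00, -0.58, 0.82),
    "P4": (0.45, -0.55, 0.70),
    "P8": (0.81, -0.59, 0.05),
    "O1": (-0.31, -0.95, 0.05),
    "Oz": (0.00, -1.00, 0.05),
    "O2": (0.31, -0.95, 0.05),
}


@dataclass(frozen=True)
class Montage:
    """Ordered channel names with unit-sphere positions."""

    channel_names: tuple
    positions: np.ndarray  # (n, 3), unit rows
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.channel_names)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def position(self, name: str) -> np.ndarray:
        if name not in self._index:
            raise KeyError(f"channel {name!r} not in montage")
        return self.positions[self._index[name]]

    def index(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"channel {name!r} not in montage")
        return self._index[name]

    def frontal_weights(self) -> np.ndarray:
        """Per-channel blink loading: anterior (y > 0) channels, scaled so the
        most frontal channel has weight 1; non-frontal channels get 0."""
        y = np.clip(self.positions[:, 1], 0.0, None) ** 2
        return y / y.max() if y.max() > 0 else y


def make_montage(n_channels: int) -> Montage:
    """Deterministic montage of ``n_channels`` distinct positions incl. Fp1.

    Raises
    ------
    ValueError
        If ``n_channels < 4`` (interpolation needs at least 3 good channels
        besides the bad one).
    """
    if n_channels < 4:
        raise ValueError("montage requires at least 4 channels")
    names = list(_TEN_TWENTY)[:n_channels]
    pos = [np.asarray(_TEN_TWENTY[c], dtype=float) for c in names]
    n_extra = n_channels - len(names)
    for k in range(n_extra):
        # golden-angle spiral on the upper hemisphere, avoiding the pole
        z = 0.15 + 0.7 * (k + 0.5) / max(n_extra, 1)
        phi = k * np.pi * (3.0 - np.sqrt(5.0))
        r = np.sqrt(1.0 - z * z)
        names.append(f"EXT{k + 1}")
        pos.append(np.array([r * np.cos(phi), r * np.sin(phi), z]))
    P = np.vstack(pos)
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    return Montage(tuple(names), P)
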