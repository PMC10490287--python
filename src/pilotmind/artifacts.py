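"""Automated epoch repair and rejection, plus ICA-based blink removal.

The rejection stage learns a per-channel peak-to-peak threshold by
cross-validation: for each candidate threshold the mean of the training
epochs that pass it is compared with the pointwise median of the validation
epochs (a robust estimate of the clean signal), and the candidate with the
lowest validation error wins.  Applying the model marks channels above their
threshold as bad; epochs with too many bad channels are dropped, otherwise
the worst offenders are interpolated from neighbouring sensors by inverse
distance weighting.

Blink removal runs a seeded FastICA over the concatenated epochs, zeroes
every component whose time course correlates with the frontal surrogate
channel (Fp1) beyond a threshold, and reconstructs the signal.

The full cleaning pipeline is: amplitude gate -> reject/repair -> blink
removal -> reject/repair again (thresholds re-learned by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .montage import Montage
from .preprocess import EpochSet, ptp_gate

__all__ = [
    "RejectionModel",
    "learn_thresholds",
    "apply_reject",
    "interpolate_channel",
    "remove_blinks",
    "clean_pipeline",
]


class DegenerateThresholdError(RuntimeError):
    """Every candidate threshold rejects all epochs on some channel."""


class ICAConvergenceError(RuntimeError):
    """FastICA failed to converge within the iteration budget."""


@dataclass(frozen=True)
class RejectionModel:
    """Learned per-channel peak-to-peak thresholds plus repair policy.

    kappa: fraction of bad channels above which an epoch is dropped rather
    than repaired; rho: maximum channels interpolated per epoch.
    """

    tau: np.ndarray  # (n_channels,) uV
    channel_names: tuple
    kappa: float = 0.5
    rho: int = 4
    cv_folds: int = 5
    candidate_grid: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.tau) <= 0):
            raise ValueError("thresholds must be strictly positive")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must lie in (0, 1]")
        if not 0 <= self.rho < len(self.channel_names):
            raise ValueError("rho must be in [0, n_channels)")


def learn_thresholds(
    eps: EpochSet,
    grid,
    cv_folds: int = 5,
    seed: int = 0,
    kappa: float = 0.5,
    rho: int = 4,
    plateau: float = 0.05,
) -> RejectionModel:
    """Pick each channel's rejection threshold by cross-validation.

    For candidate t on channel c the CV score sums, over folds, the mean
    squared difference between (a) the average time course of training epochs
    whose channel-c peak-to-peak is <= t and (b) the pointwise median time
    course of the validation epochs.  The CV landscape is flat wherever
    candidates admit the same epochs, and shallowly noisy elsewhere, so the
    largest candidate scoring within ``plateau`` (relative) of the minimum is
    chosen — keep the most data unless rejecting clearly helps.
    Deterministic given ``seed``.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if len(eps) < 2 * cv_folds:
        raise ValueError(f"need at least {2 * cv_folds} epochs for {cv_folds}-fold CV")
    X = eps.data  # (n_epochs, n_channels, L)
    ptp = X.max(axis=2) - X.min(axis=2)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    tau = np.empty(eps.n_channels)
    for c in range(eps.n_channels):
        scores = np.zeros(grid.size)
        for tr, va in splits:
            target = np.median(X[va, c, :], axis=0)
            for gi, t in enumerate(grid):
                passing = tr[ptp[tr, c] <= t]
                if passing.size == 0:
                    scores[gi] = np.inf
                    continue
                est = X[passing, c, :].mean(axis=0)
                scores[gi] += np.mean((est - target) ** 2)
        if not np.isfinite(scores).any():
            raise DegenerateThresholdError(
                f"all epochs rejected at every candidate on channel "
                f"{eps.channel_names[c]}"
            )
        best = scores.min()
        tau[c] = grid[np.flatnonzero(scores <= best * (1.0 + plateau)).max()]
    return RejectionModel(
        tau=tau,
        channel_names=tuple(eps.channel_names),
        kappa=kappa,
        rho=min(rho, eps.n_channels - 1),
        cv_folds=cv_folds,
        candidate_grid=grid,
        seed=seed,
    )


def interpolate_channel(epoch: np.ndarray, bad: int, montage: Montage,
                        good: np.ndarray | None = None) -> np.ndarray:
    """Replace one channel by the inverse-square-distance weighted average of
    the good channels; all other rows are untouched."""
    epoch = np.asarray(epoch, dtype=float)
    n_ch = epoch.shape[0]
    if good is None:
        good = np.array([i for i in range(n_ch) if i != bad])
    good = np.asarray(good)
    if good.size < 3:
        raise ValueError("need at least 3 good channels to interpolate")
    if n_ch > montage.n_channels:
        raise KeyError("epoch has more channels than the montage")
    pos = montage.positions[:n_ch]  # rows assumed aligned with montage order
    d = np.linalg.norm(pos[good] - pos[bad], axis=1)
    w = 1.0 / np.maximum(d, 1e-6) ** 2
    w /= w.sum()
    out = epoch.copy()
    out[bad] = w @ epoch[good]
    return out


def apply_reject(
    eps: EpochSet, model: RejectionModel, montage: Montage
) -> tuple[EpochSet, pd.DataFrame]:
    """Apply a rejection model: drop, repair, or keep each epoch.

    A channel is bad in an epoch when its peak-to-peak exceeds its threshold.
    If the bad fraction exceeds ``model.kappa`` the epoch is dropped;
    otherwise the worst min(n_bad, rho) channels (largest threshold excess)
    are interpolated and the epoch kept.  Returns the updated EpochSet and a
    repair log with one row per input epoch.
    """
    if tuple(eps.channel_names) != tuple(model.channel_names):
        raise ValueError("model channels do not match epoch channels")
    missing = [c for c in eps.channel_names if c not in montage.channel_names]
    if missing:
        raise KeyError(f"montage lacks channels: {missing}")
    X = eps.data.copy()
    ptp = X.max(axis=2) - X.min(axis=2)
    bad_mask = ptp > model.tau[None, :]
    n_bad = bad_mask.sum(axis=1)
    drop = n_bad / eps.n_channels > model.kappa
    rows = []
    for e in range(len(X)):
        if drop[e]:
            decision, fixed = "dropped", []
        elif n_bad[e] > 0:
            excess = np.where(bad_mask[e], ptp[e] - model.tau, -np.inf)
            order = np.argsort(excess)[::-1][: min(n_bad[e], model.rho)]
            good = np.flatnonzero(~bad_mask[e])
            for ch in order:
                X[e] = interpolate_channel(X[e], int(ch), montage, good)
            decision = "repaired"
            fixed = [eps.channel_names[int(c)] for c in order]
        else:
            decision, fixed = "kept", []
        rows.append(
            {
                "epoch": int(eps.epoch_ids[e]),
                "decision": decision,
                "n_bad": int(n_bad[e]),
                "interpolated": ";".join(fixed),
            }
        )
    log = pd.DataFrame(rows)
    out = replace(eps, data=X)
    out = out.subset(~drop, "autoreject: bad-channel consensus exceeded")
    repaired_ids = log.loc[log["decision"] == "repaired", "epoch"].to_numpy()
    out.flags.loc[repaired_ids, "status"] = "repaired"
    out.flags.loc[repaired_ids, "reason"] = "channels interpolated"
    return out, log


def remove_blinks(
    eps: EpochSet,
    surrogate: str = "Fp1",
    r_thresh: float = 0.8,
    seed: int = 0,
    max_iter: int = 1000,
    strict: bool = False,
) -> tuple[EpochSet, int]:
    """ICA blink removal with a frontal channel as surrogate ocular reference.

    Epochs are concatenated in time, decomposed with seeded FastICA
    (component count = channel count), and every component whose absolute
    correlation with the surrogate channel's time course is >= ``r_thresh``
    is zeroed before reconstruction.  Returns the cleaned epochs (re-split)
    and the number of removed components.

    EEG backgrounds are close to Gaussian, so the full unmixing is only
    weakly identifiable and FastICA routinely stops at the iteration cap even
    though the strongly non-Gaussian ocular component is already separated.
    By default this is tolerated with a warning; ``strict=True`` raises
    `ICAConvergenceError` instead.
    """
    if surrogate not in eps.channel_names:
        raise KeyError(f"surrogate channel {surrogate!r} not present")
    s_idx = eps.channel_names.index(surrogate)
    n_e, n_ch, L = eps.data.shape
    X = eps.data.transpose(1, 0, 2).reshape(n_ch, n_e * L)
    ref = X[s_idx]

    ica = FastICA(
        n_components=n_ch,
        random_state=seed,
        max_iter=max_iter,
        whiten="unit-variance",
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(X.T)  # (samples, comps)
    if ica.n_iter_ >= max_iter:
        if strict:
            raise ICAConvergenceError(
                f"FastICA did not converge in {ica.n_iter_} iterations"
            )
        warnings.warn(
            f"FastICA stopped at the {max_iter}-iteration cap; proceeding "
            "with the current decomposition",
            ConvergenceWarning,
            stacklevel=2,
        )

    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    refc = ref - ref.mean()
    r = refc @ (S - S.mean(axis=0)) / (len(refc) * sd * max(refc.std(), 1e-12))
    remove = np.abs(r) >= r_thresh
    S[:, remove] = 0.0
    Xr = ica.inverse_transform(S).T
    out = replace(eps, data=Xr.reshape(n_ch, n_e, L).transpose(1, 0, 2))
    return out, int(remove.sum())


def clean_pipeline(
    eps: EpochSet,
    montage: Montage,
    grid=None,
    max_ptp: float = 700.0,
    min_ptp: float = 1.0,
    surrogate: str = "Fp1",
    r_thresh: float = 0.8,
    cv_folds: int = 5,
    seed: int = 0,
    relearn: bool = True,
) -> tuple[EpochSet, dict]:
    """Full cleaning chain: amplitude gate, reject/repair, blink removal,
    reject/repair again.  The second pass re-learns thresholds unless
    ``relearn`` is False.  Returns the cleaned EpochSet and a log dict."""
    if grid is None:
        grid = np.linspace(40.0, 800.0, 20)
    gated = ptp_gate(eps, max_ptp=max_ptp, min_ptp=min_ptp)
    model1 = learn_thresholds(gated, grid, cv_folds=cv_folds, seed=seed)
    stage1, log1 = apply_reject(gated, model1, montage)
    deblinked, n_removed = remove_blinks(
        stage1, surrogate=surrogate, r_thresh=r_thresh, seed=seed
    )
    model2 = (
        learn_thresholds(deblinked, grid, cv_folds=cv_folds, seed=seed)
        if relearn
        else model1
    )
    stage2, log2 = apply_reject(deblinked, model2, montage)
    logs = {
        "pass1": log1,
        "pass2": log2,
        "n_blink_components": n_removed,
        "model1": model1,
        "model2": model2,
    }
    return stage2, logs
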