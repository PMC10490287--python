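"""Threshold learning, epoch repair/rejection, interpolation, blink removal."""

import numpy as np
import pytest

import pilotmind as pm
from pilotmind.artifacts import (
    apply_reject,
    clean_pipeline,
    interpolate_channel,
    learn_thresholds,
    remove_blinks,
)
from pilotmind.preprocess import EpochSet

RNG = np.random.default_rng(42)
FS = 64.0
L = 64


def _epochs(data, labels=None, names=None):
    n, n_ch, _ = data.shape
    return EpochSet(
        data=data,
        labels=labels if labels is not None else np.repeat("NE", n),
        channel_names=names or [f"ch{i}" for i in range(n_ch)],
        sample_rate=FS,
    )


def _mixed_set(n_clean=40, n_art=10, n_ch=4, art_ptp=600.0):
    """Clean epochs (ptp <= ~100) plus artifact epochs (ptp >= 500) on ch0."""
    data = 10.0 * RNG.standard_normal((n_clean + n_art, n_ch, L))
    data = np.clip(data, -50, 50)
    art_idx = np.arange(n_clean, n_clean + n_art)
    for e in art_idx:
        data[e, 0, 10] = art_ptp / 2
        data[e, 0, 11] = -art_ptp / 2
    return _epochs(data), art_idx


GRID = np.array([25.0, 50.0, 150.0, 300.0, 450.0, 700.0, 1000.0])


class TestLearnThresholds:
    def test_threshold_lands_in_gap_between_clean_and_artifact(self):
        eps, _ = _mixed_set()
        model = learn_thresholds(eps, GRID, seed=0)
        assert 100.0 < model.tau[0] < 500.0

    def test_exhaustive_criterion_agrees(self):
        # independent oracle: evaluate the CV criterion for every candidate
        # by direct enumeration and check the learner picks an argmin
        from sklearn.model_selection import KFold

        eps, _ = _mixed_set(n_clean=20, n_art=5)
        model = learn_thresholds(eps, GRID, cv_folds=3, seed=1)
        X = eps.data
        ptp = X.max(axis=2) - X.min(axis=2)
        splits = list(KFold(3, shuffle=True, random_state=1).split(X))
        for c in range(eps.n_channels):
            scores = []
            for t in GRID:
                s = 0.0
                for tr, va in splits:
                    passing = [i for i in tr if ptp[i, c] <= t]
                    if not passing:
                        s = np.inf
                        break
                    est = X[passing, c, :].mean(axis=0)
                    s += np.mean((est - np.median(X[va, c, :], axis=0)) ** 2)
                scores.append(s)
            # chosen tau is the largest candidate on the CV-score plateau
            ok = [g for g, s in zip(GRID, scores) if s <= min(scores) * 1.05]
            assert model.tau[c] == max(ok)

    def test_all_clean_data_keeps_everything(self):
        mont = pm.make_montage(4)
        data = 10.0 * np.clip(RNG.standard_normal((40, 4, L)), -5, 5)
        eps = _epochs(data, names=list(mont.channel_names))
        model = learn_thresholds(eps, GRID, seed=0)
        ptp_max = (data.max(axis=2) - data.min(axis=2)).max(axis=0)
        assert (model.tau >= ptp_max).all()
        out, log = apply_reject(eps, model, mont)
        assert len(out) == len(eps)
        assert (log["decision"] == "kept").all()

    def test_seed_determinism(self):
        eps, _ = _mixed_set()
        t1 = learn_thresholds(eps, GRID, seed=9).tau
        t2 = learn_thresholds(eps, GRID, seed=9).tau
        assert np.array_equal(t1, t2)

    def test_empty_grid_rejected(self):
        eps, _ = _mixed_set(n_clean=10, n_art=0)
        with pytest.raises(ValueError, match="grid"):
            learn_thresholds(eps, [], seed=0)


class TestApplyReject:
    def _model(self, n_ch, tau=200.0, kappa=0.5, rho=2):
        return pm.RejectionModel(
            tau=np.full(n_ch, tau),
            channel_names=tuple(f"ch{i}" for i in range(n_ch)),
            kappa=kappa,
            rho=rho,
        )

    def test_single_bad_channel_repaired(self, montage20):
        data = 10.0 * RNG.standard_normal((3, 20, L))
        data[1, 0, 5] = 500.0
        names = list(montage20.channel_names)
        eps = _epochs(data, names=names)
        model = pm.RejectionModel(tau=np.full(20, 200.0),
                                  channel_names=tuple(names), kappa=0.5, rho=2)
        out, log = apply_reject(eps, model, montage20)
        assert len(out) == 3
        assert log.loc[1, "decision"] == "repaired"
        assert log.loc[1, "interpolated"] == names[0]
        # the repaired channel no longer exceeds the threshold
        assert out.data[1, 0].max() - out.data[1, 0].min() < 200.0

    def test_majority_bad_epoch_dropped(self, montage20):
        data = 10.0 * RNG.standard_normal((2, 20, L))
        data[0, :15, 5] = 500.0  # 15/20 channels bad
        names = list(montage20.channel_names)
        eps = _epochs(data, names=names)
        model = pm.RejectionModel(tau=np.full(20, 200.0),
                                  channel_names=tuple(names), kappa=0.5, rho=4)
        out, log = apply_reject(eps, model, montage20)
        assert len(out) == 1
        assert log.loc[0, "decision"] == "dropped"

    def test_log_covers_every_epoch_exactly_once(self, montage20):
        data = 10.0 * RNG.standard_normal((8, 20, L))
        names = list(montage20.channel_names)
        eps = _epochs(data, names=names)
        model = pm.RejectionModel(tau=np.full(20, 200.0),
                                  channel_names=tuple(names))
        _, log = apply_reject(eps, model, montage20)
        assert sorted(log["epoch"]) == list(range(8))
        assert set(log["decision"]) <= {"kept", "repaired", "dropped"}

    def test_channel_mismatch_rejected(self, montage20):
        eps = _epochs(RNG.standard_normal((4, 4, L)))
        model = self._model(5)
        with pytest.raises(ValueError, match="channels"):
            apply_reject(eps, model, montage20)


class TestInterpolation:
    def test_fixed_point_recovery(self, montage20):
        epoch = RNG.standard_normal((20, L))
        bad = 3
        good = np.array([i for i in range(20) if i != bad])
        d = np.linalg.norm(montage20.positions[good] - montage20.positions[bad],
                           axis=1)
        w = 1.0 / d**2
        w /= w.sum()
        epoch[bad] = w @ epoch[good]
        out = interpolate_channel(epoch, bad, montage20)
        assert np.allclose(out[bad], epoch[bad], rtol=1e-10)
        assert np.array_equal(out[good], epoch[good])

    def test_constant_field_reproduced_exactly(self, montage20):
        epoch = np.tile(np.sin(np.arange(L) / 5.0), (20, 1))
        out = interpolate_channel(epoch, 7, montage20)
        assert np.allclose(out[7], epoch[7], rtol=1e-12)

    def test_beats_zero_replacement_on_smooth_field(self, montage20):
        # field varying smoothly with scalp position
        t = np.arange(L) / FS
        field = np.array(
            [np.sin(2 * np.pi * 5 * t) * (1.0 + p @ [0.3, 0.5, 0.2])
             for p in montage20.positions]
        )
        bad = 4
        out = interpolate_channel(field, bad, montage20)
        err_interp = np.linalg.norm(out[bad] - field[bad])
        err_zero = np.linalg.norm(field[bad])
        assert err_interp < err_zero

    def test_too_few_good_channels_rejected(self, montage20):
        epoch = RNG.standard_normal((20, L))
        with pytest.raises(ValueError, match="good channels"):
            interpolate_channel(epoch, 0, montage20, good=np.array([1, 2]))


class TestRemoveBlinks:
    def _blinky_epochs(self, n=120, with_blinks=True):
        cfg = pm.SimConfig(
            class_durations={"NE": float(n)},
            artifact_spec=(
                pm.ArtifactSpec(blink_rate=0.3, muscle_rate=0, spike_rate=0,
                                flat_rate=0)
                if with_blinks
                else pm.ArtifactSpec.none()
            ),
            seed=33,
        )
        rec, truth = pm.simulate_recording(cfg)
        eps = pm.epoch_fixed(rec, montage=pm.make_montage(20))
        return eps, truth

    def test_blink_component_removed_signal_preserved(self):
        eps, truth = self._blinky_epochs()
        out, n_removed = remove_blinks(eps, seed=0)
        assert n_removed >= 1
        bt = truth.blink_trace[: len(eps) * eps.n_times]
        X = out.data.transpose(1, 0, 2).reshape(20, -1)
        for name in ("Fp1", "Fp2", "Fz"):
            i = eps.channel_names.index(name)
            assert abs(np.corrcoef(X[i], bt)[0, 1]) < 0.2
        # background sources survive: reconstructed signal keeps most energy
        X0 = eps.data.transpose(1, 0, 2).reshape(20, -1)
        occ = eps.channel_names.index("Oz")  # no blink loading
        assert np.corrcoef(X[occ], X0[occ])[0, 1] > 0.9

    def test_no_matching_component_is_identity(self):
        eps, _ = self._blinky_epochs(n=30, with_blinks=False)
        out, n_removed = remove_blinks(eps, r_thresh=0.999, seed=0)
        assert n_removed == 0
        rel = np.linalg.norm(out.data - eps.data) / np.linalg.norm(eps.data)
        assert rel < 1e-6

    def test_zero_threshold_removes_everything(self):
        eps, _ = self._blinky_epochs(n=30, with_blinks=False)
        out, n_removed = remove_blinks(eps, r_thresh=0.0, seed=0)
        assert n_removed == eps.n_channels
        assert np.linalg.norm(out.data) < 1e-3 * np.linalg.norm(eps.data)

    def test_missing_surrogate_rejected(self):
        eps = _epochs(RNG.standard_normal((30, 4, L)))
        with pytest.raises(KeyError, match="Fp1"):
            remove_blinks(eps)


class TestCleanPipeline:
    def test_second_pass_never_increases_epoch_count(self, small_sim):
        cfg, rec, _ = small_sim
        mont = pm.make_montage(cfg.n_channels)
        eps = pm.epoch_fixed(rec, montage=mont)
        cleaned, logs = clean_pipeline(eps, mont, seed=0)
        n_after_pass1 = (logs["pass1"]["decision"] != "dropped").sum()
        n_after_pass2 = (logs["pass2"]["decision"] != "dropped").sum()
        assert n_after_pass2 <= n_after_pass1 <= len(eps)
        assert len(cleaned) == n_after_pass2

    def test_flags_account_for_all_original_epochs(self, small_sim):
        cfg, rec, _ = small_sim
        mont = pm.make_montage(cfg.n_channels)
        eps = pm.epoch_fixed(rec, montage=mont)
        cleaned, _ = clean_pipeline(eps, mont, seed=0)
        assert len(cleaned.flags) == len(eps)
        dropped = (cleaned.flags["status"] == "dropped").sum()
        assert dropped + len(cleaned) == len(eps)
        # surviving epochs are flagged kept or repaired, never dropped
        surviving = cleaned.flags.loc[cleaned.epoch_ids, "status"]
        assert set(surviving) <= {"kept", "repaired"}
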