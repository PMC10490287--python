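# pilotmind

EEG-based detection of attention-related pilot performance-limiting states.

Flight crews can slip into mental states that degrade their handling of the
aircraft: channelized attention (CA, fixation on a single task), diverted
attention (DA), startle/surprise (SS), versus the normal baseline state (NE).
`pilotmind` implements an end-to-end pipeline that classifies these four
states from multichannel EEG: automated artifact rejection and repair,
Riemannian tangent-space feature extraction from xDawn-augmented spatial
covariance matrices, and a soft-voting ensemble of tree-based classifiers
evaluated under stratified 5-fold cross-validation. A seeded synthetic-EEG
generator with known class structure and annotated artifacts makes every
stage testable without downloading any data.

## The method

**Preprocessing.** Recordings (µV, CSV with a per-sample state label) are
band-pass filtered with a zero-phase FIR (1–50 Hz), cut into one-second
non-overlapping epochs, and gated on peak-to-peak amplitude: any channel
above 700 µV or below 1 µV drops the epoch. Remaining epochs pass through a
data-driven rejection stage: per-channel peak-to-peak thresholds are learned
by cross-validation (the mean of accepted training epochs is compared with
the robust median of validation epochs), bad channels are interpolated from
neighbours by inverse distance weighting, and epochs with too many bad
channels are dropped. Blinks are removed by seeded FastICA using the frontal
channel Fp1 as a surrogate ocular reference; the rejection stage then runs
once more. The dominant NE class is finally undersampled so all four states
are balanced.

**Features.** Each epoch's spatial covariance is symmetric positive-definite
(SPD) and lives on a curved manifold. With per-class xDawn spatial filters
(W_c, 6 per class) and class prototypes P_c, each epoch X becomes a
super-trial stack [W_1 P_1; …; W_4 P_4; W_1 X; …; W_4 X] whose shrunk
covariance is a 48 × 48 SPD matrix. These are mapped into the tangent space
at their Fréchet mean G under the affine-invariant metric,

    Exp_G(S) = G^{1/2} expm(G^{-1/2} S G^{-1/2}) G^{1/2}
    Log_G(P) = G^{1/2} logm(G^{-1/2} P G^{-1/2}) G^{1/2}
    d(P, Q)  = ||logm(P^{-1/2} Q P^{-1/2})||_F

and vectorized to n(n+1)/2 = 1176 Euclidean features, with √2 weighting on
off-diagonals so the vector norm equals the Frobenius norm. Fisher geodesic
discriminant filtering (a heavily regularized Fisher basis in tangent
coordinates, projected onto and back) discards directions without
between-class structure; PCA and one-way ANOVA F-scores then select the
final feature set.

**Classification.** Random forest (200 trees, entropy), extremely randomized
trees (200, entropy), gradient tree boosting (100 stages) and AdaBoost are
trained per fold of a stratified 5-fold plan; a hybrid soft-voting ensemble
takes the argmax of the mean RF/ERT/GTB class probabilities. Reports carry
per-class precision/recall/F1 (from one-vs-rest TP/FP/TN/FN counts), macro
averages, fold-wise F1 standard errors and row-normalized confusion
matrices. All fitted transforms (filters, mean, Fisher basis, PCA/ANOVA) are
learned on training folds only.

## Worked example

```python
import pilotmind as pm

cfg = pm.SimConfig(
    class_durations={"NE": 160.0, "CA": 40.0, "DA": 40.0, "SS": 40.0},
    seed=42,
)
rec, truth = pm.simulate_recording(cfg)
montage = pm.make_montage(cfg.n_channels)

rec = pm.bandpass_fir(rec, low=1.0, high=50.0)
epochs = pm.epoch_fixed(rec, montage=montage)
epochs = pm.ptp_gate(epochs, max_ptp=700.0, min_ptp=1.0)
cleaned, logs = pm.clean_pipeline(epochs, montage, seed=0)
balanced = pm.undersample_balance(cleaned, seed=0)
print("epochs after cleaning:", len(cleaned), "after balancing:", balanced.class_counts())

results = pm.MentalStateClassifier(balanced, seed=0).fit()
print(results.macro_table().round(1).to_string())
```

prints

```
epochs after cleaning: 269 after balancing: {'CA': 36, 'DA': 36, 'NE': 36, 'SS': 36}
          accuracy  precision  recall     f1
RF            97.2       97.3    97.2   97.2
ERT           99.3       99.3    99.3   99.3
GTB           92.4       92.5    92.4   92.3
AdaBoost      51.4       50.0    51.4   49.9
Voting       100.0      100.0   100.0  100.0
```

The 280-second synthetic recording is 57 % NE; the amplitude gate and the
two rejection passes drop the epochs carrying injected spikes and repair
those with isolated bad channels, undersampling balances the survivors, and
the ensemble separates the four covariance-defined states almost perfectly
(the classes here are cleanly separated on the SPD manifold — pairwise
Riemannian distances ≥ 1.3 between class covariances). `results.report("Voting")`
holds the per-class table and confusion matrix;
`results.plot_confusion("Voting")` draws it.

The same flow is available from the shell:

```sh
pilotmind simulate --out sim --seed 4
pilotmind preprocess --in sim/recording.csv --out eps.npz --balance-seed 0
pilotmind repair --epochs eps.npz --out clean.npz --report repair.json
pilotmind train --epochs clean.npz --out report.json --seed 0
pilotmind spectra --epochs clean.npz --state CA --out bandpower.csv
```

## Limitations

The synthetic benchmark defines class identity purely through stationary
spatial covariance, which is the structure the feature pipeline is built to
detect; real pilot EEG is messier (non-stationarity, inter-subject
variability, mislabelled transitions), so synthetic scores are an upper
bound, not a forecast. See `docs/methods.md` for modelling assumptions,
parameter defaults and numerical choices.
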