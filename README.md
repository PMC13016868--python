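# physofr

Hierarchical scalar-on-function regression for trial-based olfactory
psychophysiology.

When people smell an odor, what they report — how pleasant, warm, or
intense it is — depends on the odorant itself, on stable individual rating
tendencies, and on the body's moment-to-moment response: respiration depth,
heart-rate dynamics, and facial muscle activity.  `physofr` is for
researchers who want to disentangle these sources on a trial-by-trial
basis.  It implements the full analysis chain:

1. **Signal preprocessing** — channel-specific zero-phase filtering of
   500 Hz respiration / ECG / facial-EMG recordings, trial epoching around
   odor onset, baseline correction, respiration-correction of heart rate,
   block-mean downsampling to 5 Hz, per-participant normalization.
2. **Functional QC** — Fraiman–Muniz curve depth per channel, removal of
   the 1% least-typical trials, and a per-odor retention rule for
   participants.
3. **Perceptual dimensions** — Bartlett/KMO diagnostics, factor-count
   selection, varimax-rotated EFA of the 8 rated properties, trial-wise
   regression factor scores.
4. **The model** — for each perceptual dimension *y* (valence,
   temperature, intensity):

   *y*ᵢ = α_odor(i) + γ·1{second half} + u_participant(i) +
   Σ_c ∫₀⁶ x_{ic}(t)[β_c(t) + b_{p(i),c}(t)]dt + εᵢ

   with penalized-spline coefficient functions β_c(t) (group level) and
   factor-smooth deviations b_{p,c}(t) (individual level), all smoothing
   parameters chosen by REML.
5. **Inference** — whole-smooth Wald-like tests, analysis-of-deviance F
   comparisons, a sequential adjusted-R² variance decomposition (odor vs.
   rating tendency vs. group/individual physiology), marginal per-odor
   estimates with confidence intervals, and train/test fit metrics.

A synthetic-data generator emulates the whole study design (41
participants × 96 trials = 6 odorants × 8 properties × 2 repetitions, four
physiological channels at 500 Hz) with known ground truth, so every stage
is testable without any data download.

## Worked example

```python
import physofr as pf
from physofr import sofr, inference as inf

# simulate a small study and fit the valence model
design = pf.generate_design(n_participants=6, seed=7)
truth  = pf.simulate_truth(pf.SimulationConfig(n_participants=6), seed=1)
signals, scores = pf.simulate_model_data(design, truth, seed=2)

basis = sofr.build_basis(pf.analysis_grid(), K=8)
des   = sofr.assemble_design(scores, signals,
                             scores["latent_valence"].to_numpy(),
                             sofr.ModelSpec(), basis)
fit   = sofr.fit_reml(des)

w = inf.smooth_wald_test(fit, "group:respiration")
print(f"respiration: edf={w.edf:.2f}, F({w.df1})={w.statistic:.2f}, p={w.p:.2g}")

m = inf.fit_metrics(fit, des.y, des.X)
print(f"train R2={m.r2:.3f}  adj R2={m.adj_r2:.3f}  RMSE={m.rmse:.3f}")
```

prints (seed-exact):

```
respiration: edf=4.24, F(5)=22.73, p=1.1e-20
train R2=0.680  adj R2=0.654  RMSE=0.593
```

The respiration coefficient function is strongly nonzero (the generator
places a positive inhalation-peak effect on valence), and the model
explains ~68% of the latent-score variance at this noise level.  The
`edf≈4` says the fitted β(t) is clearly nonlinear in time;
`partial_effect` returns the full curve with its 95% pointwise band.

The same workflow from a shell, end to end (simulation → preprocessing →
QC → EFA → fits → decomposition):

```bash
physofr report --seed 1 --n-participants 8 --out runs/demo
```

which writes `design.csv`, staged epoch containers, `loadings.csv`,
`metrics.csv`, `wald_tests.csv`, `partial_effects.csv`,
`marginal_estimates.csv`, `decomposition.csv` and a manifest carrying the
config hash.  Stage subcommands (`simulate`, `preprocess`, `qc`,
`factors`, `fit`, `decompose`) resume a run directory stage by stage.

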