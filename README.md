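# fermfuse

Feature-level fusion of electronic-nose and near-infrared (NIR)
spectroscopy data for monitoring the stage of a solid-state
fermentation (SSF) process.

Industrial SSF of protein feed runs for about a week through lag,
exponential and stationary phases, and process control hinges on
recognizing the current stage quickly and non-invasively. Two
instruments see complementary aspects of the fermenting substrate: an
array of 11 cross-sensitive gas sensors (an electronic nose)
fingerprints the volatile compounds, while an FT-NIR spectrometer
records 1557-point log(1/R) spectra over 10,000-4,000 cm⁻¹ that track
the substrate chemistry. Neither signal alone tells the whole story;
`fermfuse` implements the full intermediate-level fusion workflow that
combines them, plus a synthetic-study generator so the whole pipeline
is testable end to end without instrument data.

## Method

For each sample the e-nose recording is reduced to the maximum response
of each sensor over the 120 s sampling window, and the NIR spectrum is
corrected by the standard normal variate transform,
`SNV(x) = (x − mean(x)) / sd(x)`. After column z-scoring (training
statistics only), each modality is compressed by PCA; the concatenated
PC scores are unmixed by a fixed-point ICA (model `x = A s`, estimate
`y = W x`) into independent components that strip the redundancy
between the two blocks. Classification is by **BP_AdaBoost**: T = 10
rounds of boosting over 3-layer backpropagation networks (10 sigmoid
hidden units, one-of-7 dummy outputs). Round *t* trains a weak net
under the sample-weight distribution *D_t*, flags samples whose output
deviation exceeds 0.2, accumulates their weights into the weighted
error *e_t*, votes the net with *a_t = ½ ln((1−e_t)/e_t)*, and bumps
flagged weights by *k* = 1.1 before renormalizing. The strong
prediction is the vote-weighted average of the weak outputs with a 0.5
decision cutoff (samples below it are UNASSIGNED and count as errors).
Every model order — PCs per modality, then the number of ICs — is
chosen by leave-one-out cross-validation at the first local maximum of
the identification-rate curve. Models are trained on fermentation runs
1-3 (105 samples under the default 4 × 7 × 5 design) and validated on
run 4 (35 samples), so validation always probes an unseen run.

See `docs/methods.md` for the model details, the synthetic-study
generator, and the design decisions.

## Worked example

```sh
fermfuse run-study --seed 3 --out-dir results/
```

generates the default modality-split synthetic study (140 samples),
selects component counts by LOOCV, trains the three models and prints:

```
nirs    latent=3 train=87/105 (82.86%) validation=28/35 (80.00%)
enose   latent=1 train=45/105 (42.86%) validation=15/35 (42.86%)
fusion  latent=2 train=90/105 (85.71%) validation=29/35 (82.86%)
```

Each row is one model: the number of latent vectors (PCs for the
single-technique models, ICs for the fused model) its LOOCV selection
chose, and its identification rate — 100 × correct/total — on the
training and validation sets. In this study the e-nose alone resolves
only the early days (its analytes saturate once the exponential phase
ends), the spectra blur at both ends of the process, and the fused
model recovers all stages except part of the day-5/day-6 pair, which is
nearly identical by construction once the fermentation reaches the
stationary phase. `results/` also receives `report.json` (selection
curves, confusion matrices with the UNASSIGNED column, per-class rates)
and `comparison.csv`.

The same workflow is available stepwise (`fermfuse simulate`,
`preprocess`, `select`, `train`, `evaluate`) and as a library
(`fermfuse.pipeline.run_study`, and the individual modules
`synthetic_data`, `preprocessing`, `decomposition`, `bp_adaboost`).

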