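# fhrfusion

Mixed-data-type classification of fetal heart rate (FHR) recordings:
quantitative cardiotocography (cCTG) features feed an MLP, signal-to-image
encodings of the same trace feed a CNN, and the two branches are fused
into a single two-class (healthy vs. pathological) classifier.  Everything
— preprocessing, the 15-feature suite, eight image encoders, the neural
network engine, the evaluation protocol, and a ground-truth synthetic data
generator — is implemented in plain NumPy/SciPy and is deterministic under
a seed.

## The science in one paragraph

Antepartum cardiotocography records the fetal heart rate at 2 Hz.
Clinicians and computerized CTG systems read it through a small set of
quantitative regressors — short- and long-term variability of the
interbeat intervals (STV, DELTA, II, LTI), spectral power in the
low/mid/high frequency bands of the autonomic range, approximate entropy,
the excursion-free baseline, and counts of accelerations and
decelerations.  These features discard the signal's morphology, so a
second, complementary view re-expresses the same 20-minute trace as
images — Gramian angular fields, Markov transition fields, recurrence
plots, wavelet scalograms, spectrograms and persistence spectra — that a
small CNN can read directly.  `fhrfusion` implements both views and their
fusion, plus a synthetic FHR generator with fully logged ground truth so
every stage of the pipeline is testable end to end.  See
[docs/methods.md](docs/methods.md) for the full model, every parameter
with units and defaults, and limitations.

## The model

- **Preprocessing** — validity range [50, 220] bpm; gaps shorter than
  15 s linearly interpolated, longer ones spliced out; non-overlapping
  20-minute segments of exactly 2400 samples; segments with > 10%
  interpolated samples rejected.
- **MLP branch** — 15 normalized features → 500 → 250 → 150 → 50 → 2
  softmax, with dropout and L1/L2 regularization.
- **CNN branch** — a 64×64×3 stack of image encodings (default GADF, PS,
  PSP) → two conv/batch-norm/max-pool blocks (16 and 32 filters of 5×5)
  → dense 64 → dense 16 → 2 softmax.
- **Fusion** — the branch outputs are concatenated into a 128-unit head
  with a 2-way softmax; training uses Adam (lr 1e-4, hyperbolic decay),
  batch size 32, early stopping with best-weight restoration.
- **Evaluation** — full confusion-matrix metric panel (ACC, TPR, TNR,
  PPV, NPV, FPR, FNR, FDR, AUC), a repeated-training protocol on a fixed
  stratified split, and Welch t-tests for comparing architectures.

## Worked example

Generate synthetic records, extract the feature suite, and compare the
classes (`python examples/02_feature_suite.py`):

```text
20 segments -> 20 feature rows

example segment syn003_0_0000_0 (label 0):
               DELTA =    28.1147
                  II =     0.7139
                 STV =     7.0002
                 LTI =    11.5782
                  LF =    53.2358
                  MF =    12.7812
                  HF =     5.0344
               ratio =     2.9881
                ApEn =     1.3347
                FHRB =   156.1189
        small_accels =     0.0000
        large_accels =     1.0000
              decels =     0.0000
    gestational_week =    34.5000
        maternal_age =    28.2000

per-class feature means (healthy=0, pathological=1):
             STV: healthy    8.423   pathological    6.461
           DELTA: healthy   40.762   pathological   31.703
             LTI: healthy   17.921   pathological   12.659
              LF: healthy   73.424   pathological   41.935
              MF: healthy   18.810   pathological   11.306
              HF: healthy    7.042   pathological    4.158
            ApEn: healthy    1.275   pathological    1.223
```

Encode a segment with all eight image methods
(`python examples/03_image_encodings.py`):

```text
 encoder      shape    min    max    mean  nonzero%
     CWT   (64, 64)   0.00   0.98   0.035    100.0%
    GASF   (64, 64)   0.00   1.00   0.193    100.0%
    GADF   (64, 64)   0.00   1.00   0.500    100.0%
     MTF   (64, 64)   0.00   1.00   0.167     48.4%
       S   (64, 64)   0.00   1.00   0.111     98.4%
       R   (64, 64)   0.00   1.00   0.213     21.3%
      PS   (64, 64)   0.00   0.96   0.018    100.0%
     PSP   (64, 64)   0.00   1.00   0.016     19.8%

default stack ('GADF', 'PS', 'PSP') -> array (64, 64, 3)
```

Train and evaluate the combined model
(`python examples/04_train_and_evaluate.py`):

```text
generating 800 records ...
796 segments, images (796, 64, 64, 3)

training combined MLP+CNN (max 15 epochs, Adam lr 0.0001, early-stop patience 2) ...
ran 15 epochs; final train acc 0.902, val acc 0.906

held-out confusion: TP=70 FN=10 FP=5 TN=75
metric panel (positive class = pathological):
   ACC = 0.906
   TPR = 0.875
   TNR = 0.938
   PPV = 0.933
   NPV = 0.882
   FPR = 0.062
   FNR = 0.125
   FDR = 0.067
   AUC = 0.956
```

This run takes about five minutes on one CPU.

The example scripts in `examples/` walk through the pipeline in order:
simulation and preprocessing (01), the feature suite (02), the image
encodings (03), and training/evaluation (04).

## Command-line interface

The same pipeline is scriptable as files-on-disk stages:

```bash
fhrfusion simulate   --config cfg.yaml --out-dir raw/
fhrfusion preprocess --config cfg.yaml --in-dir raw/ --out-dir segments/
fhrfusion features   --config cfg.yaml --in-dir segments/ --out features.csv
fhrfusion encode     --config cfg.yaml --in-dir segments/ --out-dir images/
fhrfusion train      --config cfg.yaml --features features.csv --out-dir run/
fhrfusion evaluate   --config cfg.yaml --features features.csv --out runs.csv
fhrfusion report     --runs runs.csv
```

All stages are driven by one validated YAML configuration
(`fhrfusion.config.PipelineConfig`; any file section overrides the
defaults, unknown keys are rejected).

## Reproducing results

Everything is seeded: the same seed produces bit-identical synthetic
records, initial weights and training curves on a single thread.

- `pytest` runs the full suite.  `tests/test_acceptance.py` holds the
  package to its headline claims: the published-style metric-panel
  arithmetic, structural constants, brute-force/closed-form oracles for
  ApEn, the Gramian/Markov/recurrence encoders and the spectrogram
  Parseval identity, encoder and metric invariants, exact recovery of
  injected events from synthetic records, and an end-to-end check that
  the combined model beats both 0.75 accuracy and a label-permutation
  null on held-out synthetic data.
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the package's main quantities from scratch and writes them
  as JSON (value and sample size per entry).  The end-to-end portion
  trains the combined model on 400 records per class and takes the bulk
  of the runtime (about 6 minutes total on one CPU).  With `--seed 1`
  the headline entries come out as: `combined_heldout_accuracy` 0.9245
  (n = 159), `permutation_null_accuracy` 0.5283 (averaged over 3
  permutation draws), `exact_event_recovery_fraction` 1.0 (n = 30),
  `apen_oracle_abs_gap` 2.3e-14, and `parseval_max_rel_err` 5.3e-16.

The numbers shown in this README are verbatim program output; rerunning
the commands above with the seeds baked into the scripts reproduces them
exactly.
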