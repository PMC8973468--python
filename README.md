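# pupilload

Task-evoked pupillary response (TEPR) analysis for digit-span working-memory
experiments: preprocessing of raw pupil-diameter traces, seven per-trial
pupil-size features, subject-level mixed-model tests of task-difficulty
effects, and exhaustive wrapper feature selection for classifying trial
difficulty. A synthetic-data generator emulates the study design (2 s
fixation, then 3/5/8 digits at one per second for low/medium/high load), so
the entire pipeline runs, and is tested, without any recordings.

The package is for cognitive-pupillometry researchers who want a tested,
reproducible implementation of the standard TEPR feature set and the
difficulty analyses built on it.

## The model in brief

Each trial is summarised against its own prestimulus baseline
BLPS = mean prestimulus diameter (mm). With stimulus-phase diameters
PS_1..PS_n at times t_1..t_n:

| feature | definition |
|---|---|
| MPDC | (1/N)·ΣPS_i − BLPS |
| PCPS_i, APCPS | (PS_i − BLPS)/BLPS, and its mean |
| PPD, PD | max PS_i, and PPD − BLPS |
| E_pupil | −Σ p_i log₂ p_i over 0.01 mm diameter bins |
| TTP | time of the (first) peak sample |
| PDS | arctan of the OLS slope of PS vs t from onset through the peak |

Per feature, a linear mixed model y ~ difficulty + (difficulty | subject)
(REML; simplified to a random intercept when singular) is tested with a
likelihood-ratio test (ML refits, χ² with 2 df), followed by Tukey-style
pairwise contrasts with a single-step max-|z| family adjustment and a refit
after screening |standardised residual| > 3. For classification, all
2⁷ − 1 = 127 feature subsets × 7 classifier families (SVM linear/RBF/sigmoid,
LinearSVC, LDA, decision tree, random forest) are evaluated under stratified
5-fold CV and ranked by macro F1 from the pooled confusion matrix.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
and write their tables to `results/analysis/`:

```sh
python analysis/01_simulate_study.py    # 24 subjects x 36 trials, 50 Hz traces
python analysis/02_extract_features.py  # clean, reject, extract 7 features
python analysis/03_mixed_models.py      # LRT + pairwise contrasts per feature
python analysis/04_classify_difficulty.py  # 889-configuration wrapper search
```

`02_extract_features.py` prints the per-level feature means:

```
              BLPS    MPDC   APCPS      PD  E_pupil     TTP     PDS
difficulty
low         4.0180  0.0633  0.0160  0.2561   4.7160  3.0346  0.0451
medium      4.0185  0.1268  0.0321  0.3839   5.1542  4.7485  0.0543
high        4.0186  0.2371  0.0599  0.6005   5.7581  7.6577  0.0623
```

Baseline pupil size is flat across difficulty (fixation precedes the task),
while every dilation feature increases with memory load: mean dilation
roughly doubles per level, and the peak arrives later because encoding
lasts longer. `03_mixed_models.py` turns this into the formal tests:

```
feature        chi2  df        p    random
   BLPS    0.474503   2 7.89e-01 intercept
   MPDC  134.212475   2 7.18e-30     slope
  APCPS   87.190107   2 1.17e-19     slope
     PD  109.035067   2 2.11e-24     slope
E_pupil  127.116166   2 2.50e-28     slope
    TTP 1880.764818   2 0.00e+00 intercept
    PDS  221.721551   2 7.14e-49 intercept
```

The `random` column records the per-feature random structure: features
whose subject-level load response genuinely varies (MPDC, APCPS, PD,
E_pupil) retain the random difficulty effects, while BLPS, TTP and PDS
simplify to a random intercept when the slope covariance is a boundary
fit.

All six dilation features are significant at p < 0.001 and the baseline is
not — the signature pattern of a task-evoked (rather than tonic) load
response. The MPDC contrasts quantify the effect: medium−low 0.064 mm,
high−low 0.174 mm, high−medium 0.110 mm (all adjusted p ≪ 0.001).

`04_classify_difficulty.py` ranks all 889 classifier × subset
configurations; on this synthetic study the best model reaches macro
F1 = 0.978 (a random forest on {BLPS, APCPS, E_pupil, PDS}), against a
permuted-label best of 0.382 over the same 889 configurations (the
selection-optimism floor around the 1/3 chance level) and 0.923 for the
same model under leakage-safe subject-grouped CV. Synthetic traces are
cleaner than real recordings, so these scores are upper-end — the
informative comparisons are against the permutation baseline and between
CV schemes, not the absolute values.

The same stages are scriptable via the CLI (`pupil-load simulate`,
`extract`, `stats`, `classify`, `run`) on the CSV contracts documented in
the module docstrings, e.g.:

```sh
pupil-load simulate --seed 1 --out traces.csv
pupil-load extract --traces traces.csv --out features.csv
pupil-load classify --features features.csv --k 5 --seed 7 --out ranking.csv
```

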