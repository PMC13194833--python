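# relconn

Reliability-screened resting-state EEG connectivity analysis: directed and
phase-based connectivity estimators, MST-guided network binarization,
directed graph indices, ICC(3,k) test-retest screening and linear
mixed-effects group inference — with a synthetic-cohort generator whose
known ground truth makes every stage verifiable by parameter recovery.

## The problem

Resting-state EEG connectivity studies compare network organization between
groups (here: an occupationally exposed group, "Miners", versus matched
controls) across canonical frequency bands.  Results hinge on three fragile
choices: the connectivity estimator, the artifact-removal strategy, and the
stability of epoch-level estimates.  This package implements the complete
comparative workflow:

1. **Simulate** two groups of subjects as stable MVAR processes
   `x_t = Σ_k A_k x_{t−k} + e_t` with known directed coupling, observed
   through a zero-lag mixing matrix (volume-conduction surrogate), with
   line-noise, blink and EMG artifacts, and a controllable topology shift in
   the "Miners" group.
2. **Preprocess** each recording into 40 non-overlapping 6-s epochs (10-s
   discard), filter (50 Hz notch → 60–100 Hz band-stop → band-pass FIR) and
   clean with ASR (eigenspace variance thresholding of sliding windows) or
   ICA (FastICA with kurtosis/amplitude rejection).
3. **Estimate connectivity** per epoch and band:
   * DTF from a BIC-selected MVAR fit,
     `DTF_{j→i}(f) = |H_ij(f)|² / Σ_k |H_ik(f)|²` with
     `H(f) = [I − Σ_k A_k e^{−i2πfk/f_s}]^{−1}`;
   * iCOH, the band-mean `|Im(S_ij/√(S_ii S_jj))|`;
   * wPLI, `|E[Im S_ij]| / E[|Im S_ij|]` over within-epoch Welch segments.
4. **Binarize** at a fixed 15% density, seeding with the maximum-weight
   spanning tree so every network is connected and all networks share the
   same edge count.
5. **Score** six directed graph indices: modularity Q, global and local
   efficiency GE/LE, clustering coefficient CC, transitivity T and out–in
   degree assortativity R.
6. **Screen and infer**: ICC(3,k) across the 40 epochs (epochs as raters,
   subjects as targets) selects reliable cells (ICC ≥ 0.60); those enter the
   mixed model `Value ~ Group + (1 | Subject)` with Benjamini–Hochberg FDR
   correction and Cohen's f² effect sizes, plus Pearson correlations with
   psychometric scores.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import relconn

cfg = relconn.RunConfig(
    seed=1, n_per_group=12, states=("EC",), n_channels=12,
    bands=("full",), measures=("DTF",), cleanings=("ASR",),
    density=0.15, p_max=5)
res = relconn.run_pipeline(cfg)
print(res.reliability.query("index_name == 'CC'")[["group", "icc", "label"]])
print(res.lme.query("index_name == 'CC'")[["beta1", "ci_low", "ci_high", "p_fdr", "f2"]])
```

Output (seed 1):

```
     group       icc      label
0  Control  0.888321  excellent
6   Miners  0.712488       good
      beta1    ci_low   ci_high     p_fdr        f2
0 -0.061185 -0.085667 -0.036704  0.000002  0.132276
```

The clustering coefficient is reliable across epochs in both groups (ICC
0.89 / 0.71, i.e. good-to-excellent), so it passes the ICC ≥ 0.60 screen.
The mixed model then recovers the generator's ground truth — the "Miners"
cohort was built with half of its within-module coupling edges dispersed to
cross-module pairs, breaking its local cliques — as a negative group effect
on CC (β₁ = −0.061, 95% CI [−0.086, −0.037]) that survives FDR correction
(p_c ≈ 2·10⁻⁶) with a medium-sized Cohen's f² of 0.13.

The same pipeline is available from the shell:

```bash
relconn run-all --config cfg.yaml --seed 1 --out results/
relconn compare-cleaning --seed 1 --out ratios.csv   # ASR vs ICA power ratios
relconn simulate --seed 1 --out cohort/              # recordings + ground truth
```

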