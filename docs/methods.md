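# Methods

`relconn` implements a reliability-screened analysis of directed functional
connectivity in resting-state EEG, together with a synthetic-cohort generator
whose ground truth makes every stage verifiable by parameter recovery.  This
note records the models, the parameter choices that matter, the numerical
conventions, and the limits of what the synthetic validation shows.

## Generative model (synthetic cohorts)

Each subject's EEG is a stable multivariate autoregressive (MVAR) process
observed through an instantaneous mixing matrix:

    x_t = sum_{k=1..p} A_k x_{t-k} + e_t,      y_t = M x_t

with `e_t ~ N(0, Σ_e)` and `M` a unit-diagonal, distance-decaying matrix that
stands in for volume conduction.  MVAR-plus-zero-lag-mixing is exactly the
model class the directed transfer function assumes, so DTF estimates can be
compared against the analytic DTF of the generating coefficients.

The group template (`default_template`) uses 20 channels in the 10-20
montage at 500 Hz, two modules (anterior/posterior halves), and an
oscillatory self-model per channel (lag coefficients 0.5, −0.15).  Within
each module the channels are partitioned into cliques of 4 that are
mutually (bidirectionally) coupled — the local, segregated circuits that
give the healthy template its high directed clustering (true Fagiolo CC
around 0.5–0.6) — plus sparse random background coupling (probability 0.05
within and across modules; coefficients ≈ 0.25 at lag 1).  Volume
conduction is an off-diagonal mixing weight of 0.2 decaying with channel
distance.  The template is rescaled, if necessary, until the companion
spectral radius is ≤ 0.9; every per-subject spec is re-checked and rejected
if unstable.  The template's structure is pinned by a separate
`template_seed` (default 0): the emulated population is a fixed scenario,
while the run seed draws the cohort realization (subjects, innovations,
artifacts) — the standard replication design for simulation studies.

A design point worth recording: with *fixed-density* thresholding, simply
deleting true coupling edges does **not** lower the binarized network's
clustering — the freed slots are filled by the next-strongest DTF weights,
which are dominated by indirect (transitive-closure) flows and therefore
*add* triangles.  The clustering contrast between groups must instead come
from a redistribution of coupling at unchanged density, and the template
must be triangle-rich for any contrast to exist.  Both observations shaped
the defaults below.

Per-subject variability has two components, both chosen to reproduce the
regime in which reliability screening is meaningful (test-retest ICC of
DTF-derived indices in the good-to-excellent range, with group effects of
the large size this kind of study reports):

* **edge rewiring** — 20% of the template's cross-channel edges are
  relocated to previously absent ordered pairs of the same type
  (within-module edges stay within a module, cross-module stay cross),
  giving each subject an individual connectome with the group's modular
  statistics.  Coefficient jitter alone leaves all subjects with an
  identical topology, which collapses the between-subject variance of
  topology-dependent indices and makes ICC degenerate; individual topology
  is also the biologically realistic assumption.
* **coefficient jitter** — each coupling coefficient is scaled by
  `1 + 0.2·N(0,1)`.

The "Miners" group template disperses half of its within-module coupling
edges to absent cross-module pairs (`GroupEffect`, mode `"disperse"`):
the edge count is preserved but the cliques are broken, lowering the true
directed clustering (reduced segregation) — the ground-truth effect the
end-to-end recovery checks.  A `"remove"` mode (edge deletion, density
reduction) is available as an alternative; it is not the default for the
reason above.  Removing all cross-channel edges is rejected as degenerate.

Artifacts are injected at Poisson onsets with fixed documented morphologies:
a 50 Hz sinusoid (5 µV), frontal-weighted blink transients (raised-cosine
squared kernel, 0.4 s, 80 µV at Fp1/Fp2, rate 0.2/s) and 60–100 Hz
band-passed noise bursts (Hann envelope, 0.3 s, 20 µV, rate 0.1/s).  Only
their spectral/statistical signatures matter to the cleaners; no forward
head model is attempted.

Psychometric scores are linear-Gaussian around group anchors (means/SDs of
the emulated study's summary table); the recall score is constructed with an
exact in-sample correlation of −0.6 with the subject's true clustering
level, so the correlation stage can be validated by sign and power.

## Preprocessing

Recordings are epoched after a 10-s discard into 40 non-overlapping 6-s
epochs (240 s analysis window).  The filter chain per epoch is: 50 Hz notch
(2nd-order IIR, Q = 35), 4th-order Butterworth band-stop 60–100 Hz, then a
linear-phase FIR band-pass at the band edges — all applied forward-backward
(zero phase), since phase distortion would corrupt the phase-based
estimators.  The FIR is a Kaiser-window design targeting 80 dB stopband
attenuation with a transition band of 25% of the lower edge (1 Hz floor);
tap count is capped at a third of the epoch length so that zero-phase
application remains well-posed on 6-s epochs, which relaxes the realized
transition for the delta band.  Band edges: delta 0.5–4, theta 4–8, alpha
8–13, beta 13–30, gamma 30–60, full 0.5–60 Hz (configurable).

**ASR** estimates the epoch covariance, eigendecomposes it once, and slides
0.5-s windows with 50% overlap.  A window is flagged when any per-component
variance exceeds `mean(λ) + 5·std(λ)`; flagged windows are reconstructed
with the offending components zeroed, retaining at least
`floor(0.66·n_channels)` dimensions, and corrections are blended with a
raised-cosine taper so unflagged samples are bit-identical to the input.  A
per-channel variant thresholds window variances against a robust
(median/MAD) center and scale — a lone burst must not inflate its own
threshold — and rescales flagged windows; it is selectable via
`asr.mode = "per_channel"`.

**ICA** uses FastICA with as many components as channels and rejects
components with |excess kurtosis| > 1.25 (the threshold is read as *excess*
kurtosis: Gaussian = 0; a raw-kurtosis reading of 1.25 would reject
everything) or a peak amplitude above 4 component SDs.  The convergence
tolerance is 0.05 on the unmixing update with up to 5 seeded restarts:
near-Gaussian epochs make the FastICA rotation weakly identifiable, and the
rejection criteria depend only on gross component statistics, not on a
finely resolved rotation.  Rejected components are zeroed before
back-projection, which can leave epochs rank-deficient (handled below).

The power ratio (mean-square of the cleaned epoch over the raw epoch, per
channel) is the cleaning-comparison summary.  Because the raw epoch is
unfiltered, the no-artifact baseline of this ratio is the in-band power
fraction (≈ 0.5 for these broadband processes), not 1.

## Connectivity estimators

**DTF.**  Each broadband (full-chain-filtered) epoch is fitted with MVAR
models of order 1–30 by least squares on the common sample span; the order
minimizing `N·log det Σ̂ + p n² log N` among stable candidates (companion
spectral radius < 1) is kept.  Rank-deficient epochs are fitted in the
principal subspace (singular values above 1e−8 of the leading one) and the
coefficients mapped back to channel space, leaving H(f) well defined.  The
transfer matrix `H(f) = [I − Σ_k A_k e^{−i2πfk/fs}]^{-1}` is evaluated on a
0.5 Hz grid over 0.5–60 Hz, and

    DTF_{j→i}(f) = |H_ij(f)|² / Σ_k |H_ik(f)|²

is averaged over the band's bins (arithmetic mean over `[lo, hi)`).  The
normalization runs over all sources `k` into sink `i`, which forces inflows
to sum to one at every bin and bounds DTF in [0, 1].  DTF is computed from
broadband epochs and band-averaged in the frequency domain rather than from
band-pass-filtered epochs, because MVAR fitting on narrowband signals is
ill-conditioned and band selectivity is already explicit in `f`.

**iCOH / wPLI.**  Cross-spectra are Welch-averaged over 1-s Hann segments
with 50% overlap within each epoch (11 segments per 6-s epoch).  iCOH is the
band-mean |imaginary coherency|; wPLI is
`|E[Im S_ij]| / E[|Im S_ij|]` per bin with the expectation over the
within-epoch segments, band-averaged, with the 0/0 case defined as 0 and an
optional debiased variant.  Both are symmetric with zero diagonal and
insensitive to zero-lag mixing, whose cross-spectrum is real; their
finite-sample floor decays like `1/√n_segments`, which is why the
volume-conduction checks use long recordings with independent segments.

## Network construction and graph indices

Weighted matrices are binarized at a fixed density (default 15% of possible
edges, round-half-up) in two tiers: the maximum-weight spanning tree on
`max(w_ij, w_ji)` (equivalently, a minimum spanning tree of inverted
weights) guarantees weak connectivity; for directed matrices only the
arg-max direction of each tree link is seeded and the remaining directed
edges are added in descending weight order.  Ties break lexicographically on
(source, sink), making outputs deterministic; the identical target density
across subjects removes density-driven bias from all index comparisons.  A
proportional threshold at a fraction of the maximum weight is exposed as an
alternative but is not density-matched and is not used by the pipeline.

The six indices use the directed conventions of network neuroscience
(adjacency `A[i,j] = 1 ⇔ i→j`): directed modularity Q (maximized over
partitions), global efficiency with unreachable pairs contributing zero,
local efficiency over the union of in- and out-neighbors, Fagiolo directed
clustering with `t_i = ½[(A+Aᵀ)³]_ii` and denominator
`k_tot(k_tot−1) − 2k↔`, transitivity as the triangle/triplet census ratio,
and out–in degree assortativity over directed edges.  Zero-denominator nodes
contribute 0 (keeping the mean over a fixed n comparable across subjects);
degree-degenerate assortativity is NaN.  Modularity is solved exactly by
partition enumeration for n ≤ 8 and otherwise by seeded greedy agglomeration
with single-node relocation refinement and 20 restarts; the exact tiny-n
path is what the enumeration oracles certify.

## Reliability screening and inference

ICC(3,k) — two-way mixed, consistency, average measures — is computed from
the ANOVA mean squares of the epochs × subjects grid (epochs are raters,
k = 40).  Values are reported as computed (negatives are not truncated) and
binned as poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent.  Under the
null the estimator's small-sample bias is ≈ −2/(n_targets − 3), so null
calibration checks use many targets.  Only cells reaching ICC ≥ 0.60 in
*every* group enter group testing.

Group inference fits `Value ~ Group + (1 | Subject)` by REML
(statsmodels MixedLM), Control as reference; the Wald z 95% CI and p-value
refer to the group coefficient β₁.  Boundary fits (σ_u² → 0) fall back to
the pooled OLS reduction and are flagged as singular.  Cohen's f² is
`R²_m / (1 − R²_m)` with the marginal R² taken as fixed-effect variance over
fixed + random-intercept + residual variance.  FDR correction
(Benjamini–Hochberg) pools all state × band × index tests into one family.
Pearson correlations between per-subject epoch-mean indices and the
psychometric columns are computed per group for the most reliable
(measure, cleaning) combination, with BH-FDR across all tested pairs.

## Problem sizes used in tests and the acceptance script

The full study-scale configuration (2×19 subjects, 2 states, 20 channels, 3
estimators × 2 cleaners × 6 bands) is the `RunConfig` default.  The test
suite and the acceptance script run scaled-down problem sizes chosen as the
package's own validation design: the end-to-end recovery uses 12 channels,
12 subjects per group, one state, the full band and DTF + ASR with order
search capped at 5 (adequate for a lag-2 truth), which preserves every stage
of the pipeline while keeping a single run at a few minutes.  The channel
count matters beyond speed: a 20-channel DTF fitted on a single 6-s epoch
estimates ~400 edge weights from 3000 samples, and that estimation noise
flattens the *clustering* contrast between groups even when modularity
recovers cleanly, whereas at 12 channels the clustering contrast survives
estimation.  LME calibration uses the full 19+19 × 40 design over 500
replicates; DTF direction recovery uses 100 six-second epochs with the full
1–30 order search.

## Known limitations

* The generator's artifacts are stylized templates; passing ASR/ICA tests
  shows correct implementation of the stated rules, not cleaning performance
  on real EEG (no electrode drift, no re-referencing effects, no
  non-stationary background).
* Volume conduction is a static linear mixing; real field spread is
  frequency- and geometry-dependent.
* Subjects are exchangeable draws around a template; there is no age or
  exposure-duration structure, so covariate-adjusted analyses are out of
  scope.
* The per-channel ASR variant is a documented adaptation, not the canonical
  multichannel algorithm, and is off by default.
* Sensor-level networks only; no source localization.
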