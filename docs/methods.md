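# Methods note

## Analysis model

### Denoising and connectivity

Each subject contributes an ROI-by-time matrix sampled at a fixed
repetition interval (default TR = 2.0 s). Denoising applies, in order:

1. **Band-pass filtering** to 0.008–0.10 Hz with a second-order
   Butterworth filter applied forward and backward
   (`scipy.signal.sosfiltfilt`), giving zero phase distortion. Series
   are demeaned before filtering. The high edge must lie strictly below
   the Nyquist frequency 1/(2·TR).
2. **Nuisance regression**: ordinary least squares of each ROI series
   on user-supplied confound regressors plus an always-included
   intercept; residuals are carried forward. Rank-deficient confound
   matrices are rejected with the offending columns named.

The default order is filter-then-regress; the alternative order is
available as an explicit option because preprocessing toolchains differ
on this point and neither order is canonical.

Connectivity is the Pearson correlation between each ROI pair,
Fisher-z transformed (`atanh`). Correlations are clipped to
±(1 − 1e−7) beforehand so that numerically perfect correlations map to
the finite value atanh(1 − 1e−7) ≈ 8.40562 instead of ±inf. Diagonals
are zero by convention.

### Edge-wise GLM and the two-level significance rule

For a contrast between two cohorts (patients vs controls, the same
contrast within one sex, or males vs females within one group), the
design matrix contains an intercept, a group indicator (1 for the
first-named cohort, so positive t means "higher in the first-named
cohort"), and mean-centered age and BMI covariates. The model requires
at least p + 2 subjects for p columns and a full-rank design. OLS is
solved simultaneously for all edges via the normal equations; the
group coefficient yields a two-sided t test with n − p degrees of
freedom.

Significance uses a two-level rule: an edge is significant when its
connection-level p < 0.01 **and** its Benjamini–Hochberg q-value is
< 0.05 within at least one of its two endpoint ROIs' seed rows
(seed-level FDR, the convention of seed-based connectome toolboxes).
BH is delegated to `statsmodels.stats.multitest.multipletests`. A
`scope="global"` option applies a single BH correction across all
edges instead.

### Graph topology

Connectivity matrices are proportionally thresholded over the grid
τ = 0.20, 0.25, …, 0.60 (9 densities): the strongest round(τ·m) of the
m positive upper-triangle entries are kept, ranked by weight with ties
broken by ascending index so edge sets are deterministic. Negative
correlations are dropped by default (`negatives="abs"` ranks by
magnitude instead). Graphs may be analyzed weighted or binarized.

Per graph, the package computes natively (numpy +
`scipy.sparse.csgraph`; networkx is used only as an independent oracle
in the test suite):

- **Clustering coefficient** — binary: C(i) = 2tᵢ/(kᵢ(kᵢ−1)) with tᵢ
  the triangle count through node i (diag(A³)/2); weighted: Onnela's
  generalization with weights normalized by the network maximum and
  cube-rooted triangle products, keeping the binary degree in the
  denominator. Nodes with fewer than two neighbours contribute 0; the
  global value is the node average.
- **Characteristic path length** — mean shortest-path length over
  reachable ordered pairs (Dijkstra; hop counts when binary, edge
  lengths 1/weight when weighted). Unreachable pairs are excluded and
  counted rather than made infinite.
- **Small-world index** — γ = C/C_rand, λ = L/L_rand, σ = γ/λ against
  a null ensemble (default 1000 replicas) of degree-preserving
  double-edge-swap rewirings (10 successful swaps per edge) with the
  original weight multiset reassigned uniformly at random. Every
  replica preserves the degree sequence and the weight multiset
  exactly. For graphs that admit no swap (e.g. stars) the ensemble
  falls back to weight reshuffling alone and says so. A regime flag
  marks departures from the canonical small-world regime (γ ≤ 1 or
  |λ − 1| > 0.3).

Each metric's curve over the τ grid is summarized by its area under
the curve (trapezoidal rule), and per-subject AUCs are compared between
cohorts with two-sided Mann–Whitney U tests
(`scipy.stats.mannwhitneyu`): exact when n₁·n₂ ≤ 400 and tie-free,
otherwise the tie-corrected normal approximation with continuity
correction. Degenerate all-tied comparisons return p = 1 with a
warning. With `reps=0` the null-model stage is skipped (γ, λ, σ are
NaN) for inexpensive clustering/path-length comparisons.

## Synthetic cohort generator

The generator emulates a two-group, two-sex resting-state study. It
does **not** simulate hemodynamics or scanner artifacts; it produces
stationary multivariate normal time series whose population
correlation matrix carries the structure the analysis chain is meant to
detect:

- ROIs belong to eight anatomically named families (frontal,
  sensorimotor, parietal, thalamus/basal ganglia, cingulate,
  occipital/visual, cerebellum, brainstem) with sizes proportional to a
  132-ROI atlas-style parcellation.
- Baseline correlation is `base_within_r` = 0.5 inside a family and
  `base_between_r` = 0.1 between families — typical magnitudes for
  modular resting-state correlation structure, chosen once a priori.
- Group structure enters through `edge_effects` (add `delta_r` to one
  edge for a group and/or sex cell), `topology_effects` (add an
  increment to all within-family correlations of a cell, a diffuse
  segregation effect), and `covariate_slopes` (shift an edge linearly
  in standardized age or BMI).
- Every perturbed matrix is repaired to the nearest positive
  semidefinite matrix by eigenvalue clipping; repairs that move any
  entry by more than 0.1 are rejected as an inconsistent design.
- White measurement noise of standard deviation `noise_sd` = 0.4
  (relative to unit signal variance) shrinks all correlations by
  1/(1 + σ²), so observed correlations are realistically weaker than
  the population structure.
- Demographics (age, BMI, mJOA per group and sex) are drawn from
  truncated normal distributions parameterized by published
  DCM-cohort summary statistics; controls have mJOA fixed at 18.

Per-subject series are generated from the cell's correlation matrix
via its symmetric eigendecomposition root. Each subject's stream is
`SeedSequence([master_seed, crc32(subject_id)])`, so any subject can be
regenerated independently and cohorts are reproducible regardless of
generation order.

### Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| series_length T | 200 | typical resting-state run length at TR = 2 s |
| sampling_interval TR | 2.0 s | common fMRI repetition time |
| base_within_r / base_between_r | 0.5 / 0.1 | modular structure with clear separation |
| noise_sd | 0.4 | visible attenuation without burying structure |
| band-pass | 0.008–0.10 Hz | standard resting-state band |
| τ grid | 0.20–0.60 step 0.05 | protocol grid, 9 densities |
| null replicas | 1000 | protocol ensemble size |
| α (connection / FDR) | 0.01 / 0.05 | protocol two-level rule |

## Numerical choices

- Correlation clipping at 1 − 1e−7 bounds Fisher z at ≈ 8.41,
  preserving ordering among near-perfect correlations while keeping
  all downstream statistics finite.
- The PSD repair tolerance (0.1 maximum entry change) separates
  harmless numerical repair from genuinely inconsistent effect
  combinations, which raise an error instead of silently changing the
  design.
- Thresholding ties are broken by ascending edge index, making edge
  sets — and therefore all graph metrics — bit-deterministic.
- AUC uses the trapezoidal rule on the actual τ grid, so a constant
  curve c integrates exactly to 0.4·c over [0.2, 0.6].
- All stochastic components (cohort, rewiring, per-τ nulls) derive
  child seeds from `numpy.random.SeedSequence` spawns, never from
  global state.

## Limitations

- Time series are stationary, Gaussian, and temporally white; no
  autocorrelation, motion, drift, or physiological confounds are
  simulated. Filtering and nuisance regression are therefore exercised
  structurally rather than against realistic artifact spectra.
- Weighted path length uses the 1/weight length convention; other
  mappings (e.g. −log w) would give different absolute values.
- The seed-level FDR rule controls false discoveries within each seed
  row; under a fully null row its probability of flagging the row at
  all is close to the nominal 5%, so false-seed rates near that level
  are expected behaviour of the rule, not an implementation defect.
- Group comparisons of AUCs use independent two-sample tests; no
  repeated-measures or mixed-effect structure is modelled.
- The generator's effect parameterizations (single-edge shifts,
  uniform within-family increments, linear covariate slopes) are
  deliberately simple; they are designed to make recovery measurable,
  not to reproduce any particular empirical effect size.
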