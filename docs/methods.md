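# Methods

## The decoding model

`spikehd` decodes the identity of a visual stimulus (one of 81 Gabor grid
positions, or one of 118 natural images) from the binned spike counts of a
population of simultaneously recorded units during a 250 ms trial. The
classifier is a vector-symbolic (hyperdimensional computing) model: every
symbol is a dense vector in R^D with D = 10^4 by default, independent
random vectors are nearly orthogonal (cosine sd 1/sqrt(D)), binding is the
element-wise product and bundling the element-wise sum. The point of this
architecture for resolution analysis is that the encoder performs no
implicit averaging: the only averaging in the whole pipeline is the
explicit spatial pooling and temporal binning applied to the counts before
encoding, so differences in decoding accuracy across resolutions can be
attributed to the resolution itself.

### Encoding

For a trial binned into M bins across n spatial units, the trial
hypervector is

    V = sum_t [ sum_{i: n_i(t)>0} n_i(t) * S_i x H+  +  sum_{i: n_i(t)=0} S_i x H- ] x T(t)

with `x` element-wise multiplication. Conventions and components:

- **Spatial identities `S_i`.** Neuron level: the unit's receptive-field
  fingerprint `F_i` (mean total spike count per Gabor position, an
  81-vector) is mapped through a random-Fourier feature map
  `cos(B^T F_i + b) * sin(B^T F_i)` (`B` 81-by-D i.i.d. standard normal,
  `b` uniform on [0, 2pi)) and bound with a per-area hypervector with
  entries uniform on [0, 1). Population level: one bipolar hypervector per
  E/I class (shared across areas) bound with the area hypervector. Area
  level: the area hypervector alone. Region level: one fresh uniform
  hypervector per region. Whole-brain level: no spatial hypervector; the
  encoding degenerates to `V = sum_t n(t) T(t)`.
- **Polarization.** `H+` is a random bipolar hypervector and `H- = -H+`.
  A bin with n spikes contributes with weight n through the `H+` branch; a
  silent bin contributes with weight 1 through the `H-` branch. No 1/N
  normalization is applied (a `normalize_by_units` switch exists, default
  off). Because of this presence/absence nonlinearity, the per-unit count
  of silent bins at the working resolution is part of the code — this is
  the channel that makes fine temporal structure decodable at all (see
  "What transfers between trials" below).
- **Time.** `T(t) = (1 - t/M) T(0) + (t/M) T(M-1)` for t = 0..M-1, where
  the endpoints are random binary {0,1} vectors. The printed interpolation
  uses denominator M, so the last bin's hypervector is close to, but not
  exactly, the second endpoint; we keep the formula as printed.
  Interpolated time hypervectors are used as real-valued vectors without
  re-quantization. By default the endpoints are drawn **independently for
  every trial**, which prevents trial hypervectors from becoming similar
  merely because they share time hypervectors; a `shared` mode reuses one
  endpoint pair everywhere (it increases within-class similarity and
  typically accuracy, at the cost of implicit cross-trial averaging).
- Degenerate inputs: a unit with an all-zero fingerprint encodes to the
  zero spatial hypervector (sin 0 = 0) and then contributes only through
  the silence branch; this is documented behavior, not repaired.

The implementation exploits the linearity of the interpolation: bundling
over time collapses onto the two endpoint hypervectors,
`V = (sum_t w0(t) a_t) x T(0) + (sum_t w1(t) a_t) x T(1)`, so encoding at
M = 250 costs the same as at M = 1. A literal per-bin reference
implementation is kept and the two are cross-checked in the tests.

### What transfers between trials

Because the binary time endpoints have mean 1/2, the expected overlap of
time hypervectors from different trials is uniform over bin pairs; in
expectation only the *time-collapsed* bundle `sum_t a_t` carries similarity
across trials under independent time hypervectors. Consequently (a) trial
hypervectors with identical counts still have substantial similarity
(~0.55 in our measurements, not near zero), and (b) the decodable features
at bin size w are, per spatial unit, the total spike count and the number
of silent bins at width w. Fine temporal resolutions additionally suffer
cross-term noise that grows with M. This analysis explains the resolution
phenomenology reproduced in the tests: slow signal decodes best at coarse
bins, fast (within-trial) signal becomes decodable at bins near its
timescale through the silent-bin statistic, and both collapse at 1 ms where
counts are nearly binary and `total - silent` degenerates to an affine
function of the total.

### Adaptive training

Class hypervectors start at zero. For each training trial (shuffled order
per epoch, seeded), with true class l, predicted class l' (argmax cosine;
ties to the lowest index; an all-zero class scores 0, so the first
prediction of a blank model is class 0) and similarities d_l, d_l':

- correct: `C_l += eta (1 - d_l) V`
- error:   `C_l += eta (d_l' - d_l) V` and `C_l' -= eta (d_l' - d_l) V`

Natural scenes: eta = 0.01, 3 epochs. Gabor: every center update is echoed
to the up-to-8 grid-adjacent classes at eta_neighbor; eta_center = 0.01,
eta_neighbor = 0.001, 2 epochs. In the error case the four update lines
are applied additively in order, so a class adjacent to both l and l'
accumulates both contributions. Class hypervectors are raw sums — no
renormalization or decay. Cosine denominators are computed as
sqrt(|c|^2 |v|^2), which makes the zero-update fixed point (all samples
predicted correctly with similarity exactly 1) hold bit-exactly. Trial
hypervectors are encoded once and cached across epochs; re-encoding per
epoch would merely inject extra time-hypervector stochasticity.

## Resolution machinery

- **Temporal.** 1 ms base counts are summed into bins of 1, 2, 5, 10, 25,
  50, 125, 250 ms (the divisors of 250; exact mode conserves the total
  count). Non-divisor bins are supported via `overlap` (M = ceil(250/w)
  bins with starts floor(j(250-w)/(M-1)) — full coverage, possible
  double-counting) and `crop` (disjoint bins, trailing remainder dropped).
- **Spatial.** Counts are summed within E/I populations per area, areas,
  regions (fixed area-to-region table covering visual cortex, hippocampal
  formation, thalamus, hypothalamus, midbrain), or the whole brain.
- **E/I clustering.** Per unit, the Fano factor (variance/mean) of counts
  binned at `fano_bin_ms` pooled over all Gabor bins, positions and
  repetitions; population variance (ddof = 0, configurable); silent units
  get Fano 0 and land excitatory. Within each area the ceil(0.2 n)
  highest-Fano units are putatively inhibitory; boundary ties break by
  unit id. `fano_bin_ms` is a sweepable hyperparameter (default 25 ms):
  the split can change with the timescale at which variability is
  measured, and a practitioner selects the best-decoding value per
  subject. Pooling over bins (rather than per-bin Fano averaged) is a
  documented choice.

## Evaluation and statistics

- Natural scenes: per-class one-vs-rest F1 via scikit-learn and the macro
  mean over all m classes; classes absent from truth and prediction score
  0 (not skipped). Chance macro F1 for uniform guessing is 1/m (0.008 for
  m = 118).
- Gabor: per-trial Euclidean distance between true and predicted grid
  cells, labels mapped row-major ((x, y) = (label mod 9, label div 9) — a
  package convention; any fixed bijection is equivalent). Distances span
  [0, sqrt(128)] on the 9x9 grid; the chance level by exact enumeration
  over all 81 x 81 pairs is 4.66.
- Cross-validation: stratified 5-fold over original trials. Shuffle
  augmentation (per class: per time bin, one permutation of the trial axis
  applied to all units; 4 copies + original = 5-fold expansion) is applied
  separately inside each fold's training and test partitions, so no
  surrogate straddles the split — slightly stricter than splitting after
  augmenting. Augmentation permutations are seeded independently of the
  resolution so that per-trial errors stay paired across resolutions.
- Optimal-resolution selection: the resolution with the lowest median
  per-trial error — median ties (ubiquitous for 0/1 scene errors) broken
  by the mean — plus every resolution whose paired two-sided Wilcoxon
  signed-rank test against it has p >= alpha (0.05). Zeros dropped, exact
  null for small samples without ties, normal approximation otherwise;
  identical vectors give p = 1. Group level: each subject's whole optimal
  set is counted into the per-resolution histogram.
- Correlation significance: Pearson r with a two-sided permutation test,
  p = (1 + #{|r_perm| >= |r|}) / (1 + n_perm), n_perm = 10^4 by default.

## Oscillation analysis

Per region, the 1 ms-binned counts of its units are averaged and
concatenated across all Gabor trials in trial-id order into one contiguous
1 kHz series (not trial-averaged). Welch PSD: 4 s Hann windows, 50 %
overlap (0.25 Hz resolution, enough to localize theta peaks to +-0.5 Hz).
The aperiodic background is a line in log10 power vs log10 frequency over
3-50 Hz fit by iteratively reweighted least squares with one-sided
downweighting of points above the line (so narrow peaks do not lift the
fit); residual local maxima above 3.5x the robust residual spread (MAD x
1.4826) are candidate oscillations and the lowest-frequency one at or
above 3 Hz is reported, else "none". This is a deliberately simple,
deterministic spectral parameterization: it trades the flexibility of
knee-parameter aperiodic models and Gaussian peak fitting for full
reproducibility without manual tuning. The 3.5x multiplier was calibrated
on pure 1/f spectra (at 2x, essentially every null spectrum yields a
spurious detection because the residual spread of a well-averaged Welch
log-PSD is only ~0.08); at 3.5x the null false-positive rate is ~1/20
while injected theta-band peaks exceed the cut by an order of magnitude.
Peaks below 3 Hz are outside the fitting band and can never be reported.

## Synthetic data generator

The generator emulates the structure of a 250 ms-trial visual-coding
session: a Gabor task (81 positions x 45 repetitions by default) and a
natural-scenes task (118 images x 50 repetitions), units assigned in equal
blocks to named brain areas spanning the region table. Reduced class
counts and repetitions are supported for desk-scale experiments, and a
scenes session can prepend a Gabor receptive-field-tuning block
(`rf_block_reps`), mirroring real sessions, which neuron-level encoding
and Fano clustering require.

Per unit i and class c the rate is
`lambda_{i,c}(t) = base_rate * (1 + gain * s_{i,c}(floor(t/tau)))`, with
the template s piecewise-constant over windows of `signal_timescale_ms`
(tau, a divisor of 250):

- Gabor: s has a static part — a spatially smooth random field over the
  9x9 grid (Gaussian kernel, length scale `rf_smoothness`), the unit's
  synthetic receptive field — plus, when tau < 250, a window-varying part
  that is zero-mean across windows.
- Scenes: when tau < 250 the template is entirely the zero-mean
  window-varying part, so the class signal genuinely lives at timescale
  tau and the trial-total rate carries no class information; with
  tau = 250 the template is static. This makes "signal timescale" an
  exact, recoverable ground truth rather than a tendency.
- `signal_corr` mixes a per-area shared template component into every
  unit's signal (pairwise within-area signal correlation), enabling
  experiments where spatial pooling preserves signal while averaging out
  independent variability.

Counts are drawn per 1 ms bin: Poisson for excitatory units;
negative-binomial with matched mean and variance = `inhib_dispersion` x
mean for the ceil(20 %) inhibitory units of each area — the minimal
mechanism that yields the Fano-factor separation the population-level
clustering relies on (the Fano of the negative-binomial parameterization
equals the dispersion at any bin size under independence). A shared
per-(area, trial, window) log-normal gain with coefficient of variation
`noise_corr` induces within-area noise correlations. An optional
sinusoidal rate modulation (`oscillation_hz`, `oscillation_depth`) runs
phase-continuously across trials for spectral-recovery experiments.
Negative rates after applying the gain are clipped to zero with a warning;
strong gains (>= 1) deliberately exploit this rectification to produce
bursty on/off window structure. Everything is deterministic given the
seed, via named substreams of one master seed.

Defaults: base_rate 10 Hz, gain 0.5, tau 125 ms, noise_corr 0.2,
inhib_dispersion 3, rf_smoothness 1 grid cell — unremarkable
mouse-visual-cortex-like numbers giving a decodable but imperfect signal.

### What the generator does not emulate

No membrane or network dynamics, no refractoriness, no spike-sorting
artifacts, no drift, no behavioral covariates; noise correlations are
block-uniform within areas rather than distance-dependent; receptive
fields are smooth random fields, not Gabor-energy models. Passing tests on
this generator therefore demonstrate that the pipeline recovers the
structure it parameterizes (signal timescale, E/I dispersion, injected
oscillations, correlation structure), not that real recordings would yield
any particular optimal resolution.

## Experiment sizes used in tests and the acceptance script

Timescale-recovery runs use D = 2000, 8 scene classes, 2 areas: 30
repetitions x 10 units/area for the slow (tau = 250 ms) regime and 100
repetitions x 20 units/area with strong bursty drive (base 60 Hz, gain 3)
for the fast (tau = 10 ms) regime — sizes chosen so the accuracy gaps
exceed 3 pooled binomial sigma with margin while a full run stays in the
tens of seconds. The space-time interplay demonstration uses the Gabor
task at low rates (4 Hz) with signal_corr = 0.9 so that area-pooled counts
retain silent bins at fine resolutions. The algebra checks run at the full
D = 10^4.

## Known limitations

- With independent per-trial time hypervectors, within-trial timing whose
  collapsed statistics (totals, silent-bin counts) are class-invariant is
  provably invisible to the decoder; arrangement-only codes cannot be
  recovered. This is a property of the published encoding, not a bug.
- The simplified spectral parameterization has no knee parameter and
  assumes a single power-law background over 3-50 Hz; spectra with strong
  curvature may shift the detection threshold.
- The overlap/crop handling of non-divisor bins follows fixed start-point
  formulas; other placements are defensible.
- Training accuracy depends on sample order only through the seeded
  shuffle; different shuffle seeds give slightly different models (the
  update rule is not order-invariant).
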