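# Methods

## The problem and the data model

A SERS spectrum of a swab extract is a vector of scattering intensities on
a wavenumber grid.  The analysis must assign each spectrum to one of three
classes — mixed residue (1), pyrimethanil (2), chlorpyrifos (3) — across a
wide range of concentrations and mixing ratios.  Because the underlying
experimental spectra are not publicly released, the package ships a
generative model of the measurement that reproduces the statistical
structure the classifiers rely on, and every result in this repository is
computed on data drawn from that model.

### Synthetic spectrum generator

A noiseless single-analyte spectrum on the grid ν (200–1700 cm⁻¹, step
2 cm⁻¹, 751 points) is

    y(ν) = A(c) · Σᵢ wᵢ · L(ν; νᵢ, Γ) + s(ν) + b(ν)

* `L` is a Lorentzian of HWHM Γ = 6 cm⁻¹ (7 cm⁻¹ for the two highest
  bands), the typical linewidth of condensed-phase Raman bands; a Gaussian
  profile is selectable.
* Band positions νᵢ and relative weights wᵢ: chlorpyrifos 609 (1.0),
  675 (0.9), 1092 (0.6), 1166 (0.45), 1567 (0.35); pyrimethanil 558 (1.0),
  608 (0.5), 990 (0.9), 1294 (0.5), 1600 (0.45).  The weights order the
  bands by their qualitative prominence (strongest: 609/675 and 558/990);
  their absolute values are conventions of the generator, not measured
  cross-sections.
* Amplitude response `A(c) = max(0, b + a·log₁₀ c)` with (a, b) = (1.0, 8.0)
  for chlorpyrifos and (0.9, 7.5) for pyrimethanil — a log-linear
  concentration law, positive over the validity range 10⁻⁸–10⁻² M and
  producing intensities of order 1–6 a.u. over the dataset's levels
  10⁻³–10⁻⁷ M.
* Solvent (acetonitrile) bands at 740, 910, 1040, 1370 cm⁻¹ with fixed
  heights 0.8/0.6/1.0/0.6 a.u., concentration-independent.
* Fluorescence baseline `b(ν) = 3.0 + 10⁻³ ν + 2·10⁻⁷ ν²` (gentle positive
  curvature, comparable in magnitude to the strongest bands).
* Per-spectrum multiplicative gain `∼ N(1, 0.05²)` on the chemical signal
  (emulating replicate-to-replicate SERS enhancement variability) and
  additive white noise `N(0, 0.12²)` — about 2 % of the strongest
  noiseless band height.

A mixture mixed at volume ratio (r_a : r_b) contains each analyte at its
stock concentration scaled by its volume fraction; its signal is the sum of
the two analyte terms plus **one** solvent and **one** baseline
contribution.  With noise off, mixtures are therefore exactly additive, a
property the test suite asserts pointwise.

The default dataset holds 78 spectra — 38 mixtures (7 ratios × 5
concentration levels, cycled), 20 pyrimethanil and 20 chlorpyrifos (5
levels, cycled).  The 38/20/20 composition gives the mixture class enough
coverage of the ratio × concentration design; only the total of 78 is
externally fixed.  All randomness flows from one integer seed;
regenerating with the same configuration is bit-identical.

What the generator does **not** model: electromagnetic/chemical enhancement
physics, analyte–nanoparticle interactions that reorder band intensities at
different concentrations, wavenumber calibration drift, cosmic-ray spikes,
or fruit-matrix interferents.  Passing tests on this data show the analysis
pipeline is correct and that the study design is recoverable under the
stated noise; they do not certify accuracy on real instrument data.

## Preprocessing

Chain (fixed order): min–max normalization → Savitzky–Golay smoothing →
baseline correction.  Whether the original analysis normalized before or
after baseline removal is not documented anywhere we could check; the
chosen order is a package convention.

* **Normalization**: per-spectrum min–max to [0, 1] (`max` and `none` modes
  available).  A constant spectrum is a degenerate-input error, not a
  silent zero vector.
* **Savitzky–Golay**: window 11 points (22 cm⁻¹), polynomial order 3 —
  common practice for Raman at this sampling; edges use a polynomial fit on
  the truncated window (scipy `interp` mode) so that polynomials of degree
  ≤ 3 pass through exactly.
* **FFT low-pass** (used as the third model channel): hard cutoff at 0.15 ×
  Nyquist, which retains bands of width ≳ 6 cm⁻¹ on the default grid while
  removing pixel-scale noise; the DC component is always kept, so the mean
  is preserved.
* **Baseline correction**: order-2 polynomial fitted by iterated clipping —
  fit, clip the working signal at fit + 3·sd(residual), refit; 10
  iterations.  Peaks progressively stop biasing the fit.  The procedure is
  equivariant under subtraction of any order-2 polynomial, which makes the
  correction *exactly* idempotent (to float rounding) and exact on pure
  polynomial backgrounds.
* **Peak intensity**: per-spectrum maximum in a ±10 cm⁻¹ window, summarized
  as mean ± sample standard deviation across replicates.

## Feature set and splitting

Five characteristic-peak centres — 559, 609, 668, 675, 990 cm⁻¹, kept
verbatim from the study design even though they differ by ±1 cm⁻¹ from the
generator's band positions — are snapped to the nearest grid point (ties to
the lower wavenumber) and expanded by ±5 grid points: 5 × 11 = 55 features.
Overlapping windows keep duplicate columns so the count is invariant.

The Kennard–Stone split seeds with the pair of samples at maximum Euclidean
distance in the 55-dimensional feature space and greedily adds the sample
maximizing its minimum distance to the selected set; ties break to the
lowest index.  The default training size is 50 (so 28 test samples out of
78); the often-quoted "5:3" ratio is treated as approximate since
78·5/8 = 48.75.  Distances are computed on the feature vectors the models
see (configurable to full spectra).

## Classical models

* **PCA**: mean-centred, on the 500–700 + 950–1300 cm⁻¹ sub-ranges (the
  analyte-band regions).  Per-class 95 % confidence ellipses on the score
  planes use the class score covariance scaled by the χ²(2) 0.95 quantile.
  Variance-contribution percentages on synthetic data are reported but not
  asserted against any external figure — they depend on the data.
* **SVM**: scikit-learn `SVC`, RBF kernel `exp(−g‖x−y‖²)`, one-vs-one
  multi-class.  Grid search evaluates every integer (log₂ C, log₂ g) in
  [−10, 10]² (441 points) with 5-fold stratified cross-validated accuracy
  on the training split as the objective — training accuracy alone would
  make the largest C and g trivially optimal.  Ties resolve toward smaller
  log₂ g, then smaller log₂ C (fewer support vectors, simpler model).  The
  returned maximizer is verified in the tests by an independent exhaustive
  re-evaluation of the surface.

## MC-CNN-GRU

Architecture (per spectrum of length L = 751):

    channel c ∈ {raw, SG, FFT}:
        Conv1d(1→8, k=3) → BN → Swish → AvgPool(4)
        → Conv1d(8→16, k=3) → BN → Swish
        → Conv1d(16→32, k=3) → Swish
    fuse: concatenate the three 32-feature maps at matched positions (96)
    AvgPool(4) along wavenumber → sequence of ~47 steps
    → GRU(96→16) → GRU(16→32) → mean over steps → Dense(32→3) → softmax

16 371 parameters, independent of L (weight sharing).  Swish is
x·σ(x); batch normalization precedes the activation in the first two
blocks (either order is defensible; this one is the package's convention,
as is the absence of an extra activation on the output layer).

Two design choices deserve justification because the design space was
genuinely open:

* **Where position information comes from.**  Convolutions are
  translation-equivariant and the readout pools over position, so the
  *absolute* band positions — precisely what separates pyrimethanil
  (558 cm⁻¹) from chlorpyrifos (675 cm⁻¹) — survive only through the GRU's
  sequential dynamics: a long-memory GRU acts as a leaky integrator, and a
  band encountered early contributes to more time steps of the pooled mean
  than one encountered late, encoding position approximately linearly.
* **Making that pathway trainable.**  At the fixed optimization budget
  (Adam, lr 10⁻³ stepped ×0.1 at epoch 50, ≤ 300 epochs) a randomly
  initialized GRU over the full 751-step sequence does not converge — the
  pooled states are almost sample-independent at initialization.  Two
  standard measures fix this: average pooling after the first conv block
  and again after fusion (sequence length ~47; per-step evidence
  concentrated), and initializing the GRU update-gate biases at +2
  (chrono-style initialization, starting in the remember regime).  With
  them, training reaches the early-stopping criterion within 40–250 epochs
  across seeds.

Training: Adam (β₁ = 0.9, β₂ = 0.999), batch size 8, cross-entropy;
learning rate is an exact step function of epoch; training stops when the
epoch-mean training loss drops below 0.01 ("early stop") or at 300 epochs.
The per-epoch accuracy in the history is computed from the training-mode
batch predictions; reported train/test accuracies always come from a
separate inference pass (batch-norm running statistics).  Everything —
initialization, shuffling — derives from a single integer seed, and two
runs with the same seed produce identical histories.

Implementation: all layers are explicit numpy forward/backward pairs; the
GRU recurrence and the Swish activation are numba-compiled.  Every layer's
backward pass is checked against central finite differences (relative
error < 10⁻⁶) in the test suite.

**Embedding**: the penultimate representation (the 32-dimensional pooled
GRU state) is mapped to 2-D with t-SNE (perplexity 15, PCA initialization,
fixed seed).  Class separation is summarized by the silhouette coefficient.

## Study replicates and problem sizes

A replicate = generate the 78-spectrum dataset with seed *s* → preprocess →
55 features → KS 50/28 split → fit → score.  The reported quantities are
the KS training-set size, the median SVM training accuracy over 20 seeds,
and the median CNN-GRU training and test accuracies over 10 seeds.  These
sizes keep a full run (script plus test suite) in the minutes range on one
CPU while giving medians that are stable to the choice of base seed.

## Degenerate inputs and numerical conventions

* Constant spectra: rejected by min–max normalization; preserved exactly by
  SG and FFT filters; mapped to ~0 by baseline correction.
* Peak centres are snapped to the nearest grid point, ties to the lower
  wavenumber; windows that would cross the grid edge raise errors naming
  the peak.
* KS ties (equidistant candidates) break to the lowest sample index, making
  the split permutation-covariant whenever all pairwise distances are
  distinct.
* Grid-search ties break to smaller log₂ g then smaller log₂ C.
* CSV writers emit 17 significant digits and readers parse with
  correctly-rounded floats, so write→read round-trips are bit-exact.
* Non-finite training loss raises a training error carrying the epoch.

## Known limitations

* Synthetic-data results bound what the pipeline can do under the modeled
  noise; real SERS spectra add enhancement-factor drift, matrix bands and
  calibration error that the generator omits by design.
* The CNN-GRU's position encoding via integrator dynamics degrades for very
  long sequences or near-zero update-gate bias; both are configuration
  parameters, not learned quantities.
* PCA variance percentages and detection limits are data-dependent and are
  intentionally not asserted.
* JCAMP-DX support covers the single-spectrum `(X++(Y..Y))` affine form
  only.
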