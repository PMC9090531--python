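# Methods

`nirsimca` implements one-class brand authentication of pharmaceutical
tablets from handheld near-infrared (NIR) absorbance spectra: spectral
preprocessing, PCA screening, classical SIMCA and data-driven SIMCA
(DD-SIMCA) class models, and a synthetic spectrum generator that stands in
for field-collected tablets so the whole pipeline is testable end to end.

## The classification problem

A one-class (class-modeling) classifier is trained per brand on genuine
tablets of that brand only. A new tablet is *accepted* by a brand model if
its spectrum is consistent with the training class, and *rejected*
otherwise. Falsified tablets — fakes sold under a genuine brand name but
containing none of the declared active pharmaceutical ingredients (APIs) —
should be rejected by every model; genuine tablets of other brands should be
rejected by all models except their own. Performance is reported as
**sensitivity** (percent of target-brand test tablets accepted) and
**specificity** (percent of non-member test tablets rejected).

## Synthetic spectra

Each brand is a sum of broad Gaussian bands on a 228-channel grid over
900–1700 nm: a shared API band triplet per formulation family
(dihydroartemisinin–piperaquine or sulfadoxine–pyrimethamine) plus a
brand-specific excipient doublet. Per tablet,

    A(λ) = m · [ Σ_bands (1 + δ_batch) G_band(λ) + s·(λ − λ_mid) ] + a + ε(λ)

with `m` log-normal (median 1, sd 0.08 on the log scale) modelling
multiplicative path-length scatter, `a ~ N(0, 0.01 AU)` an additive offset,
`s ~ N(0, 2·10⁻⁵ AU/nm)` a baseline tilt, `δ_batch ~ N(0, 0.02)` a relative
band-amplitude perturbation shared by all tablets of a batch, and per-channel
Gaussian noise `ε` with sd 8·10⁻⁴ AU inside 1085–1601 nm and 4·10⁻³ AU
outside (the spectral edges of handheld instruments are noisy and poorly
repeatable). Falsified tablets replace all API bands by filler bands at
centers disjoint from (≥ 3.5 σ away from) every genuine API band.

The default sampling design is eight product entries — six licit DP/SP
brands with batch counts (6, 2, 2, 5, 2, 2, 2), two illicit street-vendor
batches of the same SP brand (falsified), and one of the six licit
Duo-Cotecxin batches falsified — ten tablets per batch, 23 batches and 230
spectra in total. Randomness is hierarchical: every (brand, channel, batch,
tablet) tuple has its own counter-based substream derived from one global
seed, so adding a product does not perturb the other products' draws and
identical inputs give bit-identical matrices.

**What the generator does and does not emulate.** It reproduces the
artifacts the preprocessing chain is designed to remove (scatter, offsets,
baseline drift, batch amplitude effects, noisy edges) and the band-structure
differences that separate brands. It does *not* model tablet-to-tablet
chemical variability, instrument drift over time, temperature effects, or
nonlinear detector response; after preprocessing, the within-class variation
is therefore dominated by filtered channel noise, which is the hardest case
for training-estimated statistical limits (see "Known limitations"). Passing
tests demonstrate the correctness and calibration of the machinery under
these controlled conditions, not field performance.

## Preprocessing

Order: **crop → Savitzky–Golay second derivative → MSC.**

- **Crop** to 1085–1601 nm (inclusive), so the noisy edges never enter the
  derivative support or the MSC reference.
- **Savitzky–Golay**: window 11 channels (~39 nm on the default grid, a
  typical handheld-NIR choice; the window width is configurable), polynomial
  degree 2, second derivative, scaled by the channel spacing so the result
  is d²A/dλ² per nm² and grid-independent. The half-window channels at each
  end are dropped rather than padded — padding invents data, and the range
  has already been cropped.
- **MSC**: each spectrum x is regressed on a reference r by OLS,
  x = a + b·r, and corrected to (x − a)/b. The reference is always the
  *training-set* channelwise mean; test spectra are corrected against the
  training reference so no test information leaks into the model.

The second derivative removes additive offsets and linear baselines exactly;
MSC removes the remaining multiplicative factor (which also absorbs the
coherent per-batch amplitude perturbation). Degenerate inputs fail loudly: a
constant MSC reference and an MSC slope |b| < 10⁻¹⁰ are errors naming the
offending sample.

## PCA and distance statistics

PCA is computed by SVD of the mean-centered matrix (no autoscaling — the
preprocessed derivative spectra are already on a common scale). Component
variances are λ_a = s_a²/(n−1). Each loading column's largest-magnitude
element is forced positive, making fits platform- and run-stable. For a
sample x with scores t = Lᵀ(x − c):

- **Hotelling T²** (score distance h): Σ_a t_a²/λ_a, with λ_a always the
  *training* score variances;
- **Q residual** (orthogonal distance v): ‖(x − c) − L t‖².

Score-plot confidence ellipses for a component pair use the two-component
limit T²_lim = 2(n−1)/(n−2)·F_level(2, n−2), with semi-axes √(λ_i·T²_lim).

## Classical SIMCA

One PCA per brand. The number of components is chosen by venetian-blinds
cross-validation: every k-th sample (k = 10 blinds, samples ordered by
batch) is held out, PCA is fitted on the rest, and the held-out squared
residual after projection onto the first A loadings (PRESS) is accumulated.
Because row-wise projection PRESS decreases monotonically in A, the selected
A is the *smallest* one within 5% of the minimum PRESS. The search range
defaults to A ≤ min(10, n/5) — the usual five-samples-per-component rule of
thumb. On data whose within-class covariance has a slowly decaying spectrum
(as filtered noise does), an uncapped search would drift to large A and
overfit the Q limit at small n.

Confidence limits at 95%:

- **Q limit**: Jackson–Mudholkar construction from the residual-component
  variances via θ_k = Σ λ^k, k = 1..3. When the Wilson–Hilferty exponent
  degenerates (h₀ ≤ 0 or a negative base, possible for heavy-tailed residual
  spectra), the Box moment approximation g·χ²(h) with g = θ₂/θ₁,
  h = θ₁²/θ₂ is used instead. Note the Jackson–Mudholkar limit is ~2.5%
  below the exact quantile in the single-eigenvalue (1 DoF) case, where the
  Wilson–Hilferty approximation is weakest; with realistic multi-component
  residuals its false-rejection rate is 5% ± 1% (verified by Monte Carlo).
- **T² limit**: A(n−1)/(n−A)·F_level(A, n−A).

Membership probability uses the reduced distance
d = √[(q/Q_lim)² + (t²/T²_lim)²] and the map **p = exp(−d²·ln2/2)**: p = 1
at the class center, p = 0.5 for a sample exactly on both 95% limits
(d = √2), p(2d) = p(d)⁴, strictly decreasing in both statistics. A sample is
attributed to every class with p ≥ 0.8; zero or multiple assignments are
possible (class-modeling semantics — no forced argmax). A degenerate
Q_lim = 0 (perfect-fit class) treats q/Q_lim as 0 for q ≈ 0 and as infinite
otherwise. The probability map is this package's own documented convention:
commercial chemometrics packages do not publish theirs, so no equivalence is
claimed. Note the 0.8 threshold corresponds to d ≈ 0.80 — *stricter* than
the 95% limits themselves (a sample on a single limit has p = 2^(−1/2) ≈
0.707) — so in-class samples in the upper tail of their own Q/T²
distributions are rejected and classical sensitivity is structurally below
100% on noise-dominated synthetic classes, while specificity is unaffected.

Each class model stores its own preprocessing config and MSC reference, so
prediction on raw spectra is self-contained.

## DD-SIMCA

For the target brand, the training score distance h and orthogonal distance
v are each modelled as scaled chi-squared: x ≈ x₀·χ²(N)/N with x₀ the sample
mean and N = round(2·x₀²/Var) by the method of moments (the classical
estimator; robust quantile-based variants are deliberately out of scope),
clipped to [1, 250] — the ceiling guards the quantile evaluation for
near-degenerate classes. The total distance

    c = N_h·h/h₀ + N_v·v/v₀   ~   χ²(N_h + N_v)

gives the acceptance rule c ≤ c_crit with c_crit = χ²_{1−α}(N_h + N_v);
the boundary is inclusive. Acceptance plots use (ln(1 + h/h₀),
ln(1 + v/v₀)). Defaults follow the study setup: 2 PCs and α = 10⁻⁶ (10⁻⁷ is
the other value used for the second target brand in the original analysis;
no selection rule for α is implemented — both are simply exposed). Training
outlier pruning is not implemented.

## Study replication and splitting

`replicate_study(seed)` generates the 230-spectrum design and splits each of
the six modelled brands: brands with ≥ 5 licit batches give 3 batches to
training and the rest to test (whole batches never straddle the split);
two-batch brands are split 60/40 by the deterministic Kennard–Stone maximin
algorithm on their preprocessed spectra. Falsified batches are never placed
in training. The eighth brand (no model) and all falsified samples join a
common test pool. Each model is then scored on that pool. Kennard–Stone
ties break toward the lowest row index, making the whole pipeline
deterministic: two runs with one seed produce byte-identical artifacts
(reports contain no timestamps).

Problem sizes throughout (230 spectra, 12–30 training spectra per class,
136 preprocessed channels) match the emulated study design; Monte-Carlo
calibration checks use 10⁴–10⁵ draws.

## Known limitations

- With n = 30 training spectra and p = 136 channels, training residuals are
  optimistic: held-out-batch orthogonal distances run a median ~1.2× the
  training mean v₀. At α = 10⁻⁶ this occasionally (≈30% of seeds) costs one
  of 20 target test tablets, i.e. DD-SIMCA sensitivity 95% instead of 100%.
  Real tablet data, whose within-class residuals are dominated by structured
  variation rather than white noise, is less exposed to this bias.
- Classical SIMCA sensitivity under the p ≥ 0.8 rule is ~70–80% pooled on
  the synthetic study (specificity 100%), for the threshold-geometry reason
  above.
- The moment DoF estimator is itself estimated from few (12–30) training
  distances; its sampling noise widens or narrows the acceptance band run
  to run.
- The Jackson–Mudholkar Q limit is anti-conservative by ~2.5% in the
  single-residual-eigenvalue limit (Wilson–Hilferty at 1 DoF).
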