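# Methods

## Problem setting

Given prediction access to a black-box classifier g — a callable or an
external executable mapping a batch of raw samples to class
probabilities in [0, 1] — and one instance x₀, the package produces the
locally valid linear explanation of g(x₀) that optimally trades
faithfulness against human interpretability. Only the input and output
layers of the model are touched; architecture and parameters are never
inspected.

## Neighborhood generation

A binary mask matrix decides, per sample and per representative
feature, whether that feature is perturbed (each entry is 1 with
probability `mask_prob`, default 0.5). Row 0 is forced to all zeros so
the unperturbed instance is always part of the neighborhood and anchors
the similarity weights (Π₀ = 1). The default neighborhood size is
N = 5000 samples.

Perturbation per modality:

- **tabular** — masked continuous entries become xₖ + ε·σₖ with
  ε ~ N(0, 1) and σₖ the feature's training-set standard deviation;
  masked categorical entries are resampled from the training pool. The
  design matrix holds z-scored values (continuous) or an
  equals-instance indicator (categorical). A zero-variance feature is
  left untouched and contributes a constant design column.
- **text** — the document's distinct token types are the features.
  Default mode removes every occurrence of a masked type; replacement
  mode substitutes from a training token pool. Design entries are
  presence indicators (1 = intact).
- **image** — the image is tiled into square superpixels (default
  16 px); a masked tile is flattened to its per-channel mean color.
  Design entries are intact indicators.

The choice ε ~ N(0, 1) puts the entire perturbation scale into σₖ,
which keeps the noise level interpretable in training-data units.
Randomness is organized as one master seed with fixed per-purpose
derived streams (masks, Gaussian noise, pool sampling), so results are
bit-reproducible and enlarging N does not reshuffle earlier samples.

## Similarity weights

Neighborhood samples are labeled in-class / not-in-class by
thresholding g at 0.5 (configurable). The design matrix is projected
onto the two-class Fisher discriminant direction
S_w⁻¹(μ₁ − μ₀); within-class scatter is ridge-regularized by
1e−6 · trace(S_w)/n on the diagonal so duplicated or collinear columns
cannot break the solve — robustness to redundant features is the
purpose of this projection. The projected coordinate is normalized to
unit pooled within-class variance, which is the convention that makes
the fixed Gaussian kernel width σ = 1 meaningful:
Πᵢ = exp(−(cᵢ − c₀)²/σ²).

If the neighborhood contains a single class the projection is
undefined; the pipeline raises a degenerate-neighborhood error by
default, or — with `similarity_fallback="euclidean"` — falls back to
standardized-Euclidean distances rescaled to unit variance.

The `similarity_error` diagnostic ΔΠ = (1/N) Σ (Πᵢᵒ − Πᵢˢ)² quantifies
how much the weights move when uninformative columns are appended; the
`diagnostics` module runs this as a repeated-trial experiment (pure
noise and correlated copies a·xᵢ + b·N(0,1) with defaults a = 1.0,
b = 0.2) against both metrics.

## Surrogate family and unfaithfulness

For a feature subset, coefficients minimize Σᵢ Πᵢ[g(xᵢ) − F(xᵢ)]² in
closed form (weighted least squares with intercept; rank-deficient
subsets get a ridge-stabilized solve and a warning). The intercept is
excluded from feature counting and from entropy: a level offset
attributes nothing to any feature.

Unfaithfulness is 𝒰 = 1 − |C(F, g)| with C the Π-weighted Pearson
correlation. The weighted form is deliberate: it makes |C|² equal the
weighted R² of the fit, which guarantees 𝒰 is non-increasing along any
nested path of fits — the property the selection scan relies on; this
is asserted at runtime on every path. An unweighted variant is
available behind a flag for comparison. A constant surrogate is
assigned |C| = 0 (it explains nothing); a constant g is rejected as
having nothing to explain. Constancy is detected with a relative
variance threshold (1e−20 × max(1, mean²)).

Forward selection fits all n single-feature models, keeps the lowest-𝒰
one, then greedily adds the feature that minimizes 𝒰 at each step, up
to `j_max` (default n). Exact ties break toward the lowest feature
index for determinism. Greedy selection is O(n²) weighted fits; for
very high feature counts, cap `j_max`.

## Entropy and free-energy selection

Interpretation entropy of a coefficient vector is the normalized
Shannon entropy of pₖ = |fₖ|/Σ|fᵢ|, with 0·log 0 = 0 and normalization
by log n over the *total* feature count n (not the support size), so
values are comparable across the family. It is invariant to rescaling
and sign flips of the coefficients.

Characteristic temperatures θʲ = −Δ𝒰ʲ/Δ𝒮ʲ are computed between
consecutive sizes; transitions with |Δ𝒮| < 1e−12 are flagged invalid
and excluded from the scan (a temperature read off numerically flat
entropy is an artifact — it occurs when the fit has saturated and an
added coefficient is exactly zero). The optimal size j* follows the
largest drop between consecutive valid temperatures; the model right
after the drop's starting transition is selected, which reduces to the
standard rule on contiguous paths and returns the sparsest of the
equivalent models when the drop spans flat transitions. Ties break to
the smaller size. θᵒ is the midpoint of the two temperatures
bracketing j*, and ζʲ = 𝒰ʲ + θᵒ·𝒮ʲ is reported for the whole family.
A family with a single valid transition selects the sparser side of
that transition at θᵒ = θ¹.

**Uniqueness caveat.** The guarantee that the free-energy minimum sits
at j* for every temperature strictly between the bracketing θ values
holds when the θ sequence is non-increasing, i.e. when the (𝒮, 𝒰) path
is convex — the regime the monotonicity theorems describe (independent
features). On non-convex paths (a local bump in θ) the selected model
can sit above the lower convex hull and the window narrows; the test
suite asserts the stability property in the convex regime and documents
this boundary rather than hiding it.

## Analytic fixtures and what they do (not) show

Real trained models are expensive and external, so validation uses
analytic stand-ins with recorded ground truth:

- **dihedral** (tabular): p = logistic(4·sin φ + 0.3·sin θ) over the 8
  sin/cos features of four backbone dihedrals, probed at a
  near-transition configuration (φ = 0.084, ψ = 0.007, θ = 0.237,
  ω = 2.990 rad); training statistics come from a 2000-row table of
  uniform angles. Emulates a two-state molecular classifier whose
  assignment flips near φ ≈ 0.
- **image**: p = logistic(10·(mean within-tile contrast of 3 textured
  signal tiles − 0.15)) on a 64×64 image with 16-px tiles. Contrast
  (mean absolute deviation from the tile mean) is exactly what the
  mean-color perturbation destroys, so the relevant tiles are
  identifiable; the offset places the intact image at ~0.82 and the
  fully flattened one at ~0.18 so both classes populate the
  neighborhood under the 0.5 threshold.
- **text**: p = logistic(2.5·present(k₁) + 2.5·present(k₂) − 2.0) over
  a 30-token document with two planted keywords. The bias is
  deliberately asymmetric: a symmetric logistic over two indicators is
  *exactly* linear in them, which saturates the fit at j = 2 and
  degenerates the temperature scan — no trained classifier is exactly
  linear, and the offset preserves a realistic residual nonlinearity.

The `transition_state_filter` helper selects configurations whose two
most probable classes both exceed 0.4, the regime where a state
classifier is most sensitive and local explanations are most
informative.

Sensitivity checks compare explanations of a fixture and of a
parameter-randomized copy whose coefficients are relocated to
previously irrelevant features (disjoint relocation rather than a
uniform permutation, which would re-hit the original support by chance
in ~7% of draws and say nothing about sensitivity). Overlap is the
Jaccard index of supports; divergence is the total-variation distance
between weight vectors on the union support.

These fixtures demonstrate correctness of the pipeline — recovery of a
known relevant set, robustness of the similarity measure, sensitivity
to model corruption. They are deliberately low-dimensional and
noiseless at the black-box level; passing them does not certify
behavior on models with strong feature interactions, label noise, or
thousands of features, where neighborhood size and `j_max` need
problem-specific thought.

## Problem sizes used in tests and the acceptance script

Recovery runs use the full default N = 5000 neighborhood over 20 seeds
per modality; monotonicity and oracle-equivalence checks use 50 and 8
independent-feature fixtures (N = 400 and 200, n = 6) where exhaustive
best-subset enumeration is feasible; the similarity experiment runs 100
trials at N = 2000; sensitivity runs 20 seeds at N = 1500. These sizes
give stable rates (identical pass percentages across master seeds)
while keeping a full run around one minute on a single CPU.

## Known limitations

- Two-class discriminant projection only; multi-class models are
  explained one class at a time via the explained-class probability.
- Regular square superpixel grids only (no SLIC-style segmentation);
  the grid must partition the image exactly.
- The whitespace/punctuation tokenizer is intentionally minimal;
  pre-tokenized input is the intended path for anything richer.
- Greedy selection is quadratic in feature count; no pre-screening
  strategy is built in beyond capping `j_max`.
- Perturbations treat features independently; structurally coupled
  features (e.g. sin/cos of one angle) are perturbed without enforcing
  their constraint, which is standard for this family of methods but
  worth remembering when reading attributions.
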