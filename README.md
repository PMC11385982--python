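# terp

Thermodynamics-inspired, model-agnostic local explanations of black-box
classifiers, with a built-in measure of how human-interpretable each
candidate explanation actually is.

## Who this is for

Anyone who has a trained classifier they can only *query* — a
metastable-state assignment network for molecular dynamics, a vision
transformer, a text classifier, or a closed commercial model behind a
prediction API — and needs to know **which input features drove one
particular prediction**, with a defensible, hyperparameter-free way of
deciding how many features belong in the answer.

## The method

Around an instance x₀, the black box g is probed on a neighborhood of
randomly perturbed copies and approximated by a sparse linear surrogate
over representative features s₁…sₙ (z-scored columns for tabular data,
token presence for text, superpixel on/off for images):

    F = f₀ + Σₖ fₖ sₖ

fitted by weighted least squares with Gaussian similarity weights
Πᵢ = exp(−dᵢ²/σ²). Distances dᵢ are measured along a supervised 1-d
Fisher-discriminant projection of the neighborhood (in-class vs.
not-in-class at probability 0.5), which makes the weights robust to
redundant or noisy features and lets σ = 1 stay fixed.

A greedy forward-selection pass produces one surrogate per support size
j = 1…n, each scored by two numbers in [0, 1]:

- **unfaithfulness** 𝒰ʲ = 1 − |C(F, g)|, where C is the Π-weighted
  Pearson correlation between surrogate and black box — 0 means the
  surrogate locally tracks the model perfectly;
- **interpretation entropy** 𝒮ʲ = −(1/log n) Σₖ pₖ log pₖ with
  pₖ = |fₖ|/Σ|fᵢ| — 0 when one feature dominates, 1 when all n matter
  equally, i.e. a direct measure of how hard the explanation is to absorb.

The two are combined into a free energy ζʲ = 𝒰ʲ + θ·𝒮ʲ with a
temperature-like trade-off parameter θ ≥ 0. Between consecutive sizes,
θʲ = −Δ𝒰ʲ/Δ𝒮ʲ is the temperature at which models j and j+1 tie; the
size reached by the **largest drop in θʲ** keeps the lowest free-energy
minimum over the widest temperature window and is returned as the unique
optimal explanation, together with θᵒ (midpoint of the bracketing
temperatures) and the normalized feature weights pₖ.

## Worked example

The built-in demo explains an analytic two-state classifier over the
sin/cos features of four backbone dihedral angles (φ, ψ, θ, ω), probed
at a near-transition-state configuration (φ = 0.084 rad):

```bash
$ terp demo --case dihedral --seed 1 --out demo
j*=2 theta_opt=0.1722 sin_phi:0.922 sin_theta:0.078
```

The trace written to `demo/trace.tsv` shows why j* = 2 was selected
(columns truncated):

```
j  added_feature  U         S         theta
1  sin_phi        0.058059  0.000000  0.341232
2  sin_theta      0.013033  0.131949  0.003096
3  sin_omega      0.013018  0.136857  0.002192
...
```

Unfaithfulness stops improving after sin φ and sin θ enter the model, so
the characteristic temperature collapses from 0.341 to 0.003 at the 1→2
transition — the largest drop in the trace — and the two-feature model is
selected with weights p = (0.922, 0.078). That is exactly the generating
structure of the demo classifier: a dominant dependence on sin φ with a
weak secondary dependence on sin θ.

The other demos (`--case image`, `--case text`) recover the 3 textured
signal superpixels of an image classifier (j* = 3) and the 2 keywords of
a text classifier (j* = 2, p ≈ 0.5/0.5).

## Explaining your own model

Any executable that reads a batch file and prints one probability per
sample can serve as the black box:

```bash
terp explain-tabular instance.csv --blackbox-cmd "python my_model.py" \
    --training-csv training.csv --out results
terp explain-text story.txt --blackbox-cmd "./score_lines"
terp explain-image photo.png --blackbox-cmd "./score_pngs" --tile-size 16
```

In Python, pass any callable mapping a batch of raw samples to
probabilities to `terp.run_explain` (see `terp.explain`). The
`terp diagnose-similarity` subcommand reproduces the Fisher-vs-Euclidean
similarity robustness experiment as a TSV of trial-wise similarity errors.

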