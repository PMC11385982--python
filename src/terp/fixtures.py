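"""Analytic black boxes with known ground truth, plus sanity harnesses.

Training real classifiers (state-assignment networks on molecular
dynamics trajectories, vision transformers, recurrent text models) is
out of scope here; what the explanation pipeline needs for validation
is *prediction access* plus a known answer.  Each factory below builds
a deterministic analytic classifier whose truly relevant features are
recorded, so end-to-end runs can be scored by exact support recovery:

* dihedral — a two-state molecular classifier over sines/cosines of
  four backbone dihedral angles (phi, psi, theta, omega), with the
  class boundary driven by sin(phi) and, weakly, sin(theta); mimics a
  metastable-state classifier whose states switch near phi ~ 0.
* image    — class probability driven by the texture contrast inside a
  few signal superpixels; flattening those tiles to their mean color
  erases the signal.
* text     — class probability driven by the presence of two keywords
  in a short document.

Also here: the feature-augmentation generator for the similarity
robustness experiment, the transition-state filter, and the
model-randomization sensitivity harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigError
from .rng import stream

__all__ = [
    "AnalyticBlackBox",
    "SensitivityReport",
    "make_dihedral_blackbox",
    "make_image_blackbox",
    "make_text_blackbox",
    "augment_features",
    "transition_state_filter",
    "randomize_blackbox",
    "randomization_sensitivity",
    "DIHEDRAL_FEATURES",
    "REFERENCE_ANGLES",
]

DIHEDRAL_FEATURES = (
    "sin_phi", "cos_phi", "sin_psi", "cos_psi",
    "sin_theta", "cos_theta", "sin_omega", "cos_omega",
)

# A near-transition-state configuration (radians) used as the default
# demo instance: phi close to 0, where the state assignment is most
# sensitive.
REFERENCE_ANGLES = (0.084, 0.007, 0.237, 2.990)


@dataclass(frozen=True)
class AnalyticBlackBox:
    """A deterministic classifier stand-in with recorded ground truth.

    ``predict`` maps a batch of raw samples to class probabilities in
    [0, 1]; ``relevant`` is the index set of truly influential
    representative features; ``params`` stores the generating
    coefficients so harnesses can randomize them.
    """

    kind: str
    predict: Callable[[Any], np.ndarray]
    relevant: tuple[int, ...]
    feature_names: tuple[str, ...]
    params: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class SensitivityReport:
    """Support overlap and weight divergence between two explanations."""

    support_a: tuple[int, ...]
    support_b: tuple[int, ...]
    overlap: float
    divergence: float


def angles_to_features(angles: np.ndarray) -> np.ndarray:
    """Map (m, 4) dihedral angles to the 8-dim sin/cos representation."""
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    out = np.empty((angles.shape[0], 8))
    out[:, 0::2] = np.sin(angles)
    out[:, 1::2] = np.cos(angles)
    return out


def make_dihedral_blackbox(
    seed: int = 0,
    sharpness: float = 4.0,
    secondary: float = 0.3,
    n_table: int = 2000,
) -> tuple[AnalyticBlackBox, np.ndarray]:
    """Two-state classifier over dihedral sin/cos features.

    Class probability is ``logistic(sharpness * sin(phi) + secondary *
    sin(theta))``: the assignment flips rapidly near phi ~ 0 with a
    weak secondary dependence on theta, the classic picture for the
    alanine-dipeptide-like two-well system.  Returns the black box and
    a sampled table of configurations (rows = sin/cos feature vectors,
    angles uniform on [-pi, pi)) standing in for training data.
    """
    if sharpness <= 0:
        raise ConfigError("sharpness must be positive")
    w = np.zeros(8)
    w[0] = sharpness  # sin_phi
    w[4] = secondary  # sin_theta

    def predict(X: np.ndarray, w: np.ndarray = w) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(X @ w)

    rng = stream(seed, "table")
    table = angles_to_features(rng.uniform(-np.pi, np.pi, size=(n_table, 4)))
    bb = AnalyticBlackBox(
        kind="dihedral",
        predict=predict,
        relevant=(0, 4),
        feature_names=DIHEDRAL_FEATURES,
        params={"weights": w},
    )
    return bb, table


def make_image_blackbox(
    tile_size: int = 16,
    image_shape: tuple[int, int] = (64, 64),
    signal_tiles: Sequence[int] = (5, 6, 9),
    seed: int = 0,
    gain: float = 10.0,
    offset: float = 0.15,
) -> tuple[AnalyticBlackBox, np.ndarray]:
    """Texture-sensitive image classifier plus its test image.

    The class probability is ``logistic(gain * (mean contrast over the
    signal tiles - offset))``, where contrast is the mean absolute
    deviation of grayscale intensity from the tile mean (intensities
    in [0, 1]).  Signal tiles carry a high-contrast checkerboard
    texture (contrast 0.3), so with the default offset at half that
    value the intact image scores ~0.82 while flattening every signal
    tile — exactly what the mean-color image perturbation does —
    drives the score down to ~0.18, past the 0.5 decision point.
    Perturbing any non-signal tile leaves the prediction untouched.
    """
    H, W = image_shape
    if H % tile_size or W % tile_size:
        raise ConfigError("tile size must partition the image")
    th, tw = H // tile_size, W // tile_size
    n = th * tw
    signal = tuple(sorted(int(t) for t in signal_tiles))
    if not signal or any(t < 0 or t >= n for t in signal):
        raise ConfigError(f"signal tiles must be a non-empty subset of 0..{n - 1}")

    rng = stream(seed, "fixture")
    img = np.empty((H, W, 3))
    for t in range(n):
        r, c = divmod(t, tw)
        sl = (slice(r * tile_size, (r + 1) * tile_size), slice(c * tile_size, (c + 1) * tile_size))
        base = rng.uniform(0.35, 0.65, size=3)
        img[sl] = base
        if t in signal:
            yy, xx = np.mgrid[0:tile_size, 0:tile_size]
            checker = ((yy // 2 + xx // 2) % 2).astype(float)  # 0/1 blocks
            img[sl] = 0.2 + 0.6 * checker[:, :, None]
    img = np.clip(img, 0.0, 1.0)

    def predict(batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=float)
        if batch.ndim == 3:
            batch = batch[None]
        if batch.max() > 1.5:  # uint8-scaled input
            batch = batch / 255.0
        gray = batch.mean(axis=-1)
        contrasts = []
        for t in signal:
            r, c = divmod(t, tw)
            tile = gray[:, r * tile_size:(r + 1) * tile_size, c * tile_size:(c + 1) * tile_size]
            mu = tile.mean(axis=(1, 2), keepdims=True)
            contrasts.append(np.abs(tile - mu).mean(axis=(1, 2)))
        return expit(gain * (np.mean(contrasts, axis=0) - offset))

    bb = AnalyticBlackBox(
        kind="image",
        predict=predict,
        relevant=signal,
        feature_names=tuple(f"tile_{r}_{c}" for r in range(th) for c in range(tw)),
        params={"gain": gain, "offset": offset, "tile_size": tile_size, "signal_tiles": signal},
    )
    return bb, img


def make_text_blackbox(
    vocab: Sequence[str] | None = None,
    keywords: tuple[str, str] = ("science", "species"),
    weights: tuple[float, float] = (2.5, 2.5),
    bias: float = -2.0,
    seed: int = 0,
    doc_length: int = 30,
) -> tuple[AnalyticBlackBox, list[str]]:
    """Keyword-presence text classifier plus a document containing both
    keywords among distractors.

    ``probability = logistic(w1 * present(k1) + w2 * present(k2) + bias)``:
    with the defaults, both keywords score 0.95, a single one 0.62,
    and neither 0.12.  The bias is deliberately *not* the symmetric
    ``-(w1+w2)/2``: a symmetric logistic over two indicators is exactly
    linear in them, which no trained text classifier is; the offset
    keeps a realistic residual nonlinearity.  Relevant indices refer
    to the distinct-token order of the returned document.
    """
    if vocab is None:
        vocab = (
            "the", "model", "predicts", "new", "results", "about", "data",
            "networks", "molecules", "study",
        )
    vocab = [v for v in vocab if v not in keywords]
    if not vocab:
        raise ConfigError("vocabulary must contain distractor tokens")
    k1, k2 = keywords
    w1, w2 = weights

    rng = stream(seed, "fixture")
    doc = [str(t) for t in rng.choice(vocab, size=doc_length)]
    # Plant each keyword twice at random positions (perturbation removes
    # *all* occurrences of a masked token, so multiplicity is realistic).
    for kw in (k1, k2):
        for pos in rng.integers(0, len(doc), size=2):
            doc.insert(int(pos), kw)

    def predict(samples: Sequence[Sequence[str]]) -> np.ndarray:
        out = np.empty(len(samples))
        for i, toks in enumerate(samples):
            s = set(toks)
            out[i] = expit(w1 * (k1 in s) + w2 * (k2 in s) + bias)
        return out

    from .neighborhood import distinct_tokens

    types = distinct_tokens(doc)
    relevant = tuple(sorted(types.index(k) for k in (k1, k2)))
    bb = AnalyticBlackBox(
        kind="text",
        predict=predict,
        relevant=relevant,
        feature_names=types,
        params={"keywords": keywords, "weights": weights, "bias": bias},
    )
    return bb, doc


def augment_features(
    design: np.ndarray,
    kind: str,
    count: int,
    a: float = 1.0,
    b: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Append uninformative columns for the similarity robustness test.

    ``pure_noise`` columns are standard normal draws; ``correlated``
    columns are ``a * x_i + b * N(0, 1)`` built from existing
    (standardized) columns, cycled in order.  ``count=0`` returns the
    design unchanged.
    """
    X = np.asarray(design, dtype=float)
    if count < 0:
        raise ConfigError("count must be non-negative")
    if count == 0:
        return X.copy()
    rng = stream(seed, "augment")
    N, n = X.shape
    if kind == "pure_noise":
        extra = rng.standard_normal((N, count))
    elif kind == "correlated":
        noise = rng.standard_normal((N, count))
        cols = [X[:, i % n] for i in range(count)]
        extra = a * np.column_stack(cols) + b * noise
    else:
        raise ConfigError(f"unknown augmentation kind {kind!r}")
    return np.column_stack([X, extra])


def transition_state_filter(
    prob_table: np.ndarray, threshold: float = 0.4
) -> np.ndarray:
    """Indices of configurations near a transition state.

    A row is kept when the probabilities of its two most likely classes
    both exceed ``threshold`` — i.e., the classifier is genuinely torn
    between two metastable states.
    """
    P = np.atleast_2d(np.asarray(prob_table, dtype=float))
    if P.shape[1] < 2:
        raise ConfigError("need probabilities for at least two classes")
    top2 = np.sort(P, axis=1)[:, -2:]
    return np.flatnonzero(np.all(top2 > threshold, axis=1))


def randomize_blackbox(bb: AnalyticBlackBox, seed: int = 0) -> AnalyticBlackBox:
    """Return a copy of a dihedral-style black box with its coefficients
    reassigned to previously irrelevant features.

    Emulates a parameter-randomized (corrupted) model: the learned
    feature dependence is destroyed, so a sound explanation method
    must produce a different explanation for it.  The new support is
    drawn disjoint from the original.
    """
    if "weights" not in bb.params:
        raise ConfigError("black box does not expose a coefficient vector")
    w = np.asarray(bb.params["weights"], dtype=float)
    rng = stream(seed, "randomize")
    old = list(bb.relevant)
    others = [k for k in range(w.size) if k not in old]
    if len(others) < len(old):
        raise ConfigError("not enough features to relocate the support")
    new = rng.choice(others, size=len(old), replace=False)
    w2 = np.zeros_like(w)
    w2[new] = w[old]

    def predict(X: np.ndarray, w: np.ndarray = w2) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(X @ w)

    return AnalyticBlackBox(
        kind=bb.kind,
        predict=predict,
        relevant=tuple(sorted(int(k) for k in new)),
        feature_names=bb.feature_names,
        params={"weights": w2},
    )


def randomization_sensitivity(
    bb: AnalyticBlackBox,
    bb_randomized: AnalyticBlackBox,
    instance: np.ndarray,
    stats,
    config=None,
) -> SensitivityReport:
    """Explain the same instance under both black boxes (identical
    seeds) and compare the explanations.

    Overlap is the Jaccard index of the optimal supports; divergence
    is the total-variation distance between the normalized weight
    vectors padded to the union support.  A sound setup gives
    overlap 1 / divergence 0 when ``bb_randomized`` *is* ``bb``.
    """
    from .explain import RunConfig, explain_tabular

    config = config or RunConfig(mode="tabular")
    _, ea = explain_tabular(bb.predict, instance, stats, config)
    _, eb = explain_tabular(bb_randomized.predict, instance, stats, config)
    sa, sb = set(ea.indices), set(eb.indices)
    union = sorted(sa | sb)
    overlap = len(sa & sb) / len(union) if union else 1.0
    pa = {k: p for k, p in zip(ea.indices, ea.p)}
    pb = {k: p for k, p in zip(eb.indices, eb.p)}
    tv = 0.5 * sum(abs(pa.get(k, 0.0) - pb.get(k, 0.0)) for k in union)
    return SensitivityReport(
        support_a=tuple(sorted(sa)),
        support_b=tuple(sorted(sb)),
        overlap=float(overlap),
        divergence=float(tv),
    )
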