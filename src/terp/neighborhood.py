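"""Local neighborhood generation around an instance to be explained.

A black-box prediction is explained by probing the model on randomly
perturbed copies of the instance.  Which features are perturbed in each
sample is encoded by a binary mask matrix; the raw perturbation itself
depends on the data modality:

* tabular  — continuous features are jittered by Gaussian noise scaled
  with the feature's training-set standard deviation; categorical
  features are resampled from the training pool,
* text     — masked tokens are removed from (or replaced in) the
  document,
* image    — masked superpixels are flattened to their mean color.

Alongside the raw samples, each modality produces a numeric *design
matrix* of representative features for the linear surrogate: z-scored
values for tabular data and presence/absence indicators (1 = intact)
for tokens and superpixels.  Row 0 is always the unperturbed instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .errors import ConfigError
from .rng import stream

__all__ = [
    "PerturbationMasks",
    "TrainingStats",
    "Neighborhood",
    "generate_perturbation_masks",
    "perturb_tabular",
    "perturb_text",
    "perturb_image",
    "distinct_tokens",
    "tokenize",
]


@dataclass(frozen=True)
class PerturbationMasks:
    """Binary perturbation plan: entry ``[i, k]`` is 1 iff feature ``k``
    is perturbed in sample ``i``.  Row 0 is all zeros (the instance)."""

    masks: np.ndarray
    seed: int
    mask_prob: float

    @property
    def n_samples(self) -> int:
        return self.masks.shape[0]

    @property
    def n_features(self) -> int:
        return self.masks.shape[1]


@dataclass(frozen=True)
class TrainingStats:
    """Per-feature summary statistics of the black box's training data.

    ``mean``/``sd`` cover continuous features; ``pools`` maps a
    categorical column index to the empirical pool of values observed
    in training; ``token_pool`` is the analogous pool for text
    replacement mode.
    """

    mean: np.ndarray
    sd: np.ndarray
    pools: dict[int, np.ndarray] = field(default_factory=dict)
    token_pool: tuple[str, ...] = ()

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        if mean.shape != sd.shape:
            raise ConfigError("mean and sd must have identical shapes")
        if np.any(sd < 0):
            raise ConfigError("standard deviations must be non-negative")
        for col, pool in self.pools.items():
            if len(pool) == 0:
                raise ConfigError(f"empty training pool for categorical column {col}")

    @classmethod
    def from_training_data(
        cls, data: np.ndarray, categorical_cols: Sequence[int] = ()
    ) -> "TrainingStats":
        """Compute stats from a (samples x features) training array."""
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ConfigError("training data must be 2-d with at least two rows")
        pools = {int(c): np.unique(data[:, c]) for c in categorical_cols}
        return cls(mean=data.mean(axis=0), sd=data.std(axis=0, ddof=1), pools=pools)


@dataclass
class Neighborhood:
    """Perturbed samples around one instance plus the surrogate inputs.

    ``samples`` holds raw representations suitable for the black box
    (array for tabular/image, list of token lists for text); ``design``
    is the numeric matrix of representative features; ``g`` holds the
    black-box class probabilities once evaluated (``None`` before).
    """

    instance: Any
    samples: Any
    design: np.ndarray
    feature_names: tuple[str, ...]
    g: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_features(self) -> int:
        return self.design.shape[1]

    def with_outputs(self, g: np.ndarray) -> "Neighborhood":
        g = np.asarray(g, dtype=float).ravel()
        if g.shape[0] != self.n_samples:
            raise ConfigError(
                f"g has {g.shape[0]} entries for {self.n_samples} samples"
            )
        return Neighborhood(self.instance, self.samples, self.design, self.feature_names, g)


def generate_perturbation_masks(
    n_features: int,
    n_samples: int,
    mask_prob: float = 0.5,
    seed: int = 0,
) -> PerturbationMasks:
    """Draw the binary perturbation plan for a neighborhood.

    Each entry of rows 1..N-1 is independently 1 with probability
    ``mask_prob`` (a feature is perturbed when its uniform draw falls
    below the threshold).  Row 0 is forced to all zeros so the
    unperturbed instance anchors the neighborhood.
    """
    if n_features < 1:
        raise ConfigError("n_features must be >= 1")
    if n_samples < 2:
        raise ConfigError("n_samples must be >= 2")
    if not 0.0 < mask_prob < 1.0:
        raise ConfigError("mask_prob must lie strictly between 0 and 1")
    rng = stream(seed, "masks")
    t = rng.random((n_samples - 1, n_features))
    body = (t < mask_prob).astype(np.uint8)
    masks = np.vstack([np.zeros((1, n_features), dtype=np.uint8), body])
    return PerturbationMasks(masks=masks, seed=int(seed), mask_prob=float(mask_prob))


def perturb_tabular(
    instance: np.ndarray,
    stats: TrainingStats,
    masks: PerturbationMasks,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> Neighborhood:
    """Build a tabular neighborhood.

    Masked continuous entries become ``x_k + eps * sd_k`` with
    ``eps ~ N(0, 1)``; masked categorical entries are resampled from
    the training pool.  The design matrix contains the z-scored sample
    values (continuous) or an equals-instance indicator (categorical),
    so a zero-variance feature contributes a constant zero column.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    n = instance.shape[0]
    if masks.n_features != n:
        raise ConfigError(
            f"masks cover {masks.n_features} features, instance has {n}"
        )
    if stats.mean.shape[0] != n:
        raise ConfigError("training stats do not cover all features")
    m = masks.masks.astype(float)
    N = masks.n_samples

    eps = stream(seed, "epsilon").standard_normal((N, n))
    samples = np.tile(instance, (N, 1))
    cont = np.ones(n, dtype=bool)
    for c in stats.pools:
        cont[c] = False
    samples[:, cont] += m[:, cont] * eps[:, cont] * stats.sd[cont]

    pool_rng = stream(seed, "pool")
    for c, pool in stats.pools.items():
        hit = masks.masks[:, c] == 1
        samples[hit, c] = pool_rng.choice(pool, size=int(hit.sum()))

    design = np.zeros((N, n))
    safe = stats.sd > 0
    cols = cont & safe
    design[:, cols] = (samples[:, cols] - stats.mean[cols]) / stats.sd[cols]
    for c in stats.pools:
        design[:, c] = (samples[:, c] == instance[c]).astype(float)

    names = tuple(feature_names) if feature_names else tuple(f"x{k}" for k in range(n))
    if len(names) != n:
        raise ConfigError("feature_names length mismatch")
    return Neighborhood(instance=instance, samples=samples, design=design, feature_names=names)


def tokenize(text: str) -> list[str]:
    """Default whitespace/punctuation tokenizer (lowercased words).

    Deliberately simple; callers with richer needs pass pre-tokenized
    input to :func:`perturb_text` directly.
    """
    import re

    return re.findall(r"[\w'-]+", text.lower())


def distinct_tokens(tokens: Sequence[str]) -> tuple[str, ...]:
    """Distinct token types in first-occurrence order."""
    seen: dict[str, None] = {}
    for t in tokens:
        seen.setdefault(t, None)
    return tuple(seen)


def perturb_text(
    tokens: Sequence[str],
    masks: PerturbationMasks,
    mode: str = "removal",
    stats: TrainingStats | None = None,
    seed: int = 0,
) -> Neighborhood:
    """Build a text neighborhood over the document's distinct tokens.

    Each distinct token type is one representative feature.  In
    ``removal`` mode (default) a masked type is deleted wherever it
    occurs; in ``replacement`` mode every occurrence is substituted by
    a token drawn from the training pool.  The design matrix is the
    presence indicator: 1 = token kept intact, 0 = perturbed.
    """
    tokens = list(tokens)
    if not tokens:
        raise ConfigError("token list is empty")
    types = distinct_tokens(tokens)
    n = len(types)
    if masks.n_features != n:
        raise ConfigError(f"masks cover {masks.n_features} features, document has {n} token types")
    if mode not in ("removal", "replacement"):
        raise ConfigError(f"unknown text perturbation mode {mode!r}")
    if mode == "replacement" and (stats is None or not stats.token_pool):
        raise ConfigError("replacement mode needs a non-empty training token pool")

    idx = {t: k for k, t in enumerate(types)}
    pool_rng = stream(seed, "pool")
    samples: list[list[str]] = []
    for row in masks.masks:
        if mode == "removal":
            samples.append([t for t in tokens if row[idx[t]] == 0])
        else:
            subs = {
                types[k]: pool_rng.choice(stats.token_pool)
                for k in np.flatnonzero(row)
            }
            samples.append([subs.get(t, t) for t in tokens])
    design = 1.0 - masks.masks.astype(float)
    return Neighborhood(
        instance=tokens, samples=samples, design=design, feature_names=types
    )


def perturb_image(
    image: np.ndarray,
    tile_size: int,
    masks: PerturbationMasks,
) -> Neighborhood:
    """Build an image neighborhood over a regular superpixel tiling.

    The image is partitioned into ``tile_size`` x ``tile_size`` tiles
    (row-major feature order).  A masked tile is replaced by its
    per-channel mean color; unmasked pixels are bit-identical.  Design
    entries: 1 = tile intact, 0 = flattened.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ConfigError("image must be HxW or HxWxC")
    H, W, C = image.shape
    if tile_size < 1 or H % tile_size or W % tile_size:
        raise ConfigError(
            f"tile size {tile_size} does not partition a {H}x{W} image"
        )
    th, tw = H // tile_size, W // tile_size
    n = th * tw
    if masks.n_features != n:
        raise ConfigError(f"masks cover {masks.n_features} features, tiling has {n} tiles")

    # Per-tile per-channel means, broadcast back to pixel resolution.
    tiles = image.reshape(th, tile_size, tw, tile_size, C).astype(float)
    means = tiles.mean(axis=(1, 3))  # (th, tw, C)
    flat = np.broadcast_to(
        means[:, None, :, None, :], (th, tile_size, tw, tile_size, C)
    ).reshape(H, W, C)
    if np.issubdtype(image.dtype, np.integer):
        flat = np.rint(flat).astype(image.dtype)
    else:
        flat = flat.astype(image.dtype)

    N = masks.n_samples
    samples = np.repeat(image[None], N, axis=0)
    pix_mask = (
        masks.masks.reshape(N, th, 1, tw, 1)
        .repeat(tile_size, axis=2)
        .repeat(tile_size, axis=4)
        .reshape(N, H, W)
        .astype(bool)
    )
    samples[pix_mask] = np.broadcast_to(flat, samples.shape)[pix_mask]

    design = 1.0 - masks.masks.astype(float)
    names = tuple(f"tile_{r}_{c}" for r in range(th) for c in range(tw))
    return Neighborhood(instance=image, samples=samples, design=design, feature_names=names)
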