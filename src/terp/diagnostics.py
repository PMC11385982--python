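"""Similarity-robustness experiment: Fisher projection vs Euclidean.

Repeats, over independent trials, the following check: build a local
neighborhood over four real (informative) features, compute similarity
weights, then append columns that carry *no* information — pure
standard-normal noise, or correlated copies ``a * x_i + b * N(0, 1)``
of existing standardized columns — and recompute the weights.  The
mean squared weight change (the similarity error) measures how badly
each metric is fooled by redundancy.  The Fisher-projected metric is
expected to be nearly immune; the standardized-Euclidean metric
degrades as soon as a single noise column appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .fixtures import augment_features
from .neighborhood import TrainingStats, generate_perturbation_masks, perturb_tabular
from .rng import stream
from .similarity import (
    binarize_predictions,
    euclidean_distances,
    fisher_projection,
    gaussian_weights,
    similarity_error,
)

__all__ = ["CONDITIONS", "similarity_robustness", "robustness_summary"]

# (label, augmentation kind, number of appended columns)
CONDITIONS = (
    ("plus_1_noise", "pure_noise", 1),
    ("plus_4_noise", "pure_noise", 4),
    ("plus_4_correlated", "correlated", 4),
)


@dataclass(frozen=True)
class _Trial:
    design: np.ndarray
    labels: np.ndarray


def _make_trial(seed: int, n_samples: int) -> _Trial:
    """One neighborhood over 4 informative dihedral-sine features."""
    rng = stream(seed, "fixture")
    angles = rng.uniform(-np.pi, np.pi, size=4)
    angles[0] = rng.uniform(-0.3, 0.3)  # anchor near the sensitive region
    instance = np.sin(angles)
    table = np.sin(rng.uniform(-np.pi, np.pi, size=(2000, 4)))
    stats = TrainingStats.from_training_data(table)
    masks = generate_perturbation_masks(4, n_samples, 0.5, seed)
    nb = perturb_tabular(instance, stats, masks, seed=seed)
    g = expit(4.0 * nb.samples[:, 0] + 0.3 * nb.samples[:, 2])
    labels = binarize_predictions(g).labels
    return _Trial(design=nb.design, labels=labels)


def _weights_lda(design: np.ndarray, labels: np.ndarray) -> np.ndarray:
    coords, _ = fisher_projection(design, labels)
    return gaussian_weights(coords, anchor_index=0).Pi


def _weights_euclidean(design: np.ndarray) -> np.ndarray:
    d = euclidean_distances(design, anchor_index=0)
    return gaussian_weights(-d, anchor_index=0).Pi


def similarity_robustness(
    n_trials: int = 100,
    seed: int = 0,
    n_samples: int = 2000,
    a: float = 1.0,
    b: float = 0.2,
) -> pd.DataFrame:
    """Trial-wise similarity errors for both metrics and all conditions.

    Returns a tidy frame with columns ``trial, condition,
    delta_pi_lda, delta_pi_euclidean``.
    """
    rows = []
    for t in range(n_trials):
        ts = int(np.random.SeedSequence([int(seed), t]).generate_state(1)[0] % (2**31))
        trial = _make_trial(ts, n_samples)
        pi_lda_o = _weights_lda(trial.design, trial.labels)
        pi_euc_o = _weights_euclidean(trial.design)
        for label, kind, count in CONDITIONS:
            aug = augment_features(trial.design, kind, count, a=a, b=b, seed=ts)
            rows.append(
                {
                    "trial": t,
                    "condition": label,
                    "delta_pi_lda": similarity_error(
                        pi_lda_o, _weights_lda(aug, trial.labels)
                    ),
                    "delta_pi_euclidean": similarity_error(
                        pi_euc_o, _weights_euclidean(aug)
                    ),
                }
            )
    return pd.DataFrame(rows)


def robustness_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Median similarity error per condition and metric."""
    return frame.groupby("condition")[["delta_pi_lda", "delta_pi_euclidean"]].median()
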