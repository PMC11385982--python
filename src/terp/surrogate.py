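"""Weighted linear surrogates and greedy forward feature selection.

The black box ``g`` is approximated near the instance by the linear
model ``F = f0 + sum_k f_k s_k`` over representative features.  Fits
minimize the similarity-weighted squared loss
``sum_i Pi_i [g(x_i) - F(x_i)]^2`` (closed-form weighted least
squares).  Fit quality is summarized by *unfaithfulness*

    U = 1 - |C(F, g)|,

with ``C`` the Pi-weighted Pearson correlation between surrogate and
black-box outputs, so ``U`` is in [0, 1] and 0 means perfectly
faithful.  The weighted correlation makes ``|C|^2`` equal the weighted
R^2 of the fit, which guarantees that along a nested forward-selection
path U is non-increasing in the support size j.

``forward_selection`` builds the whole family: the best single
feature, then greedily the best feature to add at each step, up to
``j_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .similarity import SimilarityWeights

__all__ = [
    "LinearSurrogate",
    "SurrogateFamily",
    "fit_weighted_linear",
    "unfaithfulness",
    "weighted_correlation",
    "forward_selection",
]

# Weighted variance below this (relative to the squared mean) counts as
# constant; generously above accumulated rounding of an exactly-constant
# vector, far below any genuine signal.
_VAR_EPS = 1e-20


@dataclass(frozen=True)
class LinearSurrogate:
    """One fitted surrogate: support, coefficients, fitted values.

    ``f`` is full length n with exact zeros off the support, so the
    coefficient vector can be fed directly to the entropy computation.
    """

    selected: tuple[int, ...]
    f0: float
    f: np.ndarray
    predictions: np.ndarray

    @property
    def j(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class SurrogateFamily:
    """Nested surrogates for j = 1..j_max and their unfaithfulness."""

    models: tuple[LinearSurrogate, ...]
    U: np.ndarray
    n_total: int

    @property
    def j_max(self) -> int:
        return len(self.models)


def _pi_vector(Pi, n: int) -> np.ndarray:
    w = Pi.Pi if isinstance(Pi, SimilarityWeights) else np.asarray(Pi, dtype=float)
    w = w.ravel()
    if w.shape[0] != n:
        raise ConfigError("similarity weights length mismatch")
    if np.any(w <= 0):
        raise ConfigError("similarity weights must be strictly positive")
    return w


def fit_weighted_linear(design_subset: np.ndarray, g: np.ndarray, Pi) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted least squares of g on the given columns plus intercept.

    Returns ``(f0, coefs, fitted)``.  A rank-deficient subset triggers
    a ridge-stabilized solve with a warning instead of failing: the
    surrogate family must survive duplicated or collinear features.
    """
    X = np.atleast_2d(np.asarray(design_subset, dtype=float))
    g = np.asarray(g, dtype=float).ravel()
    N, j = X.shape
    if N != g.shape[0]:
        raise ConfigError("design and g have different numbers of rows")
    if N <= j + 1:
        raise ConfigError(f"need N > j + 1 samples, got N={N} for j={j}")
    w = _pi_vector(Pi, N)
    sw = np.sqrt(w)
    A = np.column_stack([np.ones(N), X]) * sw[:, None]
    b = g * sw
    beta, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < j + 1:
        warnings.warn(
            "rank-deficient feature subset; using ridge-stabilized solve",
            RuntimeWarning,
            stacklevel=2,
        )
        lam = 1e-8 * max(np.trace(A.T @ A) / (j + 1), 1.0)
        beta = np.linalg.solve(A.T @ A + lam * np.eye(j + 1), A.T @ b)
    fitted = beta[0] + X @ beta[1:]
    return float(beta[0]), beta[1:], fitted


def weighted_correlation(F: np.ndarray, g: np.ndarray, Pi) -> float:
    """Pi-weighted Pearson correlation; 0 when F has zero weighted variance."""
    F = np.asarray(F, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    if F.shape != g.shape:
        raise ConfigError("F and g differ in length")
    w = _pi_vector(Pi, F.shape[0])
    w = w / w.sum()
    mF, mg = w @ F, w @ g
    vF = w @ (F - mF) ** 2
    vg = w @ (g - mg) ** 2
    if vg <= _VAR_EPS * max(1.0, mg * mg):
        raise DegenerateInputError(
            "black-box output is constant over the neighborhood; nothing to explain locally"
        )
    if vF <= _VAR_EPS * max(1.0, mF * mF):
        return 0.0
    c = (w @ ((F - mF) * (g - mg))) / np.sqrt(vF * vg)
    return float(np.clip(c, -1.0, 1.0))


def unfaithfulness(F: np.ndarray, g: np.ndarray, Pi, weighted: bool = True) -> float:
    """``U = 1 - |C(F, g)|`` in [0, 1]; 0 iff F tracks g up to an affine map.

    ``weighted=False`` uses the unweighted Pearson correlation, kept
    for comparison; the weighted form is the default because it ties
    |C|^2 to the weighted R^2 of the fits (and hence monotone U).
    """
    if not weighted:
        Pi = np.ones(np.asarray(F).size)
    return 1.0 - abs(weighted_correlation(F, g, Pi))


def forward_selection(
    design: np.ndarray,
    g: np.ndarray,
    Pi,
    j_max: int | None = None,
    weighted: bool = True,
) -> SurrogateFamily:
    """Greedy forward selection of the surrogate family.

    Step 1 fits all n single-feature models and keeps the one with the
    lowest U; each subsequent step adds the single feature whose
    inclusion minimizes U, keeping the previous support (nested path).
    Exact ties are broken toward the lowest feature index.
    """
    X = np.asarray(design, dtype=float)
    g = np.asarray(g, dtype=float).ravel()
    if X.ndim != 2:
        raise ConfigError("design must be 2-d")
    N, n = X.shape
    if n < 2:
        raise ConfigError("need at least 2 candidate features")
    j_max = n if j_max is None else int(j_max)
    if not 1 <= j_max <= n:
        raise ConfigError(f"j_max must lie in [1, {n}]")
    if N <= j_max + 1:
        raise ConfigError(f"N={N} too small for j_max={j_max} fits")
    w = _pi_vector(Pi, N)

    selected: list[int] = []
    models: list[LinearSurrogate] = []
    U: list[float] = []
    for _ in range(j_max):
        best = None  # (U, candidate, f0, coefs, fitted)
        for k in range(n):
            if k in selected:
                continue
            cols = selected + [k]
            f0, coefs, fitted = fit_weighted_linear(X[:, cols], g, w)
            u = unfaithfulness(fitted, g, w, weighted=weighted)
            if best is None or u < best[0]:
                best = (u, k, f0, coefs, fitted)
        u, k, f0, coefs, fitted = best
        selected.append(k)
        f = np.zeros(n)
        f[selected] = coefs
        models.append(
            LinearSurrogate(selected=tuple(selected), f0=f0, f=f, predictions=fitted)
        )
        U.append(u)

    U = np.asarray(U)
    # Nested weighted fits make U non-increasing; tolerate solver noise only.
    if np.any(np.diff(U) > 1e-9):
        raise AssertionError("unfaithfulness increased along the greedy path")
    return SurrogateFamily(models=tuple(models), U=np.minimum.accumulate(U), n_total=n)
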