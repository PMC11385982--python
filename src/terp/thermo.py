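"""Interpretation entropy and free-energy model selection.

A linear surrogate's coefficients, normalized by absolute value,
``p_k = |f_k| / sum|f_i|``, form a probability distribution over
features.  Its normalized Shannon entropy

    S = -(1/log n) * sum_k p_k log p_k          (0*log 0 := 0)

quantifies how hard the explanation is for a human to absorb: S = 0
for a single dominant feature, S = 1 for n equally important ones.

Combining entropy with the unfaithfulness U of each model in the
forward-selection family gives a free energy ``zeta^j = U^j + theta *
S^j`` tunable by a temperature-like parameter theta >= 0.  Between
consecutive sizes the stationarity condition ``delta zeta = 0``
defines characteristic temperatures ``theta^j = -dU/dS``; the size
reached by the *largest drop* in theta keeps the lowest free-energy
minimum over the widest temperature window and is selected as the
unique optimal explanation.  The reported optimal temperature is the
midpoint of the two characteristic temperatures bracketing the
selected size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConfigError, DegenerateInputError, SelectionError
from .surrogate import SurrogateFamily

__all__ = [
    "SelectionTrace",
    "Explanation",
    "interpretation_entropy",
    "entropy_profile",
    "characteristic_temperatures",
    "free_energy_curve",
    "select_optimal",
]

_DS_TOL = 1e-12  # |delta S| below this -> theta entry invalid


@dataclass(frozen=True)
class SelectionTrace:
    """Full record of the selection scan.

    ``theta`` has length j_max - 1 (entry j is the transition
    j -> j+1, 1-based); invalid entries (flat entropy) are NaN.
    ``zeta`` is evaluated at ``theta_opt``.
    """

    U: np.ndarray
    S: np.ndarray
    theta: np.ndarray
    zeta: np.ndarray
    j_opt: int
    theta_opt: float
    added_features: tuple[str, ...] = ()


@dataclass(frozen=True)
class Explanation:
    """The selected explanation: features, coefficients, and weights."""

    feature_names: tuple[str, ...]
    indices: tuple[int, ...]
    coefficients: np.ndarray
    p: np.ndarray
    U: float
    S: float
    j_opt: int
    theta_opt: float
    meta: dict[str, Any] = field(default_factory=dict)


def interpretation_entropy(f: np.ndarray, n_total: int) -> float:
    """Normalized Shannon entropy of the absolute coefficient weights.

    Normalization uses the total number of representative features
    ``n_total`` (not the support size), so entropies are comparable
    across models of different sparsity within one family.
    """
    f = np.asarray(f, dtype=float).ravel()
    if int(n_total) < 2:
        raise ConfigError("n_total must be >= 2")
    a = np.abs(f)
    tot = a.sum()
    if tot == 0 or not np.isfinite(tot):
        raise DegenerateInputError("all coefficients are zero; entropy undefined")
    p = a[a > 0] / tot
    return float(-(p @ np.log(p)) / np.log(n_total) + 0.0)


def entropy_profile(family: SurrogateFamily) -> np.ndarray:
    """S^j for every model in a forward-selection family."""
    return np.array(
        [interpretation_entropy(m.f, family.n_total) for m in family.models]
    )


def characteristic_temperatures(U: np.ndarray, S: np.ndarray) -> np.ndarray:
    """``theta^j = -(U^{j+1} - U^j) / (S^{j+1} - S^j)`` for j = 1..j_max-1.

    Transitions with numerically flat entropy (|delta S| < 1e-12) give
    NaN and are excluded from the selection scan: a temperature read
    off a vanishing entropy change is an artifact, not a signal.
    """
    U = np.asarray(U, dtype=float).ravel()
    S = np.asarray(S, dtype=float).ravel()
    if U.shape != S.shape:
        raise ConfigError("U and S differ in length")
    if U.size < 2:
        raise ConfigError("need at least two model sizes")
    dU, dS = np.diff(U), np.diff(S)
    theta = np.full(U.size - 1, np.nan)
    ok = np.abs(dS) >= _DS_TOL
    theta[ok] = -dU[ok] / dS[ok]
    return theta


def free_energy_curve(U: np.ndarray, S: np.ndarray, theta: float) -> np.ndarray:
    """``zeta^j = U^j + theta * S^j`` at a fixed temperature theta >= 0."""
    if theta < 0:
        raise ConfigError("theta must be non-negative")
    U = np.asarray(U, dtype=float).ravel()
    S = np.asarray(S, dtype=float).ravel()
    if U.shape != S.shape:
        raise ConfigError("U and S differ in length")
    return U + theta * S


def select_optimal(
    family: SurrogateFamily,
    S: np.ndarray | None = None,
    feature_names: tuple[str, ...] | None = None,
    meta: dict[str, Any] | None = None,
) -> tuple[SelectionTrace, Explanation]:
    """Scan the theta profile and return the unique optimal explanation.

    The optimal size ``j*`` follows the largest drop between
    consecutive valid characteristic temperatures; ties go to the
    smaller (sparser) size.  ``theta_opt`` is the midpoint of the two
    temperatures bracketing ``j*``.  Families with a single valid
    transition fall back to the sparser side of that transition.
    """
    S = entropy_profile(family) if S is None else np.asarray(S, dtype=float).ravel()
    U = np.asarray(family.U, dtype=float).ravel()
    if S.shape != U.shape:
        raise ConfigError("entropy vector does not match the family")
    theta = characteristic_temperatures(U, S)
    valid = np.flatnonzero(~np.isnan(theta))
    names = feature_names or tuple(f"x{k}" for k in range(family.n_total))
    added = tuple(names[m.selected[-1]] for m in family.models)

    if valid.size == 0:
        raise SelectionError(
            "no valid characteristic temperatures (entropy flat everywhere)",
            trace=SelectionTrace(
                U, S, theta, np.full_like(U, np.nan), 0, float("nan"), added
            ),
        )
    if valid.size == 1:
        # One transition only: prefer the sparser model at the zeta tie
        # that occurs exactly at theta = theta^1.
        t = int(valid[0])
        j_opt = t + 1
        theta_opt = float(theta[t])
    else:
        drops = theta[valid[1:]] - theta[valid[:-1]]
        k = int(np.argmin(drops))  # argmin takes the first (sparsest) tie
        # Model reached right after the transition the drop starts from.
        # When flat-entropy (invalid) transitions separate the two valid
        # temperatures, the models in between carry identical (U, S), so
        # the sparsest of them is selected.
        j_opt = int(valid[k]) + 2
        theta_opt = float((theta[valid[k]] + theta[valid[k + 1]]) / 2.0)

    zeta = free_energy_curve(U, S, max(theta_opt, 0.0))
    trace = SelectionTrace(
        U=U, S=S, theta=theta, zeta=zeta, j_opt=j_opt, theta_opt=theta_opt,
        added_features=added,
    )

    model = family.models[j_opt - 1]
    a = np.abs(model.f[list(model.selected)])
    p = a / a.sum()
    expl = Explanation(
        feature_names=tuple(names[k] for k in model.selected),
        indices=model.selected,
        coefficients=model.f[list(model.selected)].copy(),
        p=p,
        U=float(U[j_opt - 1]),
        S=float(S[j_opt - 1]),
        j_opt=j_opt,
        theta_opt=theta_opt,
        meta=dict(meta or {}),
    )
    return trace, expl
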