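"""End-to-end explanation pipeline, configuration, and adapters.

The pipeline is the same for every modality:

1. draw perturbation masks and build the neighborhood,
2. query the black box for class probabilities over the neighborhood,
3. binarize the probabilities and compute Fisher-projected Gaussian
   similarity weights (anchored at the unperturbed instance),
4. run greedy forward selection of weighted linear surrogates,
5. compute the entropy profile and select the optimal size by the
   free-energy temperature scan.

Black-box access is a callable mapping a batch of raw samples to class
probabilities; :func:`subprocess_adapter` wraps an external executable
behind the same contract so closed models can be explained without
linking against them.
"""

from __future__ import annotations

import json
import logging
import subprocess
import tempfile
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np

from . import __version__
from .errors import AdapterContractError, ConfigError, DegenerateNeighborhoodError
from .neighborhood import (
    Neighborhood,
    TrainingStats,
    generate_perturbation_masks,
    perturb_image,
    perturb_tabular,
    perturb_text,
)
from .similarity import (
    binarize_predictions,
    euclidean_distances,
    fisher_projection,
    gaussian_weights,
)
from .surrogate import forward_selection
from .thermo import Explanation, SelectionTrace, entropy_profile, select_optimal

logger = logging.getLogger("terp")

__all__ = [
    "RunConfig",
    "ExplanationRecord",
    "run_explain",
    "explain_tabular",
    "explain_text",
    "explain_image",
    "subprocess_adapter",
    "validate_predictions",
    "write_trace_tsv",
]

_MODES = ("tabular", "text", "image")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one explanation run.

    Defaults: 5000 neighborhood samples, perturbation probability 0.5,
    binarization threshold 0.5, kernel width sigma = 1, 16-pixel
    superpixel tiles, token-removal text perturbation.
    """

    mode: str = "tabular"
    n_samples: int = 5000
    seed: int = 0
    mask_prob: float = 0.5
    binarize_threshold: float = 0.5
    sigma: float = 1.0
    j_max: int | None = None
    similarity_fallback: str | None = None  # None or "euclidean"
    text_perturb_mode: str = "removal"
    tile_size: int = 16

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.n_samples < 10:
            raise ConfigError("n_samples must be >= 10")
        if not 0.0 < self.mask_prob < 1.0:
            raise ConfigError("mask_prob must lie strictly in (0, 1)")
        if not 0.0 <= self.binarize_threshold <= 1.0:
            raise ConfigError("binarize_threshold must lie in [0, 1]")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.similarity_fallback not in (None, "euclidean"):
            raise ConfigError("similarity_fallback must be None or 'euclidean'")
        if self.text_perturb_mode not in ("removal", "replacement"):
            raise ConfigError("text_perturb_mode must be 'removal' or 'replacement'")
        if self.tile_size < 1:
            raise ConfigError("tile_size must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid config JSON: {exc}") from exc
        return cls(**payload)


@dataclass(frozen=True)
class ExplanationRecord:
    """Serializable result of one run (JSON schema version 1)."""

    instance_id: str
    mode: str
    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    p: tuple[float, ...]
    U: float
    S: float
    j_opt: int
    theta_opt: float
    theta_trace: tuple[float, ...]
    config: dict[str, Any]
    version: str = __version__
    schema: int = 1

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExplanationRecord":
        payload = json.loads(text)
        for key in ("feature_names", "coefficients", "p", "theta_trace"):
            payload[key] = tuple(payload[key])
        return cls(**payload)


def validate_predictions(g: np.ndarray, n_expected: int) -> np.ndarray:
    """Enforce the adapter contract: one finite probability in [0, 1]
    per sample, naming the first offending row otherwise."""
    g = np.asarray(g, dtype=float).ravel()
    if g.shape[0] != n_expected:
        raise AdapterContractError(
            f"adapter returned {g.shape[0]} predictions for {n_expected} samples"
        )
    bad = np.flatnonzero(~np.isfinite(g) | (g < 0) | (g > 1))
    if bad.size:
        i = int(bad[0])
        raise AdapterContractError(
            f"adapter returned {g[i]!r} at row {i}; probabilities must lie in [0, 1]"
        )
    return g


def _similarity(nb: Neighborhood, g: np.ndarray, config: RunConfig):
    """Fisher-projected Gaussian weights, with optional Euclidean fallback."""
    try:
        labels = binarize_predictions(g, config.binarize_threshold)
        coords, _ = fisher_projection(nb.design, labels)
        return gaussian_weights(coords, anchor_index=0, sigma=config.sigma)
    except DegenerateNeighborhoodError:
        if config.similarity_fallback != "euclidean":
            raise
        logger.warning(
            "one-class neighborhood; falling back to standardized-Euclidean similarity"
        )
        d = euclidean_distances(nb.design, anchor_index=0)
        return gaussian_weights(-d, anchor_index=0, sigma=config.sigma)


def _finish(
    nb: Neighborhood, g: np.ndarray, config: RunConfig, meta: dict[str, Any]
) -> tuple[SelectionTrace, Explanation]:
    weights = _similarity(nb, g, config)
    t0 = time.perf_counter()
    family = forward_selection(nb.design, g, weights, j_max=config.j_max)
    logger.info("forward selection: %d sizes in %.2fs", family.j_max, time.perf_counter() - t0)
    S = entropy_profile(family)
    meta = {"seed": config.seed, "n_samples": config.n_samples, **meta}
    return select_optimal(family, S, feature_names=nb.feature_names, meta=meta)


def explain_tabular(
    predict: Callable,
    instance: np.ndarray,
    stats: TrainingStats,
    config: RunConfig,
    feature_names: Sequence[str] | None = None,
) -> tuple[SelectionTrace, Explanation]:
    """Explain one tabular prediction; returns (trace, explanation)."""
    masks = generate_perturbation_masks(
        len(np.ravel(instance)), config.n_samples, config.mask_prob, config.seed
    )
    nb = perturb_tabular(instance, stats, masks, seed=config.seed, feature_names=feature_names)
    g = validate_predictions(predict(nb.samples), nb.n_samples)
    return _finish(nb, g, config, {"mode": "tabular"})


def explain_text(
    predict: Callable,
    tokens: Sequence[str],
    config: RunConfig,
    stats: TrainingStats | None = None,
) -> tuple[SelectionTrace, Explanation]:
    """Explain one text prediction over the document's distinct tokens."""
    from .neighborhood import distinct_tokens

    n = len(distinct_tokens(tokens))
    masks = generate_perturbation_masks(n, config.n_samples, config.mask_prob, config.seed)
    nb = perturb_text(
        tokens, masks, mode=config.text_perturb_mode, stats=stats, seed=config.seed
    )
    g = validate_predictions(predict(nb.samples), nb.n_samples)
    return _finish(nb, g, config, {"mode": "text"})


def explain_image(
    predict: Callable,
    image: np.ndarray,
    config: RunConfig,
) -> tuple[SelectionTrace, Explanation]:
    """Explain one image prediction over a regular superpixel tiling."""
    image = np.asarray(image)
    H, W = image.shape[:2]
    t = config.tile_size
    if H % t or W % t:
        raise ConfigError(f"tile size {t} does not partition a {H}x{W} image")
    n = (H // t) * (W // t)
    masks = generate_perturbation_masks(n, config.n_samples, config.mask_prob, config.seed)
    nb = perturb_image(image, t, masks)
    g = validate_predictions(predict(nb.samples), nb.n_samples)
    return _finish(nb, g, config, {"mode": "image"})


def run_explain(
    config: RunConfig,
    instance: Any,
    predict: Callable,
    stats: TrainingStats | None = None,
    instance_id: str = "instance",
    feature_names: Sequence[str] | None = None,
) -> tuple[ExplanationRecord, SelectionTrace, Explanation]:
    """Dispatch on mode, run the full pipeline, and build the record."""
    t0 = time.perf_counter()
    if config.mode == "tabular":
        if stats is None:
            raise ConfigError("tabular mode requires training statistics")
        trace, expl = explain_tabular(predict, instance, stats, config, feature_names)
    elif config.mode == "text":
        trace, expl = explain_text(predict, instance, config, stats=stats)
    else:
        trace, expl = explain_image(predict, instance, config)
    logger.info("explained %s in %.2fs", instance_id, time.perf_counter() - t0)

    record = ExplanationRecord(
        instance_id=instance_id,
        mode=config.mode,
        feature_names=expl.feature_names,
        coefficients=tuple(float(c) for c in expl.coefficients),
        p=tuple(float(p) for p in expl.p),
        U=expl.U,
        S=expl.S,
        j_opt=expl.j_opt,
        theta_opt=expl.theta_opt,
        theta_trace=tuple(float(t) for t in trace.theta),
        config=asdict(config),
    )
    return record, trace, expl


def write_trace_tsv(path: str | Path, trace: SelectionTrace, family_features=None) -> None:
    """Dump the selection trace: j, added_feature, U, S, theta, zeta.

    ``theta`` is blank on the last row (no transition out of j_max);
    ``zeta`` is evaluated at the optimal temperature.
    """
    path = Path(path)
    feats = family_features if family_features is not None else trace.added_features
    lines = ["j\tadded_feature\tU\tS\ttheta\tzeta_at_theta_opt"]
    jmax = len(trace.U)
    for j in range(1, jmax + 1):
        th = "" if j == jmax or np.isnan(trace.theta[j - 1]) else repr(float(trace.theta[j - 1]))
        feat = str(feats[j - 1]) if feats else ""
        lines.append(
            f"{j}\t{feat}\t{float(trace.U[j - 1])!r}\t{float(trace.S[j - 1])!r}"
            f"\t{th}\t{float(trace.zeta[j - 1])!r}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def subprocess_adapter(
    command: Sequence[str],
    mode: str = "tabular",
    workdir: str | Path | None = None,
) -> Callable:
    """Wrap an external executable as a black-box prediction callable.

    The batch is serialized to a temp location (CSV for tabular, one
    UTF-8 line per sample for text, a directory of PNGs for images),
    the command is invoked with that path appended, and its standard
    output is parsed as one probability per line, order-preserving.
    """
    command = list(command)
    if mode not in _MODES:
        raise ConfigError(f"mode must be one of {_MODES}")

    def predict(batch) -> np.ndarray:
        with tempfile.TemporaryDirectory(dir=workdir) as tmp:
            tmp = Path(tmp)
            if mode == "tabular":
                arr = np.atleast_2d(np.asarray(batch, dtype=float))
                n = arr.shape[0]
                target = tmp / "batch.csv"
                header = ",".join(f"x{k}" for k in range(arr.shape[1]))
                np.savetxt(target, arr, delimiter=",", header=header, comments="")
            elif mode == "text":
                n = len(batch)
                target = tmp / "batch.txt"
                target.write_text(
                    "\n".join(" ".join(toks) for toks in batch) + "\n", encoding="utf-8"
                )
            else:
                from PIL import Image

                arr = np.asarray(batch)
                n = arr.shape[0]
                target = tmp / "images"
                target.mkdir()
                for i, im in enumerate(arr):
                    im8 = im if im.dtype == np.uint8 else np.clip(np.rint(im * 255), 0, 255).astype(np.uint8)
                    Image.fromarray(im8).save(target / f"{i:06d}.png")
            proc = subprocess.run(
                command + [str(target)], capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise AdapterContractError(
                    f"adapter command failed with code {proc.returncode}: {proc.stderr.strip()}"
                )
            lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
            if len(lines) != n:
                raise AdapterContractError(
                    f"adapter wrote {len(lines)} lines for {n} samples"
                )
            try:
                g = np.array([float(ln) for ln in lines])
            except ValueError as exc:
                raise AdapterContractError(f"non-numeric adapter output: {exc}") from exc
        return validate_predictions(g, n)

    return predict
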