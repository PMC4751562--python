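"""Linear calibration between the raw-read estimator and reference-based
target methylation levels.

Across species the GC-corrected estimate tracks the reference-based
level roughly 1:1, but systematic biases remain — most notably in
mammals, whose genomes deplete CpG dinucleotides outside CpG islands and
so violate the random-base assumption.  Calibration therefore fits
ordinary least squares of target on estimate per context, optionally
split by species class (general / plant / mammal), and scores accuracy as
the Mean Absolute Percentage Error (MAPE) of the fitted predictions.

The shipped default model is the identity (slope 1, intercept 0) for
every context and class; users fit their own models from (estimate,
target) tables for the taxa they study.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .contexts import ALL_CONTEXTS, Context, as_context
from .errors import ConfigurationError, EstimationError, FitError

__all__ = [
    "SPECIES_CLASSES",
    "CalibrationModel",
    "fit_linear_model",
    "compute_mape",
    "predict_target",
    "default_models",
    "select_model",
    "write_models",
    "read_models",
]

SPECIES_CLASSES = ("general", "plant", "mammal")
_MODEL_FILE_HEADER = "# rawmeth calibration models v1"


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from an estimate m_hat to a predicted target level."""

    context: Context
    species_class: str = "general"
    slope: float = 1.0
    intercept: float = 0.0
    r_squared: float = 1.0
    mape: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.species_class not in SPECIES_CLASSES:
            raise ConfigurationError(
                f"unknown species class {self.species_class!r}; "
                f"expected one of {SPECIES_CLASSES}"
            )

    @property
    def is_identity(self) -> bool:
        return self.slope == 1.0 and self.intercept == 0.0


def compute_mape(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent.

    Pairs with a zero actual value are excluded (near-zero methylomes,
    e.g. many insects, would otherwise blow up the average); if any are
    excluded a RuntimeWarning says how many.
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape or pred.size == 0:
        raise EstimationError("predicted and actual must be equal, nonzero length")
    nonzero = act != 0
    n_excluded = int((~nonzero).sum())
    if not nonzero.any():
        raise EstimationError("MAPE undefined: every actual value is zero")
    if n_excluded:
        _warnings.warn(
            f"MAPE excludes {n_excluded} pair(s) with zero actual value",
            RuntimeWarning, stacklevel=2,
        )
    return float(
        np.mean(np.abs(pred[nonzero] - act[nonzero]) / act[nonzero]) * 100.0
    )


def fit_linear_model(
    points: Sequence[tuple[float, float]],
    context: "Context | str",
    species_class: str = "general",
) -> CalibrationModel:
    """Ordinary least squares of target (y) on estimate (x).

    Requires at least two points with non-identical estimates.  MAPE is
    computed on the fitted values against the targets.
    """
    context = as_context(context)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise FitError("need at least 2 (estimate, target) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise FitError("zero variance in estimates; slope undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mape = compute_mape(fitted, y)
    except EstimationError:
        mape = float("nan")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float(res.rvalue**2) if ss_tot > 0 else 1.0
    return CalibrationModel(
        context=context,
        species_class=species_class,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        mape=mape,
        n_points=int(pts.shape[0]),
    )


def predict_target(m_hat: float, model: CalibrationModel) -> float:
    """Predicted reference-based level, floored at 0.

    Predictions above 1 emit a RuntimeWarning but are returned unclamped
    at the 1 end only after flooring at 0 (a level cannot be negative).
    """
    value = model.intercept + model.slope * float(m_hat)
    if value > 1.0:
        _warnings.warn(
            f"predicted level {value:.4f} exceeds 1", RuntimeWarning,
            stacklevel=2,
        )
    return max(0.0, value)


def default_models() -> dict[tuple[Context, str], CalibrationModel]:
    """Identity model for every (context, species class)."""
    return {
        (c, k): CalibrationModel(context=c, species_class=k)
        for c in ALL_CONTEXTS
        for k in SPECIES_CLASSES
    }


def select_model(
    models: Mapping[tuple[Context, str], CalibrationModel],
    context: "Context | str",
    species_class: str = "general",
) -> CalibrationModel:
    """Exact (context, class) match, else (context, general) with a
    warning; never silently crosses contexts."""
    context = as_context(context)
    if species_class not in SPECIES_CLASSES:
        raise ConfigurationError(f"unknown species class {species_class!r}")
    key = (context, species_class)
    if key in models:
        return models[key]
    fallback = (context, "general")
    if fallback in models:
        _warnings.warn(
            f"no {species_class} model for {context.value}; "
            "falling back to the general model",
            RuntimeWarning, stacklevel=2,
        )
        return models[fallback]
    raise ConfigurationError(f"no calibration model for context {context.value}")


def write_models(
    models: "Mapping[tuple[Context, str], CalibrationModel] | Iterable[CalibrationModel]",
    path,
) -> None:
    """Persist models as a versioned plain-text key-value file."""
    items = list(models.values()) if isinstance(models, Mapping) else list(models)
    lines = [_MODEL_FILE_HEADER, ""]
    for m in items:
        lines += [
            "[model]",
            f"context = {m.context.value}",
            f"species_class = {m.species_class}",
            f"slope = {m.slope!r}",
            f"intercept = {m.intercept!r}",
            f"r_squared = {m.r_squared!r}",
            f"mape = {m.mape!r}",
            f"n_points = {m.n_points}",
            "",
        ]
    Path(path).write_text("\n".join(lines))


def read_models(path) -> dict[tuple[Context, str], CalibrationModel]:
    """Load a model file written by :func:`write_models`."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    if not lines or not lines[0].startswith("# rawmeth calibration models"):
        raise ConfigurationError(f"{path}: not a calibration model file")
    models: dict[tuple[Context, str], CalibrationModel] = {}
    block: dict[str, str] = {}

    def close_block() -> None:
        if not block:
            return
        try:
            model = CalibrationModel(
                context=as_context(block["context"]),
                species_class=block["species_class"],
                slope=float(block["slope"]),
                intercept=float(block["intercept"]),
                r_squared=float(block["r_squared"]),
                mape=float(block["mape"]),
                n_points=int(block["n_points"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: model block missing {exc}") from exc
        models[(model.context, model.species_class)] = model
        block.clear()

    for ln in lines[1:]:
        if not ln or ln.startswith("#"):
            continue
        if ln == "[model]":
            close_block()
            continue
        if "=" not in ln:
            raise ConfigurationError(f"{path}: unparseable line {ln!r}")
        key, _, value = ln.partition("=")
        block[key.strip()] = value.strip()
    close_block()
    if not models:
        raise ConfigurationError(f"{path}: no models found")
    return models
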