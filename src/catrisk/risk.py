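"""Multinomial logistic TdP risk classification with a 0.8 decision threshold.

Fits a ridge-penalized three-class (high / intermediate / low) logistic
model on the per-compound predictor panel with a deterministic LBFGS
solver, and reports per-compound predicted probabilities. The faithful
default predicts the same compounds the model was trained on
(in-sample); a leave-one-out mode is provided as an extension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import matplotlib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .predictors import PredictorSet
from .registry import CellLine, RiskLabel

matplotlib.use("Agg", force=False)

__all__ = [
    "CLASS_ORDER",
    "RISK_THRESHOLD",
    "FitSpec",
    "RiskPrediction",
    "fit_risk_model",
    "predict_risk",
    "predict_risk_loo",
    "features_from_panel",
    "labels_from_registry",
    "plot_stacked_probabilities",
]

#: Fixed class order for every probability column.
CLASS_ORDER = (RiskLabel.HIGH, RiskLabel.INTERMEDIATE, RiskLabel.LOW)

#: Combined high+intermediate probability above which a compound is flagged.
RISK_THRESHOLD = 0.8


@dataclass(frozen=True)
class FitSpec:
    """Solver settings for the multinomial fit.

    ``penalty_strength_inverse`` is the ridge C (larger = weaker
    penalty); the optimizer is LBFGS capped at ``max_iterations``.
    """

    penalty_strength_inverse: float = 1.0
    max_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.penalty_strength_inverse <= 0:
            raise ValueError("penalty_strength_inverse must be > 0")


@dataclass(frozen=True)
class RiskPrediction:
    """Per-compound probability triple plus the combined-risk flag."""

    compound: str
    cell_line: CellLine
    prob_high: float
    prob_intermediate: float
    prob_low: float

    @property
    def combined_risk(self) -> float:
        return self.prob_high + self.prob_intermediate

    @property
    def exceeds_threshold(self) -> bool:
        return self.combined_risk > RISK_THRESHOLD

    def __post_init__(self) -> None:
        total = self.prob_high + self.prob_intermediate + self.prob_low
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {total}")


def features_from_panel(panel: Sequence[PredictorSet]) -> np.ndarray:
    """Assemble the n x 3 design matrix: ordinal type, normalized
    P80@Cmax, normalized P80_Max."""
    rows = []
    for p in panel:
        if not np.isfinite(p.p80_at_cmax_norm) or not np.isfinite(p.p80_max_norm):
            raise ValueError(
                f"{p.compound}: normalized predictors undefined; run "
                "normalize_panel first"
            )
        rows.append([p.atype.ordinal_score, p.p80_at_cmax_norm, p.p80_max_norm])
    return np.asarray(rows, dtype=float)


def labels_from_registry(panel, registry) -> list[str]:
    by_name = {r.name: r.risk_label.value for r in registry}
    return [by_name[p.compound] for p in panel]


def fit_risk_model(
    features: np.ndarray,
    labels: Sequence[str | RiskLabel],
    spec: FitSpec | None = None,
) -> LogisticRegression:
    """Fit the three-class multinomial logistic model.

    All three risk classes must be present. Non-convergence within the
    iteration cap raises a warning but still returns the coefficients.
    The fit is deterministic for fixed inputs.
    """
    spec = spec or FitSpec()
    X = np.asarray(features, dtype=float)
    y = np.array([RiskLabel(l).value for l in labels])
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be n x d with one label per row")
    present = set(y)
    missing = {c.value for c in CLASS_ORDER} - present
    if missing:
        raise ValueError(f"missing risk classes in training labels: {missing}")
    if X.shape[0] < 3:
        raise ValueError("need at least as many samples as classes")
    model = LogisticRegression(
        solver="lbfgs",
        C=spec.penalty_strength_inverse,
        max_iter=spec.max_iterations,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            warnings.warn(
                f"LBFGS did not converge within {spec.max_iterations} "
                "iterations; coefficients returned as-is",
                stacklevel=2,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
    # sklearn orders classes lexicographically: high, intermediate, low —
    # exactly the fixed CLASS_ORDER; assert to keep column semantics stable.
    assert list(model.classes_) == [c.value for c in CLASS_ORDER]
    return model


def predict_risk(
    model: LogisticRegression,
    features: np.ndarray,
    compounds: Sequence[str],
    cell_line: CellLine | str,
) -> list[RiskPrediction]:
    """Predicted probability triples for each compound."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coef_.shape[1]:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match fitted model ({model.coef_.shape[1]})"
        )
    if X.shape[0] != len(compounds):
        raise ValueError("one compound name per feature row required")
    cell_line = CellLine(cell_line)
    proba = model.predict_proba(X)
    return [
        RiskPrediction(
            compound=name,
            cell_line=cell_line,
            prob_high=float(p[0]),
            prob_intermediate=float(p[1]),
            prob_low=float(p[2]),
        )
        for name, p in zip(compounds, proba)
    ]


def predict_risk_loo(
    features: np.ndarray,
    labels: Sequence[str | RiskLabel],
    compounds: Sequence[str],
    cell_line: CellLine | str,
    spec: FitSpec | None = None,
) -> list[RiskPrediction]:
    """Leave-one-out prediction (extension; not the in-sample default).

    Each compound is predicted by a model trained on the other
    compounds. Requires all three classes to remain present in every
    training fold.
    """
    X = np.asarray(features, dtype=float)
    out: list[RiskPrediction] = []
    for i, name in enumerate(compounds):
        keep = np.arange(X.shape[0]) != i
        model = fit_risk_model(X[keep], [l for j, l in enumerate(labels) if j != i],
                               spec)
        out.extend(predict_risk(model, X[i : i + 1], [name], cell_line))
    return out


_STACK_COLORS = {
    RiskLabel.HIGH: "#08306b",
    RiskLabel.INTERMEDIATE: "#4292c6",
    RiskLabel.LOW: "#c6dbef",
}


def plot_stacked_probabilities(
    predictions: Sequence[RiskPrediction], path: str
) -> None:
    """Stacked probability bars per compound with a dotted line at 0.8.

    High, intermediate and low segments use dark blue, blue and light
    blue. SVG output is byte-deterministic for fixed input.
    """
    import matplotlib.pyplot as plt

    if not predictions:
        raise ValueError("need at least one prediction")
    names = [p.compound for p in predictions]
    highs = np.array([p.prob_high for p in predictions])
    inters = np.array([p.prob_intermediate for p in predictions])
    lows = np.array([p.prob_low for p in predictions])
    with matplotlib.rc_context({"svg.hashsalt": "catrisk"}):
        fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(names)), 4))
        x = np.arange(len(names))
        ax.bar(x, highs, color=_STACK_COLORS[RiskLabel.HIGH], label="high")
        ax.bar(x, inters, bottom=highs,
               color=_STACK_COLORS[RiskLabel.INTERMEDIATE], label="intermediate")
        ax.bar(x, lows, bottom=highs + inters,
               color=_STACK_COLORS[RiskLabel.LOW], label="low")
        ax.axhline(RISK_THRESHOLD, color="red", linestyle=":", linewidth=1.2)
        ax.set_xticks(x)
        ax.set_xticklabels(names, rotation=60, ha="right", fontsize=8)
        ax.set_ylabel("predicted probability")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        metadata = {"Date": None} if str(path).lower().endswith(".svg") else None
        fig.savefig(path, metadata=metadata, bbox_inches="tight")
        plt.close(fig)
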