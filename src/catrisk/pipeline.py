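"""End-to-end glue: simulate -> phenotype -> predictors -> risk model."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .phenotyping import (
    PARAMETER_NAMES,
    DetectionConfig,
    PhenotypeError,
    PhenotypeVector,
    percent_change,
    phenotype,
)
from .predictors import ClassifierConfig, PredictorSet, build_predictors, normalize_panel
from .registry import DMSO, CellLine, CompoundRecord, Phase, Trace, load_registry
from .risk import (
    FitSpec,
    RiskPrediction,
    features_from_panel,
    fit_risk_model,
    labels_from_registry,
    predict_risk,
    predict_risk_loo,
)
from .synth import TraceConfig, simulate_plate

log = logging.getLogger(__name__)

__all__ = [
    "build_well_table",
    "predictors_to_frame",
    "predictions_to_frame",
    "LineResult",
    "run_line_analysis",
    "run_default_pipeline",
]


def build_well_table(
    traces: Sequence[Trace], cfg: DetectionConfig | None = None
) -> pd.DataFrame:
    """Phenotype paired pre/post traces into a per-well table.

    One row per well with ``pre_*``, ``post_*`` and ``pct_*`` columns
    for the six parameters, the raw post-dose 80/20 ratio, and a
    ``ceased`` flag. Wells whose pre-dose trace has no cycles are
    excluded with a logged warning.
    """
    by_well: dict[str, dict[Phase, Trace]] = {}
    for tr in traces:
        by_well.setdefault(tr.meta.well_id, {})[tr.meta.phase] = tr
    rows = []
    for well_id, pair in by_well.items():
        if Phase.PRE not in pair or Phase.POST not in pair:
            raise ValueError(f"well {well_id} lacks a pre/post pair")
        pre_tr, post_tr = pair[Phase.PRE], pair[Phase.POST]
        pre = phenotype(pre_tr, cfg)
        post = phenotype(post_tr, cfg)
        try:
            change = percent_change(post, pre)
        except PhenotypeError:
            log.warning("well %s: no cycles in pre-dose trace; excluded", well_id)
            continue
        meta = post_tr.meta
        row: dict[str, object] = {
            "well_id": well_id,
            "cell_line": meta.cell_line.value,
            "compound": meta.compound,
            "dose_index": -1 if meta.dose_index is None else meta.dose_index,
            "ceased": change.ceased,
            "post_r82": post.r82,
        }
        for name in PARAMETER_NAMES:
            row[f"pre_{name}"] = getattr(pre, name)
            row[f"post_{name}"] = getattr(post, name)
            row[f"pct_{name}"] = getattr(change, name)
        rows.append(row)
    return pd.DataFrame(rows)


def predictors_to_frame(panel: Sequence[PredictorSet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": p.compound,
                "cell_line": p.cell_line.value,
                "arrhythmia_type": p.atype.value,
                "atype_score": p.atype.ordinal_score,
                "p80_at_cmax": p.p80_at_cmax,
                "p80_max": p.p80_max,
                "p80_at_cmax_norm": p.p80_at_cmax_norm,
                "p80_max_norm": p.p80_max_norm,
                "extrapolated": p.extrapolated,
            }
            for p in panel
        ]
    )


def predictions_to_frame(predictions: Sequence[RiskPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": p.compound,
                "cell_line": p.cell_line.value,
                "prob_high": p.prob_high,
                "prob_intermediate": p.prob_intermediate,
                "prob_low": p.prob_low,
                "combined_risk": p.combined_risk,
                "exceeds_threshold": p.exceeds_threshold,
            }
            for p in predictions
        ]
    )


@dataclass
class LineResult:
    """All per-line artifacts of one end-to-end run."""

    cell_line: CellLine
    well_table: pd.DataFrame
    panel: list[PredictorSet]
    model: LogisticRegression
    predictions: list[RiskPrediction]


def run_line_analysis(
    well_table: pd.DataFrame,
    registry: Sequence[CompoundRecord],
    cell_line: CellLine | str,
    classifier_cfg: ClassifierConfig | None = None,
    fit_spec: FitSpec | None = None,
    mode: str = "insample",
) -> LineResult:
    """Predictors + multinomial fit + risk prediction for one cell line."""
    cell_line = CellLine(cell_line)
    panel = normalize_panel(
        build_predictors(well_table, registry, cell_line, classifier_cfg)
    )
    X = features_from_panel(panel)
    y = labels_from_registry(panel, registry)
    compounds = [p.compound for p in panel]
    model = fit_risk_model(X, y, fit_spec)
    if mode == "insample":
        predictions = predict_risk(model, X, compounds, cell_line)
    elif mode == "loo":
        predictions = predict_risk_loo(X, y, compounds, cell_line, fit_spec)
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    line_table = well_table[well_table["cell_line"] == cell_line.value]
    return LineResult(cell_line, line_table, panel, model, predictions)


def run_default_pipeline(
    seed: int = 0,
    registry: Sequence[CompoundRecord] | None = None,
    duration: float = 30.0,
    fs: float = 50.0,
    replicates: Mapping[CellLine, int] | int | None = None,
    detection_cfg: DetectionConfig | None = None,
    classifier_cfg: ClassifierConfig | None = None,
    fit_spec: FitSpec | None = None,
    trace_cfg: TraceConfig | None = None,
    mode: str = "insample",
) -> dict[CellLine, LineResult]:
    """Full synthetic screen at the shipped default calibration.

    Simulates both cell-line plates, phenotypes every well, builds the
    predictor panels, and fits one risk model per cell line.
    """
    registry = list(registry) if registry is not None else load_registry()
    traces, _, _ = simulate_plate(
        registry,
        duration=duration,
        fs=fs,
        seed=seed,
        replicates=replicates,
        config=trace_cfg,
    )
    well_table = build_well_table(traces, detection_cfg)
    results = {}
    for line in (CellLine.CONTROL, CellLine.PROGERIA):
        results[line] = run_line_analysis(
            well_table, registry, line, classifier_cfg, fit_spec, mode
        )
    return results
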