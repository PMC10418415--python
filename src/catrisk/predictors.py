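"""Per-compound regression predictors: arrhythmia type, P80@Cmax, P80_Max.

Three features summarize each compound x cell line dose response:

1. an ordinal arrhythmia-waveform type (NONE=0, OTHER=1, TYPE_A=2),
2. the mean P80 percent change interpolated at the clinical Cmax
   (piecewise-linear in log10 dose, clamped at the dose-grid ends), and
3. the maximum mean P80 percent change over the dose grid.

The two continuous features are min-max normalized across the compound
panel within each cell line before entering the risk model.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import CellLine, CompoundRecord
from .transforms import ead_indicator

__all__ = [
    "ArrhythmiaType",
    "ClassifierConfig",
    "PredictorSet",
    "classify_arrhythmia",
    "p80_at_cmax",
    "p80_max",
    "build_predictors",
    "normalize_panel",
]


class ArrhythmiaType(enum.Enum):
    """Waveform categories: no change, extended-duration/cessation, EAD-like."""

    NONE = "none"
    OTHER = "other"
    TYPE_A = "type_a"

    @property
    def ordinal_score(self) -> int:
        return {"none": 0, "other": 1, "type_a": 2}[self.value]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the waveform-type decision rule.

    TYPE_A when at any dose at least ``ead_well_fraction`` of the wells
    have EAD indicator above ``ead_indicator_cut``; else OTHER when any
    dose has at least ``cease_well_fraction`` ceased wells or a mean P80
    change of at least ``other_p80_cutoff`` percent; else NONE.
    """

    ead_indicator_cut: float = 0.5
    ead_well_fraction: float = 0.25
    cease_well_fraction: float = 0.5
    other_p80_cutoff: float = 100.0


@dataclass(frozen=True)
class PredictorSet:
    """The three model predictors for one compound x cell line."""

    compound: str
    cell_line: CellLine
    atype: ArrhythmiaType
    p80_at_cmax: float
    p80_max: float
    extrapolated: bool = False
    p80_at_cmax_norm: float = math.nan
    p80_max_norm: float = math.nan


def classify_arrhythmia(
    well_table: pd.DataFrame, cfg: ClassifierConfig | None = None
) -> ArrhythmiaType:
    """Classify one compound x cell line table into a waveform type.

    ``well_table`` needs columns ``dose_index``, ``ceased``,
    ``post_r82`` and ``pct_p80``. Precedence: TYPE_A > OTHER > NONE.
    """
    cfg = cfg or ClassifierConfig()
    is_other = False
    for dose_index in sorted(well_table["dose_index"].unique()):
        rows = well_table[well_table["dose_index"] == dose_index]
        n = len(rows)
        indicator = ead_indicator(rows["post_r82"].to_numpy(dtype=float))
        ead_frac = float(np.sum(indicator > cfg.ead_indicator_cut)) / n
        if ead_frac >= cfg.ead_well_fraction:
            return ArrhythmiaType.TYPE_A
        ceased_frac = float(rows["ceased"].astype(bool).sum()) / n
        alive = rows[~rows["ceased"].astype(bool)]
        mean_p80 = float(alive["pct_p80"].mean()) if len(alive) else math.nan
        if ceased_frac >= cfg.cease_well_fraction or (
            np.isfinite(mean_p80) and mean_p80 >= cfg.other_p80_cutoff
        ):
            is_other = True
    return ArrhythmiaType.OTHER if is_other else ArrhythmiaType.NONE


def p80_at_cmax(
    doses: Sequence[float], means: Sequence[float], cmax: float
) -> tuple[float, bool]:
    """Interpolate the mean P80 change at Cmax, linear in log10(dose).

    Dose entries with undefined means (all wells ceased) are dropped
    first. A Cmax outside the surviving grid is clamped to the nearest
    endpoint and flagged ``extrapolated=True``. Returns ``(nan, True)``
    when no dose has a defined mean.
    """
    doses = np.asarray(doses, dtype=float)
    means = np.asarray(means, dtype=float)
    if doses.ndim != 1 or doses.shape != means.shape:
        raise ValueError("doses and means must be 1-D and equal length")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    if cmax <= 0:
        raise ValueError("cmax must be > 0")
    keep = np.isfinite(means)
    if not np.any(keep):
        return math.nan, True
    d, m = doses[keep], means[keep]
    extrapolated = bool(cmax < d[0] or cmax > d[-1])
    value = float(np.interp(math.log10(cmax), np.log10(d), m))
    return value, extrapolated


def p80_max(means: Sequence[float]) -> float:
    """Maximum defined per-dose mean P80 change; NaN when none is defined."""
    means = np.asarray(means, dtype=float)
    keep = np.isfinite(means)
    if not np.any(keep):
        return math.nan
    return float(np.max(means[keep]))


def _dose_means(well_table: pd.DataFrame) -> np.ndarray:
    means = np.full(4, math.nan)
    for dose_index in range(4):
        rows = well_table[well_table["dose_index"] == dose_index]
        alive = rows[~rows["ceased"].astype(bool)]
        if len(alive):
            means[dose_index] = float(alive["pct_p80"].mean())
    return means


def build_predictors(
    well_table: pd.DataFrame,
    registry: Sequence[CompoundRecord],
    cell_line: CellLine | str,
    cfg: ClassifierConfig | None = None,
) -> list[PredictorSet]:
    """Compute raw predictors for every registry compound in one cell line.

    ``well_table`` is the per-well percent-change table of the whole
    plate (one row per well); DMSO wells are ignored.
    """
    cell_line = CellLine(cell_line)
    table = well_table[well_table["cell_line"] == cell_line.value]
    out: list[PredictorSet] = []
    for rec in registry:
        sub = table[table["compound"] == rec.name]
        if sub.empty:
            raise ValueError(f"no wells for compound {rec.name!r}")
        means = _dose_means(sub)
        at_cmax, extrapolated = p80_at_cmax(rec.doses, means, rec.cmax)
        out.append(
            PredictorSet(
                compound=rec.name,
                cell_line=cell_line,
                atype=classify_arrhythmia(sub, cfg),
                p80_at_cmax=at_cmax,
                p80_max=p80_max(means),
                extrapolated=extrapolated,
            )
        )
    return out


def _minmax(values: np.ndarray) -> np.ndarray:
    defined = np.isfinite(values)
    lo, hi = np.min(values[defined]), np.max(values[defined])
    if hi == lo:
        warnings.warn("zero range in predictor panel; normalized values set to 0.5")
        out = np.where(defined, 0.5, math.nan)
        return out
    return (values - lo) / (hi - lo)


def normalize_panel(
    panel: Sequence[PredictorSet], method: str = "minmax"
) -> list[PredictorSet]:
    """Scale the continuous predictors across a single-line compound panel.

    ``minmax`` maps the defined values onto [0, 1]; ``zscore`` is the
    config alternative. The ordinal arrhythmia score is left unscaled.
    Requires at least two compounds with defined values.
    """
    lines = {p.cell_line for p in panel}
    if len(lines) != 1:
        raise ValueError("panel must come from a single cell line")
    at_cmax = np.array([p.p80_at_cmax for p in panel])
    p_max = np.array([p.p80_max for p in panel])
    if np.sum(np.isfinite(at_cmax)) < 2 or np.sum(np.isfinite(p_max)) < 2:
        raise ValueError("need at least 2 compounds with defined predictors")
    if method == "minmax":
        at_norm, max_norm = _minmax(at_cmax), _minmax(p_max)
    elif method == "zscore":
        at_norm = (at_cmax - np.nanmean(at_cmax)) / np.nanstd(at_cmax)
        max_norm = (p_max - np.nanmean(p_max)) / np.nanstd(p_max)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return [
        replace(p, p80_at_cmax_norm=float(a), p80_max_norm=float(m))
        for p, a, m in zip(panel, at_norm, max_norm)
    ]
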