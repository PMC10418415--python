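"""Percent-change transforms and dose-dependent radial (spider) profiles.

Two scalar transforms shape the radial axes: a logistic EAD indicator
applied to the raw post-dose 80/20 width ratio (centered at 3, slope 9),
and a signed base-10 log-modulus ``L(x) = sign(x) * log10(|x| + 1)``
applied to the remaining percent-change axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd
from scipy.special import expit

from .phenotyping import PARAMETER_NAMES
from .registry import CellLine

matplotlib.use("Agg", force=False)

__all__ = [
    "ead_indicator",
    "log_modulus",
    "RadialProfile",
    "build_radial_profile",
    "plot_radial",
    "DOSE_COLORS",
]

#: Dose 1-4 polygon colors, in order.
DOSE_COLORS = ("tab:blue", "tab:orange", "tab:green", "tab:red")

_EAD_SLOPE = 9.0
_EAD_CENTER = 3.0


def ead_indicator(x: float | np.ndarray) -> float | np.ndarray:
    """Logistic EAD indicator ``1 / (1 + exp(-9*(x - 3)))``.

    Strictly increasing with limits 0 and 1; equals 0.5 at ``x == 3``.
    Intended for the raw 80/20 width ratio, which sits near 2 for a
    clean pulse train and beyond 3 when a decay-phase hump stretches the
    80%-recovery width.
    """
    out = expit(_EAD_SLOPE * (np.asarray(x, dtype=float) - _EAD_CENTER))
    return float(out) if np.isscalar(x) else out


def log_modulus(x: float | np.ndarray) -> float | np.ndarray:
    """Signed base-10 log-modulus ``sign(x) * log10(|x| + 1)``.

    Odd, monotone, and defined at zero; compresses wide percent-change
    ranges onto comparable radial axes.
    """
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.log10(np.abs(arr) + 1.0)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class RadialProfile:
    """Transformed dose-response profile for one compound x cell line.

    ``per_dose`` is a 4 x 6 matrix (doses x parameters, in the order
    P80, 8/2, CL, AMP, PN, CSD). Continuous axes are NaN for a dose at
    which every replicate well ceased. ``survivors`` counts the
    non-ceased wells contributing to each dose's continuous axes.
    """

    compound: str
    cell_line: CellLine
    per_dose: np.ndarray
    survivors: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.per_dose.shape != (4, 6):
            raise ValueError("per_dose must be a 4 x 6 matrix")


def build_radial_profile(well_table: pd.DataFrame) -> RadialProfile:
    """Aggregate a per-well percent-change table into a radial profile.

    ``well_table`` must hold one compound x cell line: columns
    ``dose_index`` (0-3), ``ceased``, ``post_r82`` (raw post-dose 80/20
    ratio) and ``pct_<param>`` for the six parameters. Per dose, means
    are taken over replicate wells; the 8/2 axis is the EAD indicator of
    the mean raw post-dose ratio over surviving wells, the other five
    axes are log-modulus-transformed mean percent changes. Ceased wells
    contribute to the PN axis only.
    """
    compounds = well_table["compound"].unique()
    lines = well_table["cell_line"].unique()
    if len(compounds) != 1 or len(lines) != 1:
        raise ValueError("well_table must hold exactly one compound x cell line")
    matrix = np.full((4, 6), math.nan)
    survivors = []
    for dose_index in range(4):
        rows = well_table[well_table["dose_index"] == dose_index]
        if rows.empty:
            raise ValueError(f"no wells for dose index {dose_index}")
        alive = rows[~rows["ceased"].astype(bool)]
        survivors.append(len(alive))
        # PN axis includes ceased wells (a -100% count change is signal)
        matrix[dose_index, 4] = log_modulus(float(rows["pct_pn"].mean()))
        if len(alive):
            matrix[dose_index, 1] = ead_indicator(float(alive["post_r82"].mean()))
            for j, name in enumerate(PARAMETER_NAMES):
                if name in ("r82", "pn"):
                    continue
                matrix[dose_index, j] = log_modulus(
                    float(alive[f"pct_{name}"].mean())
                )
    return RadialProfile(
        compound=str(compounds[0]),
        cell_line=CellLine(lines[0]),
        per_dose=matrix,
        survivors=tuple(survivors),  # type: ignore[arg-type]
    )


_AXIS_LABELS = ("P80", "8/2", "CL", "AMP", "PN", "CSD")


def plot_radial(profile: RadialProfile, path: str) -> None:
    """Render a six-axis radial chart with one polygon per dose.

    Doses 1-4 use blue, orange, green and red; a dose whose continuous
    axes are all NaN (every well ceased) is omitted. SVG output is
    byte-deterministic for a fixed profile.
    """
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "catrisk"}):
        angles = np.linspace(0.0, 2.0 * np.pi, 6, endpoint=False)
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
        for d in range(4):
            row = profile.per_dose[d]
            if np.all(np.isnan(np.delete(row, 4))):
                continue
            closed = np.concatenate([row, row[:1]])
            theta = np.concatenate([angles, angles[:1]])
            ax.plot(theta, closed, color=DOSE_COLORS[d], label=f"Dose {d + 1}")
        ax.set_xticks(angles)
        ax.set_xticklabels(_AXIS_LABELS)
        ax.set_title(f"{profile.compound} ({profile.cell_line.value})")
        ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
        fig.savefig(path, metadata=_deterministic_metadata(path), bbox_inches="tight")
        plt.close(fig)


def _deterministic_metadata(path: str) -> dict | None:
    if str(path).lower().endswith(".svg"):
        return {"Date": None}
    return None
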