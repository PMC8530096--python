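"""Parameter-consistency sweeps over the benchmark series.

Evaluates the entropy curve of each input series while one parameter axis
(m, B, tau, r_coef or scale) varies, producing a tidy table for plotting or
trend assertions.  Infeasible combinations are flagged in the table rather
than aborting the sweep.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    EmbeddingError,
    EntropyParams,
    InvalidScaleError,
    MultichannelSeries,
    mm_mdisten,
)

__all__ = ["SWEEP_AXES", "run_sweep"]

SWEEP_AXES = ("m", "B", "tau", "r_coef", "scale")


def _params_for(base: EntropyParams, axis: str, value) -> EntropyParams:
    if axis == "scale":
        return base
    if axis == "B":
        return replace(base, B=int(value))
    if axis == "m":
        return replace(base, m=int(value))
    if axis == "tau":
        return replace(base, tau=int(value))
    if axis == "r_coef":
        return replace(base, r_coef=float(value))
    raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")


def run_sweep(
    series_map: Mapping[str, MultichannelSeries],
    axis: str,
    values: Sequence,
    base_params: EntropyParams | None = None,
) -> pd.DataFrame:
    """Cartesian sweep: every series x axis value x scale.

    Returns a tidy frame with columns ``series, axis, value, scale, entropy,
    feasible``, sorted by (series, value, scale).  For ``axis="scale"`` the
    swept values replace the scale list (one row per value).
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")
    base_params = base_params or EntropyParams()
    rows = []
    for name in sorted(series_map):
        series = series_map[name]
        for value in values:
            params = _params_for(base_params, axis, value)
            scales = [int(value)] if axis == "scale" else params.scales
            for s in scales:
                try:
                    ent = mm_mdisten(series, params, s)
                    ok = True
                except (EmbeddingError, InvalidScaleError, ValueError):
                    ent, ok = np.nan, False
                rows.append(
                    {
                        "series": name,
                        "axis": axis,
                        "value": value,
                        "scale": s,
                        "entropy": ent,
                        "feasible": ok,
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(["series", "value", "scale"], kind="stable").reset_index(drop=True)
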