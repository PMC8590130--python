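"""Fitted population-level circadian curves per marginal-mean cell."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SpecificationError, TWO_PI
from .emm import EmmSpec, marginal_linear_params
from .model import LinearFit


def predict_curve(fit: LinearFit, emm_spec: EmmSpec, time_grid) -> pd.DataFrame:
    """Evaluate the fitted cosinor curve of each grid cell over a time grid.

    For cell *g* the curve is ``M_g + beta_g*cos(2*pi*t/tau) +
    gamma_g*sin(2*pi*t/tau)``; its maximum over a period equals
    ``M_g + A_g`` and is attained at the cell's peak time.  Returns a
    long table (cell levels, t, fitted).
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise SpecificationError("time grid must not be empty")
    period = fit.spec.period
    grid = marginal_linear_params(fit, emm_spec)
    angle = TWO_PI * t / period
    cx, sz = np.cos(angle), np.sin(angle)
    frames = []
    for i in range(grid.n_cells):
        m, b, g = grid.coef[i]
        frame = pd.DataFrame({"t": t, "fitted": m + b * cx + g * sz})
        for col in grid.levels.columns:
            frame.insert(0, col, grid.levels.iloc[i][col])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
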