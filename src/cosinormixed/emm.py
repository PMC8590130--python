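"""Estimated marginal means (EMMs) of the linear cosinor parameters.

For each cell of a factor grid — e.g. ``~COVID`` (means by COVID
status) or ``~bmi_cat|sex`` (means by BMI category within each sex) —
the cell's linear parameters ``(M_g, beta_g, gamma_g)`` are an exact
linear combination ``L b`` of the fixed-effect coefficients: factors
named in the grid are held at their levels, all other model factors are
averaged over their levels (equal weights by default, as in emmeans).
The nonlinear parameters (MESOR, amplitude, acrophase) then follow by
the inverse relationship.  Uncertainty for the nonlinear parameters is
delegated to the bootstrap layer; this module only propagates the
linear-scale covariance ``L V L'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal

import numpy as np
import pandas as pd

from .core import SpecificationError, linear_to_cosinor, LinearCoefficients
from .model import LinearFit

__all__ = ["EmmSpec", "EmmGrid", "parse_emm_formula", "marginal_linear_params",
           "marginal_cosinor_params"]


@dataclass(frozen=True)
class EmmSpec:
    """Which factors index the grid, and how the rest are averaged.

    ``means_over`` are the factors whose level combinations index the
    grid (left of ``|`` in formula notation); ``conditioned_on`` are
    stratifying factors (right of ``|``): contrasts are later formed
    only within each conditioning stratum.
    """

    means_over: tuple[str, ...]
    conditioned_on: tuple[str, ...] = ()
    averaging_weights: Literal["equal", "proportional"] = "equal"

    def __post_init__(self) -> None:
        if not self.means_over:
            raise SpecificationError("means_over must name at least one factor")
        overlap = set(self.means_over) & set(self.conditioned_on)
        if overlap:
            raise SpecificationError(
                f"factors cannot be both means_over and conditioned_on: {sorted(overlap)}"
            )


def parse_emm_formula(formula: str, weights: str = "equal") -> EmmSpec:
    """Parse ``"~F"`` or ``"~F1|F2"`` (emmeans-style) into an EmmSpec.

    Multiple factors on either side are separated by ``+`` or ``*``.
    """
    s = formula.strip()
    if s.startswith("~"):
        s = s[1:]
    if not s:
        raise SpecificationError(f"cannot parse EMM formula {formula!r}")
    left, _, right = s.partition("|")

    def split(part: str) -> tuple[str, ...]:
        toks = [t.strip() for t in part.replace("*", "+").split("+")]
        return tuple(t for t in toks if t)

    return EmmSpec(
        means_over=split(left), conditioned_on=split(right),
        averaging_weights=weights,  # type: ignore[arg-type]
    )


@dataclass
class EmmGrid:
    """One row per (conditioning x means) level combination.

    ``coef[i]`` holds the cell's ``(M_g, beta_g, gamma_g)``; ``cov[i]``
    the corresponding 3x3 covariance block; ``L[i]`` the width-k weight
    row over the covariate design (identical across the three scales).
    Cells whose factor combination was never observed are flagged
    ``extrapolated``: the model-based mean is still defined, but rests
    on the additivity assumptions rather than data.
    """

    levels: pd.DataFrame  # grid factor level columns, one row per cell
    coef: np.ndarray  # n_cells x 3 (M, beta, gamma)
    cov: np.ndarray  # n_cells x 3 x 3
    L: np.ndarray  # n_cells x k
    extrapolated: np.ndarray  # bool per cell
    spec: EmmSpec
    period: float

    @property
    def n_cells(self) -> int:
        return len(self.levels)

    def cell_label(self, i: int) -> str:
        row = self.levels.iloc[i]
        return ",".join(f"{c}={row[c]}" for c in self.levels.columns)

    def linear_coefficients(self, i: int) -> LinearCoefficients:
        m, b, g = self.coef[i]
        return LinearCoefficients(mesor=float(m), beta=float(b), gamma=float(g))


def _averaging_weights(
    fit: LinearFit, factor: str, scheme: str
) -> dict[str, float]:
    levels = fit.design.levels[factor]
    if scheme == "equal":
        w = 1.0 / len(levels)
        return {lev: w for lev in levels}
    counts = fit.dataset.records[factor].value_counts()
    total = counts.sum()
    return {lev: counts.get(lev, 0) / total for lev in levels}


def marginal_linear_params(fit: LinearFit, spec: EmmSpec) -> EmmGrid:
    """Compute the EMM grid of linear cosinor parameters.

    Deterministic; invariant to the treatment-coding reference levels
    used in the fit (the user-facing contract).
    """
    design = fit.design
    model_factors = design.spec.all_factors()
    grid_factors = list(spec.conditioned_on) + list(spec.means_over)
    for f in grid_factors:
        if f not in model_factors:
            raise SpecificationError(f"factor {f!r} is not in the fitted model")
    averaged = [f for f in model_factors if f not in grid_factors]
    avg_weights = {
        f: _averaging_weights(fit, f, spec.averaging_weights) for f in averaged
    }

    k = design.k
    b = fit.params.to_numpy()
    V = fit.vcov.to_numpy()
    cells = list(product(*(design.levels[f] for f in grid_factors)))

    rows, covs, Ls, extrap = [], [], [], []
    level_records = []
    for cell in cells:
        assignment = dict(zip(grid_factors, cell))
        row = np.zeros(k)
        combos = list(product(*(avg_weights[f].items() for f in averaged)))
        for combo in combos:
            full = dict(assignment)
            weight = 1.0
            for f, (lev, w) in zip(averaged, combo):
                full[f] = lev
                weight *= w
            row += weight * design.covariate_row(full)
        if not combos:
            row = design.covariate_row(assignment)

        Lfull = np.zeros((3, 3 * k))
        for s in range(3):
            Lfull[s, s * k:(s + 1) * k] = row
        rows.append(Lfull @ b)
        covs.append(Lfull @ V @ Lfull.T)
        Ls.append(row)

        if model_factors and design.observed_cells:
            observed = any(
                tuple(dict(assignment, **{f: lev for f, (lev, _) in zip(averaged, combo)})[g]
                      for g in model_factors) in design.observed_cells
                for combo in (combos or [()])
            )
        else:
            observed = True
        extrap.append(not observed)
        level_records.append(dict(zip(grid_factors, cell)))

    return EmmGrid(
        levels=pd.DataFrame(level_records, columns=grid_factors),
        coef=np.array(rows),
        cov=np.array(covs),
        L=np.array(Ls),
        extrapolated=np.array(extrap, dtype=bool),
        spec=spec,
        period=fit.spec.period,
    )


def marginal_cosinor_params(grid: EmmGrid, period: float | None = None) -> pd.DataFrame:
    """Transform the EMM grid to the nonlinear scale, cell by cell.

    Returns one row per cell with the point estimates of MESOR,
    amplitude, acrophase (radians, in ``(-2*pi, 0]``) and peak time
    (hours).  These are point estimates only; confidence intervals come
    from the bootstrap, not the delta method, because amplitude and
    acrophase are nonlinear in the coefficients.
    """
    period = grid.period if period is None else period
    out = grid.levels.copy()
    params = [linear_to_cosinor(grid.linear_coefficients(i), period)
              for i in range(grid.n_cells)]
    out["mesor"] = [p.mesor for p in params]
    out["amplitude"] = [p.amplitude for p in params]
    out["acrophase"] = [p.acrophase for p in params]
    out["peak_time"] = [p.peak_time for p in params]
    out["degenerate"] = [p.degenerate for p in params]
    out["extrapolated"] = grid.extrapolated
    return out
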