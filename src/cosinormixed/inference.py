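"""Bootstrap inference for the nonlinear cosinor parameters.

Amplitude and acrophase are nonlinear functions of the fixed-effect
coefficients, so their sampling distributions are obtained by a
bootstrap.  Each replicate (1) regenerates data — by default
parametrically, simulating responses from the fitted model (estimated
fixed effects, random-effects covariance and residual variance); (2)
refits the same mixed model; (3) computes the marginal-mean grid of
linear parameters; (4) inverts to (MESOR, amplitude, acrophase) per
cell; and (5) forms all pairwise differences within each conditioning
stratum, acrophase differences wrapped to the minimal circular
difference.  Percentile confidence intervals and sign-count p-values
are then read off the replicate distributions.

Linear-scale hypotheses (any linear function of the coefficients) do
not need the bootstrap and are served by a Wald z-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .core import (
    SpecificationError,
    TWO_PI,
    wrap_phase_difference,
    wrap_time_difference,
)
from .data import CosinorDataset
from .emm import EmmGrid, EmmSpec, marginal_linear_params
from .model import LinearFit, fit as fit_model

__all__ = [
    "BootstrapResult",
    "bootstrap_cosinor",
    "percentile_ci",
    "bootstrap_p_value",
    "significance_stars",
    "wald_linear_test",
    "means_with_ci",
    "contrasts_with_ci",
]

PARAM_NAMES = ("mesor", "amplitude", "acrophase")

#: default number of bootstrap replicates
DEFAULT_N_SIM = 500
#: fraction of failed refits above which a result is flagged unreliable
MAX_FAILURE_FRACTION = 0.1


def percentile_ci(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval from bootstrap draws.

    Quantiles use linear (type-7) interpolation.  Identical draws give
    a valid zero-width interval.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise SpecificationError("need at least 2 draws for a percentile CI")
    if not 0 < level < 1:
        raise SpecificationError(f"ci level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_p_value(contrast_draws) -> float:
    """Two-sided add-one sign-count p-value for a bootstrap difference.

    p = 2 * min(#{d <= 0} + 1, #{d >= 0} + 1) / (B + 1), capped at 1:
    never exactly zero, and monotone in the evidence that the draws sit
    on one side of zero.
    """
    d = np.asarray(contrast_draws, dtype=float)
    if d.size < 1:
        raise SpecificationError("need at least 1 draw for a p-value")
    n_le = int(np.sum(d <= 0.0))
    n_ge = int(np.sum(d >= 0.0))
    p = 2.0 * min(n_le + 1, n_ge + 1) / (d.size + 1)
    return min(p, 1.0)


def significance_stars(p: float) -> str:
    """Significance label: *** <0.001, ** <0.01, * <0.05, + <0.1."""
    if not (0.0 <= p <= 1.0):
        raise SpecificationError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


@dataclass(frozen=True)
class WaldTest:
    estimate: float
    se: float
    z: float
    p_value: float


def wald_linear_test(fit: LinearFit, weights) -> WaldTest:
    """Wald z-test for a linear function w'b of the fixed effects.

    ``weights`` may be a vector over the coefficient index or a mapping
    term-name -> weight (unnamed terms get weight 0).
    """
    if isinstance(weights, dict):
        w = np.zeros(len(fit.params))
        idx = {name: i for i, name in enumerate(fit.params.index)}
        for name, val in weights.items():
            if name not in idx:
                raise SpecificationError(f"unknown coefficient {name!r}")
            w[idx[name]] = val
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(fit.params),):
            raise SpecificationError(
                f"weights length {w.shape} does not match {len(fit.params)} coefficients"
            )
    if not np.any(w):
        raise SpecificationError("weights must not be all zero")
    est = float(w @ fit.params.to_numpy())
    se = float(math.sqrt(w @ fit.vcov.to_numpy() @ w))
    z = est / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return WaldTest(estimate=est, se=se, z=z, p_value=p)


def _pairs_within_strata(grid: EmmGrid) -> list[tuple[int, int]]:
    """All cell pairs sharing their conditioning levels, in grid order."""
    cond = list(grid.spec.conditioned_on)
    if cond:
        keys = [tuple(grid.levels.iloc[i][c] for c in cond) for i in range(grid.n_cells)]
    else:
        keys = [()] * grid.n_cells
    pairs = []
    for a, b in combinations(range(grid.n_cells), 2):
        if keys[a] == keys[b]:
            pairs.append((a, b))
    return pairs


def _pair_label(grid: EmmGrid, a: int, b: int) -> str:
    mo = list(grid.spec.means_over)
    la = " ".join(str(grid.levels.iloc[a][f]) for f in mo)
    lb = " ".join(str(grid.levels.iloc[b][f]) for f in mo)
    return f"{la} - {lb}"


def _cell_params(grid_coef: np.ndarray, period: float) -> np.ndarray:
    """(n_cells, 3) array of (M, A, phi) from (M, beta, gamma) rows.

    Vectorized version of :func:`cosinormixed.core.linear_to_cosinor`
    (hot path of the bootstrap loop); phi follows the same (-2*pi, 0]
    convention, with phi = 0 at zero amplitude.
    """
    m = grid_coef[:, 0]
    beta = grid_coef[:, 1]
    gamma = grid_coef[:, 2]
    amp = np.hypot(beta, gamma)
    phi = np.arctan2(-gamma, beta)
    phi = np.where(phi > 0.0, phi - TWO_PI, phi)
    phi = np.where(amp == 0.0, 0.0, phi)
    return np.column_stack([m, amp, phi])


def _contrast_rows(cells: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    rows = np.empty((len(pairs), 3))
    for k, (a, b) in enumerate(pairs):
        rows[k, 0] = cells[a, 0] - cells[b, 0]
        rows[k, 1] = cells[a, 1] - cells[b, 1]
        rows[k, 2] = wrap_phase_difference(cells[a, 2], cells[b, 2])
    return rows


@dataclass
class BootstrapResult:
    """Replicate draws of cell-wise (M, A, phi) and their contrasts.

    ``draws`` has shape (B_success, n_cells, 3) on the parameter order
    (mesor, amplitude, acrophase); ``contrasts`` has shape
    (B_success, n_pairs, 3) with acrophase differences wrapped to
    ``(-pi, pi]``.  ``point`` and ``point_contrasts`` are the full-data
    estimates on the same layout.
    """

    grid: EmmGrid
    draws: np.ndarray
    contrasts: np.ndarray
    pairs: list[tuple[int, int]]
    pair_labels: list[str]
    point: np.ndarray
    point_contrasts: np.ndarray
    n_requested: int
    n_failed: int
    ci_level: float
    seed: int
    scheme: str

    @property
    def unreliable(self) -> bool:
        return self.n_failed > MAX_FAILURE_FRACTION * self.n_requested

    @property
    def n_success(self) -> int:
        return self.draws.shape[0]


def _parametric_replicates(fit: LinearFit, n_sim: int, rng: np.random.Generator):
    """Yield simulated response vectors from the fitted model."""
    design = fit.design
    Xb = design.X @ fit.params.to_numpy()
    groups = pd.Series(design.groups)
    codes, uniques = pd.factorize(groups, sort=False)
    n_sub = len(uniques)
    q = fit.cov_re.shape[0]
    # Sigma-hat can sit at the PSD boundary; draw through its symmetric square root
    evals, evecs = np.linalg.eigh(fit.cov_re)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    sd_resid = math.sqrt(fit.scale)
    Z = design.exog_re
    for _ in range(n_sim):
        theta = rng.standard_normal((n_sub, q)) @ root.T
        y = Xb + np.einsum("ij,ij->i", Z, theta[codes]) + rng.normal(0.0, sd_resid, len(Xb))
        yield y


def bootstrap_cosinor(
    fit: LinearFit,
    emm_spec: EmmSpec,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    scheme: str = "parametric",
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap the marginal-mean cosinor parameters and contrasts.

    ``scheme`` is ``"parametric"`` (simulate responses from the fitted
    model and refit; the default for mixed models) or
    ``"cluster_nonparametric"`` (resample whole subjects with
    replacement).  Failed refits are skipped and counted, never
    retried; more than 10% failures flags the result unreliable, and a
    run with no successful replicate is an error.  Reproducible given
    the seed.
    """
    if n_sim < 1:
        raise SpecificationError("n_sim must be >= 1")
    if scheme not in ("parametric", "cluster_nonparametric"):
        raise SpecificationError(f"unknown bootstrap scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    period = fit.spec.period

    grid = marginal_linear_params(fit, emm_spec)
    point = _cell_params(grid.coef, period)
    pairs = _pairs_within_strata(grid)
    pair_labels = [_pair_label(grid, a, b) for a, b in pairs]
    point_contrasts = _contrast_rows(point, pairs)

    draws, contrast_draws = [], []
    n_failed = 0
    if scheme == "parametric":
        design = fit.design
        model_template = (design.X, design.groups, design.exog_re)
        start = _start_params(fit)
        for y in _parametric_replicates(fit, n_sim, rng):
            fe = _refit_fe(model_template, y, fit.method == "reml", start)
            if fe is None:
                n_failed += 1
                continue
            coef = np.column_stack([
                grid.L @ fe[:design.k],
                grid.L @ fe[design.k:2 * design.k],
                grid.L @ fe[2 * design.k:],
            ])
            cells = _cell_params(coef, period)
            draws.append(cells)
            contrast_draws.append(_contrast_rows(cells, pairs))
    else:
        for _ in range(n_sim):
            cells = _cluster_replicate(fit, emm_spec, grid, rng)
            if cells is None:
                n_failed += 1
                continue
            draws.append(cells)
            contrast_draws.append(_contrast_rows(cells, pairs))

    if not draws:
        raise RuntimeError("all bootstrap replicates failed to refit")
    result = BootstrapResult(
        grid=grid,
        draws=np.array(draws),
        contrasts=np.array(contrast_draws),
        pairs=pairs,
        pair_labels=pair_labels,
        point=point,
        point_contrasts=point_contrasts,
        n_requested=n_sim,
        n_failed=n_failed,
        ci_level=ci_level,
        seed=seed,
        scheme=scheme,
    )
    if result.unreliable:
        warnings.warn(
            f"{n_failed}/{n_sim} bootstrap refits failed; result flagged unreliable",
            stacklevel=2,
        )
    return result


def _start_params(fit: LinearFit):
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    q = fit.cov_re.shape[0]
    return MixedLMParams.from_components(
        fe_params=fit.params.to_numpy(), cov_re=fit.cov_re / fit.scale
    )


def _refit_fe(template, y, reml: bool, start) -> np.ndarray | None:
    X, groups, exog_re = template
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = MixedLM(y, X, groups=groups, exog_re=exog_re).fit(
                reml=reml, method="lbfgs", start_params=start
            )
        except Exception:
            try:
                res = MixedLM(y, X, groups=groups, exog_re=exog_re).fit(
                    reml=reml, method="lbfgs"
                )
            except Exception:
                return None
    return np.asarray(res.fe_params)


def _cluster_replicate(
    fit: LinearFit, emm_spec: EmmSpec, grid: EmmGrid, rng: np.random.Generator
) -> np.ndarray | None:
    """One cluster (subject-level) nonparametric replicate."""
    df = fit.dataset.records
    subjects = df["subject_id"].unique()
    chosen = rng.choice(subjects, size=len(subjects), replace=True)
    blocks = []
    for j, s in enumerate(chosen):
        block = df[df["subject_id"] == s].copy()
        block["subject_id"] = f"bs{j}"
        blocks.append(block)
    new = CosinorDataset(
        records=pd.concat(blocks, ignore_index=True),
        period=fit.dataset.period,
        covariates=fit.dataset.covariates,
    )
    try:
        refit = fit_model(new, fit.spec, reml=fit.method == "reml")
        regrid = marginal_linear_params(refit, emm_spec)
    except Exception:
        return None
    if not regrid.levels.equals(grid.levels):
        return None
    return _cell_params(regrid.coef, fit.spec.period)


def _acrophase_ci(
    draws: np.ndarray, center: float, level: float
) -> tuple[float, float, bool]:
    """Percentile CI for a circular quantity.

    Draws are unwrapped onto the branch nearest the full-data estimate
    before taking quantiles, so the interval is a contiguous arc around
    the point estimate.  Returns (lower, upper, wide_flag); the flag is
    set when the unwrapped draw range exceeds pi, i.e. the arc covers
    more than half the circle and the interval is unstable.
    """
    adj = center + np.array([wrap_phase_difference(d, center) for d in draws])
    lo, hi = percentile_ci(adj, level)
    wide = bool(adj.max() - adj.min() > math.pi)
    return lo, hi, wide


def means_with_ci(boot: BootstrapResult) -> pd.DataFrame:
    """Cell-wise estimates with bootstrap percentile CIs.

    One row per grid cell; for each parameter the full-data point
    estimate and the percentile interval over replicates.  Acrophase
    intervals are taken on the branch nearest the point estimate and
    may extend outside ``(-2*pi, 0]``; cells with any zero-amplitude
    (degenerate) draw report an undefined acrophase interval.
    """
    grid = boot.grid
    out = grid.levels.copy()
    level = boot.ci_level
    for j, name in enumerate(PARAM_NAMES):
        est = boot.point[:, j]
        lo = np.empty(grid.n_cells)
        hi = np.empty(grid.n_cells)
        flags = []
        for i in range(grid.n_cells):
            d = boot.draws[:, i, j]
            if name == "acrophase":
                degen = np.abs(boot.draws[:, i, 1]) == 0.0
                if degen.any() or boot.point[i, 1] == 0.0:
                    lo[i], hi[i] = np.nan, np.nan
                    flags.append("undefined")
                    continue
                lo[i], hi[i], wide = _acrophase_ci(d, est[i], level)
                flags.append("wide" if wide else "")
            else:
                lo[i], hi[i] = percentile_ci(d, level)
                flags.append("")
        out[name] = est
        out[f"{name}_lower"] = lo
        out[f"{name}_upper"] = hi
        if name == "acrophase":
            out["acrophase_flag"] = flags
    period = grid.period
    out["peak_time"] = (-out["acrophase"] * period / TWO_PI) % period
    out["extrapolated"] = grid.extrapolated
    return out


def contrasts_with_ci(boot: BootstrapResult) -> pd.DataFrame:
    """Pairwise contrasts with percentile CIs, p-values and stars.

    One row per (stratum, pair, parameter).  Acrophase contrasts are
    reported in radians wrapped to ``(-pi, pi]`` and additionally as a
    peak-time difference in hours wrapped to ``(-tau/2, tau/2]``.
    """
    grid = boot.grid
    cond = list(grid.spec.conditioned_on)
    period = grid.period
    rows = []
    for k, (a, b) in enumerate(boot.pairs):
        stratum = {c: grid.levels.iloc[a][c] for c in cond}
        for j, name in enumerate(PARAM_NAMES):
            d = boot.contrasts[:, k, j]
            est = boot.point_contrasts[k, j]
            if name == "acrophase":
                lo, hi, wide = _acrophase_ci(d, est, boot.ci_level)
                flag = "wide" if wide else ""
            else:
                lo, hi = percentile_ci(d, boot.ci_level)
                flag = ""
            p = bootstrap_p_value(d)
            rows.append(
                {
                    **stratum,
                    "contrast": boot.pair_labels[k],
                    "parameter": name,
                    "estimate": est,
                    "lower": lo,
                    "upper": hi,
                    "p_value": p,
                    "stars": significance_stars(p),
                    "flag": flag,
                }
            )
            if name == "acrophase":
                # hour scale: peak-time shift is a monotone (negating)
                # transform of the radian difference, so the interval maps
                # endpoint-to-endpoint with the bounds swapped
                dh = np.array([wrap_time_difference(v, period) for v in d])
                est_h = wrap_time_difference(est, period)
                lo_h = -hi * period / TWO_PI
                hi_h = -lo * period / TWO_PI
                rows.append(
                    {
                        **stratum,
                        "contrast": boot.pair_labels[k],
                        "parameter": "acrophase_hours",
                        "estimate": est_h,
                        "lower": lo_h,
                        "upper": hi_h,
                        "p_value": bootstrap_p_value(dh),
                        "stars": significance_stars(bootstrap_p_value(dh)),
                        "flag": flag,
                    }
                )
    report = pd.DataFrame(rows)
    bad = report["lower"] > report["upper"]
    assert not bad.any(), "percentile interval inverted"
    return report
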