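"""Mixed-effects cosinor model: design construction and fitting.

The fitted model for subject *i* at time *t* is

    Y_it = M + a0*C_i + (beta + a2*C_i) * x_it + (gamma + a3*C_i) * z_it
           + W_it * theta_i + e_i(t)

where ``C`` holds treatment-coded categorical covariates, ``x``/``z``
are the unit-circle rhythm regressors, ``theta_i ~ N(0, Sigma)`` are
subject-level random effects capturing within-subject correlation, and
``e ~ N(0, s)`` is residual noise.  Every covariate (or interaction
cell) enters three ways: as a main effect (shifting the MESOR) and
crossed with ``x`` and ``z`` (shifting amplitude and acrophase).

Two random-effect structures are supported: a random MESOR per subject
(``1 | id``) and random MESOR plus rhythm coefficients
(``1 + x + z | id``), with a full (correlated) covariance.

Estimation uses REML by default via :class:`statsmodels` ``MixedLM``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.linalg import qr
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .core import SpecificationError
from .data import CosinorDataset, X_COL, Z_COL

logger = logging.getLogger(__name__)

RANDOM_MESOR = "random_mesor"
RANDOM_MESOR_AND_RHYTHM = "random_mesor_and_rhythm"


class RankDeficiencyError(SpecificationError):
    """The fixed-effects design is not of full column rank."""


@dataclass
class ModelSpec:
    """Declarative description of a mixed-effects cosinor model.

    Parameters
    ----------
    factors
        Categorical covariates entering additively (each crossed with
        the rhythm regressors).
    interaction_factors
        Optional pairs of factors whose full interaction enters the
        model; the pair's main effects are included automatically.
    random_structure
        ``"random_mesor"`` (random intercept) or
        ``"random_mesor_and_rhythm"`` (random intercept, x and z).
    reference_levels
        Optional map factor -> reference level for treatment coding;
        defaults to the alphabetically first observed level.
    """

    factors: list[str] = field(default_factory=list)
    interaction_factors: list[tuple[str, str]] = field(default_factory=list)
    random_structure: Literal["random_mesor", "random_mesor_and_rhythm"] = RANDOM_MESOR
    period: float = 24.0
    response: str = "response"
    grouping: str = "subject_id"
    reference_levels: dict = field(default_factory=dict)

    def all_factors(self) -> list[str]:
        """Model factors in deterministic order (mains then interaction
        members), without duplicates."""
        seen: list[str] = []
        for f in list(self.factors) + [f for pair in self.interaction_factors for f in pair]:
            if f not in seen:
                seen.append(f)
        return seen

    def validate(self, dataset: CosinorDataset) -> None:
        if self.random_structure not in (RANDOM_MESOR, RANDOM_MESOR_AND_RHYTHM):
            raise SpecificationError(
                f"unknown random structure {self.random_structure!r}"
            )
        for pair in self.interaction_factors:
            if len(pair) != 2:
                raise SpecificationError("interaction_factors must be pairs")
        for f in self.all_factors():
            if f not in dataset.records.columns:
                raise SpecificationError(f"factor {f!r} not present in the dataset")
            n_levels = dataset.records[f].dropna().nunique()
            if n_levels < 2:
                raise SpecificationError(
                    f"factor {f!r} has {n_levels} observed level(s); need >= 2"
                )


@dataclass
class Design:
    """Materialized fixed- and random-effects design for a dataset.

    The fixed-effects coefficient vector is ordered in three blocks of
    equal width ``k``: MESOR-scale terms, the same terms crossed with
    ``x``, and with ``z``.  ``covariate_row`` evaluates the width-``k``
    covariate row for a complete factor-level assignment, which is the
    primitive used for marginal means.
    """

    spec: ModelSpec
    levels: dict[str, list[str]]  # factor -> levels, reference first
    base_columns: list[str]  # covariate-design column names (width k)
    column_names: list[str]  # all 3k fixed-effect names
    X: np.ndarray  # n x 3k fixed design
    exog_re: np.ndarray  # n x q random-effects design
    re_names: list[str]
    groups: np.ndarray
    observed_cells: set  # observed level combinations over all factors

    @property
    def k(self) -> int:
        return len(self.base_columns)

    def covariate_row(self, assignment: dict[str, str]) -> np.ndarray:
        """Width-k covariate row for one level per model factor."""
        row = np.zeros(self.k)
        row[0] = 1.0
        pos = {name: j for j, name in enumerate(self.base_columns)}
        for f in self.spec.all_factors():
            lev = assignment[f]
            if lev not in self.levels[f]:
                raise SpecificationError(f"unknown level {lev!r} for factor {f!r}")
            name = f"{f}[{lev}]"
            if name in pos:
                row[pos[name]] = 1.0
        for fa, fb in self.spec.interaction_factors:
            name = f"{fa}[{assignment[fa]}]:{fb}[{assignment[fb]}]"
            if name in pos:
                row[pos[name]] = 1.0
        return row


def _factor_levels(dataset: CosinorDataset, spec: ModelSpec) -> dict[str, list[str]]:
    levels = {}
    for f in spec.all_factors():
        obs = sorted(dataset.records[f].dropna().unique())
        ref = spec.reference_levels.get(f, obs[0])
        if ref not in obs:
            raise SpecificationError(
                f"reference level {ref!r} for factor {f!r} not observed"
            )
        levels[f] = [ref] + [l for l in obs if l != ref]
    return levels


def build_design(dataset: CosinorDataset, spec: ModelSpec) -> Design:
    """Construct the treatment-coded fixed and random effects designs.

    Column ordering is deterministic: the intercept, factor dummies in
    declaration order (levels alphabetical within factor, reference
    omitted), interaction product dummies; the whole block is then
    repeated crossed with ``x`` and with ``z``.
    """
    spec.validate(dataset)
    df = dataset.records
    levels = _factor_levels(dataset, spec)

    base_cols: list[str] = ["Intercept"]
    base_mats: list[np.ndarray] = [np.ones(len(df))]
    dummies: dict[tuple[str, str], np.ndarray] = {}
    for f in spec.all_factors():
        for lev in levels[f][1:]:
            d = (df[f] == lev).to_numpy(dtype=float)
            dummies[(f, lev)] = d
            base_cols.append(f"{f}[{lev}]")
            base_mats.append(d)
    for fa, fb in spec.interaction_factors:
        for la in levels[fa][1:]:
            for lb in levels[fb][1:]:
                base_cols.append(f"{fa}[{la}]:{fb}[{lb}]")
                base_mats.append(dummies[(fa, la)] * dummies[(fb, lb)])

    D = np.column_stack(base_mats) if base_mats else np.ones((len(df), 1))
    x = df[X_COL].to_numpy()
    z = df[Z_COL].to_numpy()

    def crossed(name: str, reg: str) -> str:
        return reg if name == "Intercept" else f"{name}:{reg}"

    names = (
        list(base_cols)
        + [crossed(c, X_COL) for c in base_cols]
        + [crossed(c, Z_COL) for c in base_cols]
    )
    X = np.hstack([D, D * x[:, None], D * z[:, None]])

    if spec.random_structure == RANDOM_MESOR:
        exog_re = np.ones((len(df), 1))
        re_names = ["Intercept"]
    else:
        exog_re = np.column_stack([np.ones(len(df)), x, z])
        re_names = ["Intercept", X_COL, Z_COL]

    singletons = df.groupby("subject_id").size()
    n_single = int((singletons == 1).sum())
    if n_single:
        logger.info("%d subject(s) contribute a single observation", n_single)

    observed = set(
        map(tuple, df[spec.all_factors()].drop_duplicates().itertuples(index=False))
    ) if spec.all_factors() else set()

    return Design(
        spec=spec,
        levels=levels,
        base_columns=base_cols,
        column_names=names,
        X=X,
        exog_re=exog_re,
        re_names=re_names,
        groups=df["subject_id"].to_numpy(),
        observed_cells=observed,
    )


@dataclass
class LinearFit:
    """A fitted mixed-effects cosinor model on the linear scale.

    ``params`` indexes the fixed effects by term name (three blocks:
    MESOR scale, ``:x`` terms, ``:z`` terms); ``vcov`` is their
    sampling covariance.  ``cov_re`` is the estimated random-effects
    covariance Sigma and ``scale`` the residual variance s.
    """

    params: pd.Series
    vcov: pd.DataFrame
    cov_re: np.ndarray
    re_names: list[str]
    scale: float
    converged: bool
    boundary: bool
    n_obs: int
    n_subjects: int
    spec: ModelSpec
    design: Design
    dataset: CosinorDataset
    method: str  # "reml" or "ml"

    def fitted_values(self) -> np.ndarray:
        return self.design.X @ self.params.to_numpy()

    def summary_text(self) -> str:
        lines = [
            "Mixed-effects cosinor fit",
            f"  estimation: {self.method.upper()}, converged={self.converged}"
            + (" (variance boundary)" if self.boundary else ""),
            f"  observations: {self.n_obs}  subjects: {self.n_subjects}",
            f"  period: {self.spec.period} h",
            "",
            f"  {'term':<28} {'estimate':>12} {'se':>10}",
        ]
        se = np.sqrt(np.diag(self.vcov.to_numpy()))
        for name, est, s in zip(self.params.index, self.params.to_numpy(), se):
            lines.append(f"  {name:<28} {est:>12.6g} {s:>10.4g}")
        lines.append("")
        lines.append(f"  residual variance: {self.scale:.6g}")
        lines.append("  random-effects covariance:")
        for i, rn in enumerate(self.re_names):
            row = " ".join(f"{v:>10.4g}" for v in self.cov_re[i])
            lines.append(f"    {rn:<12} {row}")
        return "\n".join(lines)

    def to_key_values(self) -> dict:
        out = {
            "method": self.method,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "period": self.spec.period,
            "residual_variance": float(self.scale),
        }
        se = np.sqrt(np.diag(self.vcov.to_numpy()))
        for name, est, s in zip(self.params.index, self.params.to_numpy(), se):
            out[f"coef.{name}"] = float(est)
            out[f"se.{name}"] = float(s)
        for i, a in enumerate(self.re_names):
            for j, b in enumerate(self.re_names):
                if j <= i:
                    out[f"cov_re.{a}.{b}"] = float(self.cov_re[i, j])
        return out


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = sorted(names[j] for j in piv[np.flatnonzero(diag <= tol)])
        extra = piv[X.shape[1]:] if len(piv) > X.shape[1] else []
        aliased += [names[j] for j in extra]
        raise RankDeficiencyError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )


def fit(
    dataset: CosinorDataset,
    spec: ModelSpec,
    *,
    reml: bool = True,
    maxiter: int = 500,
    start: MixedLMParams | None = None,
    zero_random_variance: bool = False,
) -> LinearFit:
    """Fit the mixed-effects cosinor model.

    REML is the default criterion; pass ``reml=False`` for ML (needed
    for likelihood-based model comparison).  The fit is deterministic
    given the data and settings.  Non-convergence is reported through
    ``converged=False`` with a warning rather than an exception, so the
    bootstrap layer can decide how to handle it.
    """
    design = build_design(dataset, spec)
    _check_rank(design.X, design.column_names)
    y = dataset.records["response"].to_numpy(dtype=float)

    model = MixedLM(y, design.X, groups=design.groups, exog_re=design.exog_re)
    free = None
    if zero_random_variance:
        # pin Sigma at a negligible value (exact zero is singular in the
        # optimizer); the fit then coincides with least squares
        q = design.exog_re.shape[1]
        free = MixedLMParams.from_components(
            fe_params=np.ones(design.X.shape[1]), cov_re=np.zeros((q, q))
        )
        start = MixedLMParams.from_components(
            fe_params=np.zeros(design.X.shape[1]), cov_re=1e-10 * np.eye(q)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = None
        err: Exception | None = None
        for method in ("lbfgs", "cg", "powell"):
            try:
                result = model.fit(
                    reml=reml, method=method, maxiter=maxiter,
                    start_params=start, free=free,
                )
                break
            except np.linalg.LinAlgError as e:  # singular step during optimization
                err = e
                start = None
                continue
        if result is None:
            raise RuntimeError(f"mixed-model fit failed: {err}") from err

    converged = bool(result.converged)
    if not converged:
        warnings.warn("mixed-model fit did not converge", stacklevel=2)

    k_fe = model.k_fe
    params = pd.Series(result.fe_params, index=design.column_names)
    vcov_arr = np.asarray(result.cov_params())[:k_fe, :k_fe]
    vcov = pd.DataFrame(vcov_arr, index=design.column_names, columns=design.column_names)
    cov_re = np.asarray(result.cov_re)
    eig = np.linalg.eigvalsh(cov_re) if cov_re.size else np.array([0.0])
    boundary = bool(eig.min() < 1e-8 * max(1.0, eig.max()))

    return LinearFit(
        params=params,
        vcov=vcov,
        cov_re=cov_re,
        re_names=design.re_names,
        scale=float(result.scale),
        converged=converged,
        boundary=boundary,
        n_obs=dataset.n_obs,
        n_subjects=dataset.n_subjects,
        spec=spec,
        design=design,
        dataset=dataset,
        method="reml" if reml else "ml",
    )
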