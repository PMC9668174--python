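"""Flexible main-effect models and phenotype residualization.

The null model for a quantitative trait is

    Y_i = mu(E_i, Z_i) + sum_j pi0_j X_ij + eps_i

with mu additive in smooth (spline) terms of each continuous exposure and
covariate, linear terms for binary columns, and a linear additive genetic
block with constant per-variant coefficients pi0_j.  Candidate interaction
scores can be appended as plain linear predictors; they receive a
coefficient, standard error and two-sided p-value, but never contribute to
the residualization prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .basis import BasisSpec, OLSFit, fit_smooth_basis, ols
from .data import Cohort

__all__ = ["MainEffectModel", "fit_main_effects", "predict_residuals"]


@dataclass
class MainEffectModel:
    """Fitted additive main-effect model mu(E,Z) + X'pi0."""

    env_basis: BasisSpec
    covar_basis: BasisSpec
    coef: np.ndarray                     # [intercept, env block, covar block, genotypes]
    m: int
    extras: list = field(default_factory=list)   # (beta, se, p) per extra predictor
    rank: int = 0
    sigma2: float = 0.0

    @property
    def genetic_coefs(self) -> np.ndarray:
        """pi0 estimates (length m)."""
        return self.coef[len(self.coef) - self.m:]

    def design(self, cohort: Cohort, rows: np.ndarray) -> np.ndarray:
        De = self.env_basis.transform(cohort.E[rows])          # includes intercept
        Dz = self.covar_basis.transform(cohort.Z[rows])[:, 1:]  # intercept dropped
        if De.shape[1] + Dz.shape[1] + cohort.m != len(self.coef):
            raise ValueError("cohort schema does not match fitted model")
        return np.hstack([De, Dz, cohort.X[rows]])

    def predict(self, cohort: Cohort, rows: np.ndarray) -> np.ndarray:
        return self.design(cohort, rows) @ self.coef

    def to_dict(self) -> dict:
        return {
            "env_basis": self.env_basis.to_dict(),
            "covar_basis": self.covar_basis.to_dict(),
            "coef": self.coef.tolist(),
            "m": self.m,
            "extras": [
                {"beta": b, "se": s, "p_value": p} for b, s, p in self.extras
            ],
            "rank": self.rank,
            "sigma2": self.sigma2,
        }


def fit_main_effects(
    cohort: Cohort,
    rows: np.ndarray | Sequence[int],
    extra_predictors: Sequence[np.ndarray] | None = None,
    n_basis: int = 5,
    force_linear: bool = False,
    min_obs_per_param: float = 5.0,
) -> MainEffectModel:
    """Fit the additive null model on `rows`, optionally with extra predictors.

    Parameters
    ----------
    extra_predictors
        Vectors aligned to `rows` (e.g. candidate interaction scores) entered
        as plain linear predictors.  Perfectly collinear extras are an error.
    n_basis
        B-spline basis size per continuous smooth; ``force_linear`` collapses
        every smooth to a linear term (then the fit is ordinary least squares).
    """
    rows = np.asarray(rows, dtype=int)
    extras = [np.asarray(u, dtype=float) for u in (extra_predictors or [])]
    for u in extras:
        if len(u) != len(rows):
            raise ValueError("extra predictor length does not match rows")

    env_basis = fit_smooth_basis(
        cohort.E[rows], cohort.env_names, n_basis=n_basis, force_linear=force_linear
    )
    covar_basis = fit_smooth_basis(
        cohort.Z[rows], cohort.covar_names, n_basis=n_basis, force_linear=force_linear
    )
    De = env_basis.transform(cohort.E[rows])
    Dz = covar_basis.transform(cohort.Z[rows])[:, 1:]
    D_main = np.hstack([De, Dz, cohort.X[rows]])
    q = D_main.shape[1] + len(extras)
    if len(rows) < min_obs_per_param * q:
        raise ValueError(
            f"{len(rows)} rows for {q} parameters violates the "
            f"{min_obs_per_param}x observations-per-parameter floor"
        )

    D = np.hstack([D_main] + [u[:, None] for u in extras]) if extras else D_main
    fit: OLSFit = ols(D, cohort.Y[rows], warn_label="fit_main_effects")
    extra_idx = list(range(D_main.shape[1], q))
    dropped_extras = [i for i in extra_idx if i not in fit.kept]
    if dropped_extras:
        raise ValueError("extra predictors are perfectly collinear with the design")

    return MainEffectModel(
        env_basis=env_basis,
        covar_basis=covar_basis,
        coef=fit.coef[: D_main.shape[1]],
        m=cohort.m,
        extras=[fit.coef_inference(i) for i in extra_idx],
        rank=fit.rank,
        sigma2=fit.sigma2,
    )


def predict_residuals(
    model: MainEffectModel, cohort: Cohort, rows: np.ndarray | Sequence[int]
) -> np.ndarray:
    """Residuals Y - mu_hat(E,Z) - X'pi0_hat on `rows` (extras excluded)."""
    rows = np.asarray(rows, dtype=int)
    return cohort.Y[rows] - model.predict(cohort, rows)
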