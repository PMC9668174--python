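"""Orthogonalization of interaction scores against main effects.

The robust statistic requires a transformation U' of the combined interaction
score U with zero covariance against both the environmental/covariate main
effects and the genetic main effects.  U' is estimated by alternating
conditional expectations (ACE) in its two-block backfitting form:

    (i)  given gamma, regress U - X'gamma on the smooth (E, Z) basis -> f
    (ii) given f,     regress U - f(E, Z) on X (least squares)      -> gamma

until the maximum coefficient change falls below ``tol``.  Each half-step is
an exact least-squares minimization, so the residual sum of squares is
non-increasing; with all smooth terms linear the procedure converges to the
joint least-squares projection of U on [E, Z, X].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from .basis import BasisSpec, fit_smooth_basis
from .data import Cohort, InteractionScoreSpec, evaluate_score
from .screening import CombinedScore

__all__ = ["OrthoModel", "fit_ortho", "predict_ortho"]


@dataclass
class OrthoModel:
    """Fitted transformation U' = U - f(E,Z) - X'gamma."""

    spec: InteractionScoreSpec
    degenerate: bool
    smooth_basis: BasisSpec | None = None
    smooth_coef: np.ndarray | None = None   # over smooth design columns (incl. intercept)
    gamma: np.ndarray | None = None         # length m, zeros at aliased columns
    iterations: int = 0
    final_change: float = np.inf
    converged: bool = True
    rss_path: list = field(default_factory=list)
    fitted_train: np.ndarray | None = None  # U' on the fitting rows

    def to_dict(self) -> dict:
        return {
            "degenerate": self.degenerate,
            "iterations": self.iterations,
            "final_change": self.final_change,
            "converged": self.converged,
            "gamma": None if self.gamma is None else self.gamma.tolist(),
            "smooth_coef": None if self.smooth_coef is None else self.smooth_coef.tolist(),
            "smooth_basis": None if self.smooth_basis is None else self.smooth_basis.to_dict(),
        }


def _kept_columns(M: np.ndarray) -> np.ndarray:
    """Indices of a maximal independent column subset (pivoted QR)."""
    if M.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = linalg.qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(M.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    return np.sort(piv[:rank])


def _solver(M: np.ndarray):
    Q, R = np.linalg.qr(M)
    return lambda v: linalg.solve_triangular(R, Q.T @ v)


def fit_ortho(
    cohort: Cohort,
    rows: np.ndarray | Sequence[int],
    score: CombinedScore | InteractionScoreSpec,
    tol: float = 1e-10,
    max_iter: int = 200,
    n_basis: int = 5,
    force_linear: bool = False,
) -> OrthoModel:
    """Estimate the orthogonalized transformation of the score on `rows`."""
    rows = np.asarray(rows, dtype=int)
    spec = score.spec if isinstance(score, CombinedScore) else score
    u = evaluate_score(spec, cohort, rows)
    if np.ptp(u) == 0:
        model = OrthoModel(spec=spec, degenerate=True)
        model.fitted_train = predict_ortho(model, cohort, rows)
        return model

    EZ = np.hstack([cohort.E[rows], cohort.Z[rows]])
    names = list(cohort.env_names) + list(cohort.covar_names)
    smooth_basis = fit_smooth_basis(EZ, names, n_basis=n_basis, force_linear=force_linear)
    Ds = smooth_basis.transform(EZ)
    ds_kept = _kept_columns(Ds)
    Dsk = Ds[:, ds_kept]
    X = cohort.X[rows]
    x_kept = _kept_columns(X)
    if len(x_kept) < cohort.m:
        warnings.warn("fit_ortho: dropped aliased genotype column(s)")
    Xk = X[:, x_kept]

    solve_s = _solver(Dsk)
    solve_x = _solver(Xk) if Xk.shape[1] else (lambda v: np.empty(0))

    # Both blocks are linear in their coefficients, so the alternation has a
    # closed-form fixed point (partial out the smooth block, then solve the
    # genetic block on the residualized problem).  Starting there makes the
    # loop a convergence check rather than a slow contraction.
    if Xk.shape[1]:
        Xt = Xk - Dsk @ solve_s(Xk)
        ut = u - Dsk @ solve_s(u)
        g = np.linalg.lstsq(Xt, ut, rcond=None)[0]
    else:
        g = np.zeros(0)
    a = solve_s(u - (Xk @ g if Xk.shape[1] else 0.0))
    rss_path = []
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        a_new = solve_s(u - Xk @ g)
        g_new = solve_x(u - Dsk @ a_new) if Xk.shape[1] else g
        change = max(
            float(np.max(np.abs(a_new - a), initial=0.0)),
            float(np.max(np.abs(g_new - g), initial=0.0)),
        )
        a, g = a_new, g_new
        r = u - Dsk @ a - (Xk @ g if Xk.shape[1] else 0.0)
        rss_path.append(float(r @ r))
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"fit_ortho: ACE did not converge in {max_iter} iterations "
            f"(last change {change:.3g}); returning current model"
        )

    smooth_coef = np.zeros(Ds.shape[1])
    smooth_coef[ds_kept] = a
    gamma = np.zeros(cohort.m)
    gamma[x_kept] = g
    model = OrthoModel(
        spec=spec,
        degenerate=False,
        smooth_basis=smooth_basis,
        smooth_coef=smooth_coef,
        gamma=gamma,
        iterations=it,
        final_change=change,
        converged=converged,
        rss_path=rss_path,
    )
    model.fitted_train = predict_ortho(model, cohort, rows)
    return model


def predict_ortho(
    model: OrthoModel, cohort: Cohort, rows: np.ndarray | Sequence[int]
) -> np.ndarray:
    """Evaluate U' = U - f(E,Z) - X'gamma on `rows` (out-of-sample safe)."""
    rows = np.asarray(rows, dtype=int)
    if model.degenerate:
        return np.zeros(len(rows))
    u = evaluate_score(model.spec, cohort, rows)
    EZ = np.hstack([cohort.E[rows], cohort.Z[rows]])
    if EZ.shape[1] != len(model.smooth_basis.columns):
        raise ValueError("cohort schema does not match fitted orthogonalization model")
    Ds = model.smooth_basis.transform(EZ)
    return u - Ds @ model.smooth_coef - cohort.X[rows] @ model.gamma
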