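"""Spline design matrices and least-squares helpers shared across modules.

Smooth terms are unpenalized cubic regression splines: for each continuous
column a B-spline basis (default 5 basis functions, i.e. one interior knot at
the training median with boundary knots at the training range) is built and
its first basis column dropped so the block is identifiable next to a global
intercept.  Binary columns (<= 2 distinct training values) enter linearly.
Out-of-range values at prediction time are clipped to the training range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.interpolate import BSpline

__all__ = ["ColumnBasis", "BasisSpec", "fit_smooth_basis", "OLSFit", "ols", "residualizer"]


@dataclass
class ColumnBasis:
    name: str
    kind: str                      # "spline" | "linear" | "drop"
    knots: np.ndarray | None = None
    degree: int = 3

    @property
    def n_columns(self) -> int:
        if self.kind == "linear":
            return 1
        if self.kind == "drop":
            return 0
        return len(self.knots) - self.degree - 2  # full basis minus dropped first

    def transform(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.kind == "linear":
            return v[:, None]
        if self.kind == "drop":
            return np.empty((len(v), 0))
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        vc = np.clip(v, lo, hi)
        dm = BSpline.design_matrix(vc, self.knots, self.degree).toarray()
        return dm[:, 1:]  # drop first basis fn (absorbed by intercept)


@dataclass
class BasisSpec:
    """Fitted basis description for a matrix of columns; includes an intercept."""

    columns: list[ColumnBasis]

    @property
    def n_columns(self) -> int:
        return 1 + sum(c.n_columns for c in self.columns)

    @property
    def column_names(self) -> list[str]:
        names = ["intercept"]
        for c in self.columns:
            if c.kind == "linear":
                names.append(c.name)
            else:
                names.extend(f"{c.name}:s{i}" for i in range(c.n_columns))
        return names

    def transform(self, M: np.ndarray) -> np.ndarray:
        M = np.atleast_2d(np.asarray(M, dtype=float))
        if M.shape[1] != len(self.columns):
            raise ValueError(
                f"schema mismatch: {M.shape[1]} columns, basis has {len(self.columns)}"
            )
        blocks = [np.ones((M.shape[0], 1))]
        for idx, c in enumerate(self.columns):
            blocks.append(c.transform(M[:, idx]))
        return np.hstack(blocks)

    def to_dict(self) -> dict:
        return {
            "columns": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "knots": None if c.knots is None else c.knots.tolist(),
                    "degree": c.degree,
                }
                for c in self.columns
            ]
        }


def _spline_basis(name: str, v: np.ndarray, n_basis: int, degree: int) -> ColumnBasis:
    lo, hi = float(np.min(v)), float(np.max(v))
    n_interior = n_basis - degree - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(v, qs)
    if lo == hi or np.any(interior <= lo) or np.any(interior >= hi):
        # degenerate spread: fall back to a linear term
        return ColumnBasis(name=name, kind="linear")
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return ColumnBasis(name=name, kind="spline", knots=knots, degree=degree)


def fit_smooth_basis(
    M: np.ndarray,
    names: list[str] | None = None,
    n_basis: int = 5,
    degree: int = 3,
    force_linear: bool = False,
) -> BasisSpec:
    """Choose per-column bases from training data.

    Continuous columns get a cubic regression spline with ``n_basis`` basis
    functions; binary columns (and all columns when ``force_linear``) get a
    linear term; constant columns are dropped.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if names is None:
        names = [f"x{j}" for j in range(M.shape[1])]
    cols = []
    for j, name in enumerate(names):
        v = M[:, j]
        nuniq = len(np.unique(v))
        if nuniq <= 1:
            cols.append(ColumnBasis(name=name, kind="drop"))
        elif force_linear or nuniq <= 2 or n_basis < degree + 2:
            cols.append(ColumnBasis(name=name, kind="linear"))
        else:
            cols.append(_spline_basis(name, v, n_basis, degree))
    return BasisSpec(columns=cols)


@dataclass
class OLSFit:
    """Least-squares fit with pivoted-QR handling of aliased columns."""

    coef: np.ndarray          # full length; zeros at dropped columns
    kept: np.ndarray          # indices of retained (non-aliased) columns
    rank: int
    resid: np.ndarray
    sigma2: float             # residual variance with df = n - rank
    df_resid: int
    _xtx_inv: np.ndarray      # (X_kept' X_kept)^{-1}

    def fitted(self, y: np.ndarray) -> np.ndarray:
        return y - self.resid

    def coef_inference(self, idx: int) -> tuple[float, float, float]:
        """(beta, se, two-sided p) for design column `idx` (t reference)."""
        pos = np.searchsorted(self.kept, idx)
        if pos >= len(self.kept) or self.kept[pos] != idx:
            return 0.0, np.inf, 1.0
        se = float(np.sqrt(self.sigma2 * self._xtx_inv[pos, pos]))
        beta = float(self.coef[idx])
        if se == 0 or not np.isfinite(se):
            return beta, se, 1.0
        t = beta / se
        p = 2 * stats.t.sf(abs(t), self.df_resid) if self.df_resid > 0 else 1.0
        return beta, se, float(p)


def ols(D: np.ndarray, y: np.ndarray, warn_label: str | None = None) -> OLSFit:
    """Least squares of y on D, dropping aliased columns via pivoted QR."""
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = D.shape
    Q, R, piv = linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, q) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < q and warn_label is not None:
        warnings.warn(f"{warn_label}: dropped {q - rank} aliased design column(s)")
    kept = np.sort(piv[:rank])
    Dk = D[:, kept]
    Qk, Rk = np.linalg.qr(Dk)
    beta_k = linalg.solve_triangular(Rk, Qk.T @ y)
    coef = np.zeros(q)
    coef[kept] = beta_k
    resid = y - Dk @ beta_k
    df = n - rank
    sigma2 = float(resid @ resid / df) if df > 0 else 0.0
    Rinv = linalg.solve_triangular(Rk, np.eye(rank))
    return OLSFit(
        coef=coef,
        kept=kept,
        rank=rank,
        resid=resid,
        sigma2=sigma2,
        df_resid=df,
        _xtx_inv=Rinv @ Rinv.T,
    )


def residualizer(D: np.ndarray):
    """Return a function projecting vectors/matrices off the column span of D."""
    Q, R, piv = linalg.qr(np.asarray(D, dtype=float), mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(D.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    Q = Q[:, :rank]

    def project_out(M: np.ndarray) -> np.ndarray:
        return M - Q @ (Q.T @ M)

    return project_out
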