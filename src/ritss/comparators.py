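"""Comparator tests used in the simulation studies.

* GAMsv — a single-variant scan with spline-modelled environmental main
  effects: for each variant the model has the variant and its interaction
  with ``E_t`` as plain covariates next to the smooth environmental part and
  linear covariates; the m interaction p-values are summarized by the
  Bonferroni-corrected minimum.
* D1/D2 — the non-robust counterparts of the cross-fitted tests: identical
  screening/combination/residualization pipeline, but the fold statistic
  uses the raw combined score U instead of the orthogonalized U'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import fit_smooth_basis, residualizer
from .data import Cohort
from .inference import RitssResult, run_pipeline
from .splitting import SplitConfig

__all__ = ["ComparatorResult", "gamsv_test", "nonrobust_test"]


@dataclass
class ComparatorResult:
    method: str
    p_value: float
    variant_p_values: np.ndarray | None = None
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "p_value": self.p_value,
            "variant_p_values": None
            if self.variant_p_values is None
            else self.variant_p_values.tolist(),
        }


def gamsv_test(cohort: Cohort, t: int, n_basis: int = 5) -> ComparatorResult:
    """Minimum Bonferroni-corrected single-variant interaction p-value.

    Environmental main effects are modelled with the same unpenalized spline
    bases as the cross-fitted tests; covariates enter linearly.
    """
    if cohort.m < 1:
        raise ValueError("need at least one genetic variant")
    env_basis = fit_smooth_basis(cohort.E, cohort.env_names, n_basis=n_basis)
    base = np.hstack([env_basis.transform(cohort.E), cohort.Z])
    proj = residualizer(base)
    rank_base = np.linalg.matrix_rank(base)
    y_res = proj(cohort.Y)
    yy = float(y_res @ y_res)
    et = cohort.E[:, t]
    df = cohort.n - rank_base - 2

    p_values = np.ones(cohort.m)
    for j in range(cohort.m):
        extra = np.column_stack([cohort.X[:, j], cohort.X[:, j] * et])
        Ex = proj(extra)
        G = Ex.T @ Ex
        if df <= 0 or np.linalg.matrix_rank(G) < 2:
            continue  # fit failure: keep p_j = 1
        rhs = Ex.T @ y_res
        b = np.linalg.solve(G, rhs)
        rss = max(yy - float(b @ rhs), 0.0)
        sigma2 = rss / df
        se = np.sqrt(max(sigma2 * np.linalg.inv(G)[1, 1], 0.0))
        if se > 0:
            p_values[j] = 2 * stats.t.sf(abs(b[1] / se), df)

    summary = float(min(1.0, cohort.m * p_values.min()))
    return ComparatorResult(method="GAMsv", p_value=summary, variant_p_values=p_values)


def nonrobust_test(
    cohort: Cohort,
    t: int,
    strategy: int = 1,
    split_config: SplitConfig | None = None,
    n_basis: int = 5,
    screen_kwargs: dict | None = None,
) -> ComparatorResult:
    """D1/D2: the cross-fitted test with the orthogonalization step skipped."""
    _, raw = run_pipeline(
        cohort, t, strategy=strategy, split_config=split_config,
        n_basis=n_basis, screen_kwargs=screen_kwargs,
    )
    return ComparatorResult(
        method=raw.method,
        p_value=raw.p_value,
        detail={"z": raw.z, "T": raw.T, "sigma2_T": raw.sigma2_T},
    )


def nonrobust_result(
    cohort: Cohort,
    t: int,
    strategy: int = 1,
    split_config: SplitConfig | None = None,
    **kwargs,
) -> RitssResult:
    """Full fold-level result object for the non-robust variant."""
    _, raw = run_pipeline(cohort, t, strategy=strategy, split_config=split_config, **kwargs)
    return raw
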