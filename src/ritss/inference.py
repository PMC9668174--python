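"""Fold statistics, the overall z-score, fine-mapping overlaps and validation.

Per test fold k the statistic is ``T_k = sum_{i in I_k} U'_i * Yresid_i`` with
empirical variance ``sigma2_k = sum (U'_i Yresid_i)^2``; folds combine as
``T = sum T_k``, ``sigma2_T = sum sigma2_k`` and ``z = T / sqrt(sigma2_T)``,
which is asymptotically standard normal under the null of no interaction.
The per-fold variant sets m(I_k) yield the fine-mapping overlaps m4 (variants
in all K sets) and m3 (in exactly K-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import Cohort, evaluate_score
from .main_effects import predict_residuals
from .orthogonalize import fit_ortho, predict_ortho
from .screening import combine_scores, screen_strategy1, screen_strategy2
from .splitting import FoldPlan, SplitConfig, make_fold_plan

__all__ = [
    "FoldResult",
    "RitssResult",
    "fold_statistic",
    "combine_folds",
    "overlap_sets",
    "validation_test",
    "run_ritss",
    "run_pipeline",
]


@dataclass
class FoldResult:
    k: int
    T_k: float
    sigma2_k: float
    variant_set: list[int]
    n_k: int
    gate_c2: int = 0
    degenerate: bool = False
    ortho_iterations: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_k < 0:
            raise ValueError("sigma2_k must be non-negative")


@dataclass
class RitssResult:
    z: float
    p_value: float
    T: float
    sigma2_T: float
    fold_results: list
    m4: list[int] = field(default_factory=list)
    m3: list[int] = field(default_factory=list)
    degenerate: bool = False
    method: str = "RITSS"

    def to_dict(self, variant_ids: list[str] | None = None) -> dict:
        def ids(js):
            return [variant_ids[j] if variant_ids else j for j in js]

        return {
            "method": self.method,
            "z": self.z,
            "p_value": self.p_value,
            "T": self.T,
            "sigma2_T": self.sigma2_T,
            "degenerate": self.degenerate,
            "m4": ids(self.m4),
            "m3": ids(self.m3),
            "folds": [
                {
                    "k": f.k,
                    "T_k": f.T_k,
                    "sigma2_k": f.sigma2_k,
                    "n_k": f.n_k,
                    "gate_c2": f.gate_c2,
                    "degenerate": f.degenerate,
                    "variant_set": ids(f.variant_set),
                }
                for f in self.fold_results
            ],
        }

    def write_json(self, path: str | Path, variant_ids: list[str] | None = None) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(variant_ids), indent=2, sort_keys=True)
        )

    def membership_table(self, variant_ids: list[str] | None = None) -> pd.DataFrame:
        """Per-variant fold membership (mirrors a fine-mapping appendix layout)."""
        all_js = sorted({j for f in self.fold_results for j in f.variant_set})
        rows = []
        for j in all_js:
            member = [int(j in f.variant_set) for f in self.fold_results]
            rows.append(
                {
                    "variant": variant_ids[j] if variant_ids else j,
                    **{f"fold_{f.k}": mk for f, mk in zip(self.fold_results, member)},
                    "n_folds": sum(member),
                }
            )
        return pd.DataFrame(rows)


def fold_statistic(u_prime: np.ndarray, y_resid: np.ndarray) -> tuple[float, float]:
    """T_k = sum u'_i r_i and sigma2_k = sum (u'_i r_i)^2."""
    u_prime = np.asarray(u_prime, dtype=float)
    y_resid = np.asarray(y_resid, dtype=float)
    if u_prime.shape != y_resid.shape:
        raise ValueError("u_prime and y_resid must have equal length")
    prod = u_prime * y_resid
    return float(prod.sum()), float(prod @ prod)


def combine_folds(fold_results: Sequence[FoldResult], method: str = "RITSS") -> RitssResult:
    """Aggregate fold statistics into the overall z-score and p-value."""
    if not fold_results:
        raise ValueError("need at least one fold result")
    T = float(sum(f.T_k for f in fold_results))
    s2 = float(sum(f.sigma2_k for f in fold_results))
    if s2 > 0:
        z = T / np.sqrt(s2)
        p = float(2 * stats.norm.sf(abs(z)))
        degenerate = False
    else:
        z, p, degenerate = 0.0, 1.0, True
    m4, m3 = overlap_sets([f.variant_set for f in fold_results])
    return RitssResult(
        z=float(z),
        p_value=p,
        T=T,
        sigma2_T=s2,
        fold_results=list(fold_results),
        m4=m4,
        m3=m3,
        degenerate=degenerate,
        method=method,
    )


def overlap_sets(variant_sets: Sequence[Sequence]) -> tuple[list, list]:
    """m4 = variants in all K sets; m3 = variants in exactly K-1 sets."""
    K = len(variant_sets)
    counts: dict = {}
    for s in variant_sets:
        for v in set(s):
            counts[v] = counts.get(v, 0) + 1
    m4 = sorted(v for v, c in counts.items() if c == K)
    m3 = sorted(v for v, c in counts.items() if c == K - 1)
    return m4, m3


def validation_test(
    cohort: Cohort,
    variant_set: Sequence[int],
    weights: np.ndarray | Sequence[float],
    t: int,
) -> tuple[float, float, float]:
    """Standard interaction regression in an independent sample.

    Builds the weighted genetic score ``G_i = sum_{j in set} w_j X_ij`` and
    fits ``Y ~ 1 + X + E + Z + G*E_t``; the main effect of G is absorbed by
    the X block.  Returns the interaction coefficient with its model-based
    and HC0-sandwich p-values.
    """
    variant_set = sorted(int(j) for j in variant_set)
    if not variant_set:
        raise ValueError("variant_set must be non-empty")
    weights = np.asarray(weights, dtype=float)
    if weights.shape == (cohort.m,):
        w = weights[variant_set]
    elif weights.shape == (len(variant_set),):
        w = weights
    else:
        raise ValueError("weights must have length m or len(variant_set)")
    G = cohort.X[:, variant_set] @ w
    D = np.column_stack(
        [np.ones(cohort.n), cohort.X, cohort.E, cohort.Z, G * cohort.E[:, t]]
    )
    fit = sm.OLS(cohort.Y, D).fit()
    beta = float(fit.params[-1])
    p_model = float(fit.pvalues[-1])
    p_sandwich = float(fit.get_robustcov_results(cov_type="HC0").pvalues[-1])
    return beta, p_model, p_sandwich


def run_pipeline(
    cohort: Cohort,
    t: int,
    strategy: int = 1,
    split_config: SplitConfig | None = None,
    n_basis: int = 5,
    screen_kwargs: dict | None = None,
    fold_plan: FoldPlan | None = None,
) -> tuple[RitssResult, RitssResult]:
    """Full cross-fitted pipeline; returns (robust, non-robust) results.

    The non-robust variant shares every stage except that the test statistic
    uses the raw score U on I_k instead of the orthogonalized U' (the third
    complement part is simply unused by it).
    """
    if strategy not in (1, 2):
        raise ValueError("strategy must be 1 or 2")
    split_config = split_config or SplitConfig()
    plan = fold_plan or make_fold_plan(cohort.n, split_config)
    screen_kwargs = dict(screen_kwargs or {})
    seed_seq = np.random.SeedSequence(split_config.seed)
    fold_seeds = [int(c.generate_state(1)[0] % 2**31) for c in seed_seq.spawn(len(plan.folds))]

    robust_folds = []
    raw_folds = []
    for fold, fseed in zip(plan.folds, fold_seeds):
        if strategy == 1:
            screen = screen_strategy1(
                cohort, fold.c1, t, seed=fseed, **screen_kwargs
            )
        else:
            screen = screen_strategy2(cohort, fold.c1, t, **screen_kwargs)
        combined = combine_scores(cohort, fold.c2, screen, n_basis=n_basis)
        y_resid = predict_residuals(combined.model, cohort, fold.test)
        ortho = fit_ortho(cohort, fold.c3, combined, n_basis=n_basis)
        u_prime = predict_ortho(ortho, cohort, fold.test)
        T_k, s2_k = fold_statistic(u_prime, y_resid)
        robust_folds.append(
            FoldResult(
                k=fold.k,
                T_k=T_k,
                sigma2_k=s2_k,
                variant_set=combined.variant_set,
                n_k=len(fold.test),
                gate_c2=combined.gate_c2,
                degenerate=ortho.degenerate,
                ortho_iterations=ortho.iterations,
            )
        )
        u_raw = evaluate_score(combined.spec, cohort, fold.test)
        T_d, s2_d = fold_statistic(u_raw, y_resid)
        raw_folds.append(
            FoldResult(
                k=fold.k,
                T_k=T_d,
                sigma2_k=s2_d,
                variant_set=combined.variant_set,
                n_k=len(fold.test),
                gate_c2=combined.gate_c2,
                degenerate=np.ptp(u_raw) == 0,
            )
        )

    label = f"RITSS{strategy}"
    robust = combine_folds(robust_folds, method=label)
    raw = combine_folds(raw_folds, method=f"D{strategy}")
    return robust, raw


def run_ritss(
    cohort: Cohort,
    t: int,
    strategy: int = 1,
    split_config: SplitConfig | None = None,
    n_basis: int = 5,
    screen_kwargs: dict | None = None,
) -> RitssResult:
    """Run the full robust interaction test (screen, combine, orthogonalize, test)."""
    robust, _ = run_pipeline(
        cohort, t, strategy=strategy, split_config=split_config,
        n_basis=n_basis, screen_kwargs=screen_kwargs,
    )
    return robust
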