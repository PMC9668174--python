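"""Interaction-signal screening and score combination.

Two screening strategies, both targeting a single exposure ``E_t``:

* Strategy 1 screens for a *risk-score subcomponent* interacting with E_t.
  Genetic main-effect weights pi0_hat come from an all-linear fit; approximate
  best-subset selection over subset sizes (step 5 grid starting at 10, with
  the full size appended) is run on a 2-sample split, ranking variants in one
  half and scoring candidate subsets by the interaction z^2 in the other.
  J1 = variants picked by both halves, J2 = variants picked exactly once.

* Strategy 2 runs per-variant interaction scans
  ``Y ~ 1 + E + Z + X_j + E_t X_j`` and groups variants into two scores by
  Benjamini-Hochberg q-value bands (q <= q1; q1 < q <= q2), weighted by the
  estimated per-variant interaction coefficients.

``combine_scores`` fits both candidate scores as linear predictors next to
flexible main effects on a disjoint subsample; the second score is kept only
if its coefficient p-value is below 0.05.  The fitted main-effect model is
retained for residualizing the test fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .basis import ols, residualizer
from .data import Cohort, InteractionScoreSpec, evaluate_score
from .main_effects import MainEffectModel, fit_main_effects

__all__ = ["ScreenOutput", "CombinedScore", "screen_strategy1", "screen_strategy2", "combine_scores"]

logger = logging.getLogger(__name__)

GATE_ALPHA = 0.05  # p-value threshold for including the second score


@dataclass
class ScreenOutput:
    candidate_scores: list[InteractionScoreSpec]
    env_index: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self, variant_ids: list[str] | None = None) -> dict:
        def terms(spec):
            return [
                {
                    "variant": variant_ids[j] if variant_ids else j,
                    "env": l,
                    "weight": w,
                }
                for j, l, w in spec.terms
            ]

        return {
            "env_index": self.env_index,
            "candidates": [
                {"label": s.label, "terms": terms(s)} for s in self.candidate_scores
            ],
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


@dataclass
class CombinedScore:
    spec: InteractionScoreSpec
    gate_c2: int
    gate_p_value: float | None
    variant_set: list[int]
    model: MainEffectModel

    def to_dict(self, variant_ids: list[str] | None = None) -> dict:
        return {
            "gate_c2": self.gate_c2,
            "gate_p_value": self.gate_p_value,
            "variant_set": [
                variant_ids[j] if variant_ids else j for j in self.variant_set
            ],
            "n_terms": len(self.spec.terms),
        }


def _linear_design(cohort: Cohort, rows: np.ndarray) -> np.ndarray:
    return np.hstack(
        [np.ones((len(rows), 1)), cohort.E[rows], cohort.Z[rows], cohort.X[rows]]
    )


def _grid_sizes(grid_start: int, grid_step: int, m_avail: int) -> list[int]:
    if m_avail <= grid_start:
        return [m_avail]
    sizes = list(range(grid_start, m_avail, grid_step))
    sizes.append(m_avail)
    return sizes


def screen_strategy1(
    cohort: Cohort,
    rows: np.ndarray | Sequence[int],
    t: int,
    grid_start: int = 10,
    grid_step: int = 5,
    seed: int = 0,
    filter_quantile: float | None = None,
) -> ScreenOutput:
    """Risk-score-subcomponent screening on the first complement part."""
    rows = np.asarray(rows, dtype=int)
    y = cohort.Y[rows]
    D = _linear_design(cohort, rows)
    fit0 = ols(D, y, warn_label="screen_strategy1 base fit")
    pi0 = fit0.coef[1 + cohort.d + cohort.p:]

    avail = np.arange(cohort.m)
    if filter_quantile is not None and 0 < filter_quantile < 1:
        thresh = np.quantile(np.abs(pi0), filter_quantile)
        avail = avail[np.abs(pi0[avail]) >= thresh]

    # weighted single-variant interaction columns, evaluated on the local rows
    W = pi0[None, :] * cohort.X[rows] * cohort.E[rows, t][:, None]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(rows))
    half = len(rows) // 2
    halves = [perm[:half], perm[half:]]

    proj = [residualizer(D[h]) for h in halves]
    y_res = [proj[i](y[h]) for i, h in enumerate(halves)]
    base_rank = [np.linalg.matrix_rank(D[h]) for h in halves]

    def ranking(i: int) -> np.ndarray:
        h = halves[i]
        Wt = proj[i](W[np.ix_(h, avail)])
        norms = np.sqrt(np.sum(Wt**2, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.abs(Wt.T @ y_res[i]) / np.where(norms > 0, norms, np.inf)
        return avail[np.argsort(-stat, kind="stable")]

    def subset_z2(i_other: int, subset: np.ndarray) -> float:
        h = halves[i_other]
        u = W[np.ix_(h, subset)].sum(axis=1)
        ut = proj[i_other](u)
        uu = float(ut @ ut)
        if uu <= 1e-12:
            return 0.0
        uy = float(ut @ y_res[i_other])
        beta = uy / uu
        rss = float(y_res[i_other] @ y_res[i_other]) - beta * uy
        df = len(h) - base_rank[i_other] - 1
        if df <= 0 or rss <= 0:
            return 0.0
        return beta**2 * uu / (rss / df)

    sizes = _grid_sizes(grid_start, grid_step, len(avail))
    best_subsets = []
    chosen_sizes = []
    for i in (0, 1):
        ranked = ranking(i)
        other = 1 - i
        crits = [subset_z2(other, ranked[:s]) for s in sizes]
        s_best = sizes[int(np.argmax(crits))]
        best_subsets.append(set(int(j) for j in ranked[:s_best]))
        chosen_sizes.append(s_best)

    j1 = sorted(best_subsets[0] & best_subsets[1])
    j2 = sorted(best_subsets[0] ^ best_subsets[1])
    if not j1:
        logger.info("screen_strategy1: empty intersection J1; U1 is the zero score")

    specs = [
        InteractionScoreSpec(
            terms=[(j, t, float(pi0[j])) for j in js], label=label
        )
        for js, label in ((j1, "U1"), (j2, "U2"))
    ]
    return ScreenOutput(
        candidate_scores=specs,
        env_index=t,
        diagnostics={
            "sizes_tried": sizes,
            "chosen_sizes": chosen_sizes,
            "n_available": len(avail),
        },
    )


def screen_strategy2(
    cohort: Cohort,
    rows: np.ndarray | Sequence[int],
    t: int,
    q1: float = 0.05,
    q2: float = 0.2,
) -> ScreenOutput:
    """Per-variant interaction scan grouped by FDR q-value bands.

    Score 1 collects the confidently significant variants (q <= q1); score 2
    the remaining suggestive ones (q1 < q <= q2).  When the confident band is
    empty but some variant shows evidence (q < 1), score 1 falls back to the
    single best-ranked variant: the fold statistic then stays non-degenerate,
    at no cost to validity because the weight is estimated on screening data
    disjoint from the test fold.
    """
    rows = np.asarray(rows, dtype=int)
    y = cohort.Y[rows]
    base = np.hstack([np.ones((len(rows), 1)), cohort.E[rows], cohort.Z[rows]])
    proj = residualizer(base)
    rank_base = np.linalg.matrix_rank(base)
    y_res = proj(y)
    yy = float(y_res @ y_res)
    et = cohort.E[rows, t]

    p_values = np.ones(cohort.m)
    weights = np.zeros(cohort.m)
    df = len(rows) - rank_base - 2
    for j in range(cohort.m):
        extra = np.column_stack([cohort.X[rows, j], cohort.X[rows, j] * et])
        Ex = proj(extra)
        G = Ex.T @ Ex
        if np.linalg.matrix_rank(G) < 2 or df <= 0:
            continue
        rhs = Ex.T @ y_res
        b = np.linalg.solve(G, rhs)
        rss = yy - float(b @ rhs)
        sigma2 = max(rss, 0.0) / df
        Ginv = np.linalg.inv(G)
        se = np.sqrt(max(sigma2 * Ginv[1, 1], 0.0))
        weights[j] = b[1]
        if se > 0:
            p_values[j] = 2 * stats.t.sf(abs(b[1] / se), df)

    qvals = multipletests(p_values, method="fdr_bh")[1]
    j1 = [int(j) for j in np.where(qvals <= q1)[0]]
    if not j1 and qvals.min() < 1:
        j1 = [int(np.argmin(p_values))]  # best-candidate fallback
    j2 = [int(j) for j in np.where((qvals > q1) & (qvals <= q2))[0] if int(j) not in j1]

    specs = [
        InteractionScoreSpec(
            terms=[(j, t, float(weights[j])) for j in js], label=label
        )
        for js, label in ((j1, "U1"), (j2, "U2"))
    ]
    return ScreenOutput(
        candidate_scores=specs,
        env_index=t,
        diagnostics={"q_values": qvals, "p_values": p_values},
    )


def combine_scores(
    cohort: Cohort,
    rows: np.ndarray | Sequence[int],
    screen_out: ScreenOutput,
    n_basis: int = 5,
    force_linear: bool = False,
) -> CombinedScore:
    """Gate and merge the candidate scores on the second complement part.

    Both candidates enter a flexible main-effect fit as linear predictors;
    U1 is always retained, U2 only if its coefficient p-value is below 0.05.
    The fitted main-effect model is kept for residualizing the test fold.
    """
    rows = np.asarray(rows, dtype=int)
    cands = screen_out.candidate_scores
    if len(cands) > 2:
        raise ValueError("combine_scores expects at most two candidate scores")
    spec1 = cands[0] if cands else InteractionScoreSpec(label="U1")
    spec2 = cands[1] if len(cands) > 1 else InteractionScoreSpec(label="U2")

    extras = []
    included = []  # which candidate index each extra belongs to
    for idx, spec in enumerate((spec1, spec2)):
        if spec.terms:
            u = evaluate_score(spec, cohort, rows)
            if np.ptp(u) > 0:
                extras.append(u)
                included.append(idx)

    gating_model = fit_main_effects(
        cohort, rows, extra_predictors=extras, n_basis=n_basis, force_linear=force_linear
    )
    # Residualization uses a pure null-model fit: keeping the jointly fitted
    # score coefficients out of the design (not merely out of the prediction)
    # avoids retaining fold-common score-direction noise in Yresid, which the
    # per-sample empirical variance of the fold statistic cannot account for.
    model = fit_main_effects(
        cohort, rows, n_basis=n_basis, force_linear=force_linear
    )

    p2 = None
    if 1 in included:
        p2 = gating_model.extras[included.index(1)][2]
    c2 = 1 if (p2 is not None and p2 < GATE_ALPHA) else 0

    terms = list(spec1.terms) + (list(spec2.terms) if c2 else [])
    combined = InteractionScoreSpec(terms=terms, label="combined")
    variants = {j for j, _, _ in spec1.terms}
    if c2:
        variants |= {j for j, _, _ in spec2.terms}
    return CombinedScore(
        spec=combined,
        gate_c2=c2,
        gate_p_value=p2,
        variant_set=sorted(variants),
        model=model,
    )
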