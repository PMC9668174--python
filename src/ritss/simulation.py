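"""Synthetic cohort generators and replicate study harness.

Null phenotypes follow ``Y = mu(E, Z) + X'pi0 + eps(E, Z)`` with
``E[eps | X, E, Z] = 0``.  Five null scenarios stress the test in distinct
ways (the screening stages always assume linear environmental main effects):

1. no misspecification, normal homoscedastic errors;
2. a nonlinear main effect of the first exposure (quadratic plus sine);
3. scenario 2 plus heteroscedastic non-normal errors
   ``(1 + |E1|/2) * centered-scaled chi^2_4``;
4. scenario 2 plus gene-environment correlation (a standardized burden of a
   designated 10% of variants is mixed into E1);
5. scenario 3 plus that gene-environment correlation.

With ``select=True`` a larger pool of ``m_pool`` variants is simulated and
the m variants with the smallest marginal association p-values *in the same
cohort* enter the analysis, emulating GWAS-based variant selection.

Power cohorts start from scenario 1 and add interaction effects with the
first exposure: each variant interacts independently with probability
``p_XE`` and effect ``delta_j = pi0_j * beta_j``, ``beta_j ~ N(mu_XE,
sigma_XE^2)`` — a risk-score-subcomponent architecture, since interaction
effects are proportional to main-effect weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import gamsv_test
from .data import Cohort
from .inference import run_pipeline
from .splitting import SplitConfig

__all__ = [
    "ScenarioConfig",
    "PowerConfig",
    "simulate_null",
    "simulate_power",
    "desk_scale",
    "make_test_fns",
    "run_study",
    "StudyResult",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Null-scenario generator settings (defaults follow the full-scale study)."""

    scenario: int = 1
    select: bool = False
    n: int = 30_000
    m: int = 100
    m_pool: int | None = None          # pool size for select=True (>= m)
    d: int = 5
    p: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    env_correlation: float = 0.3       # exchangeable correlation of E
    n_env_binary: int = 0              # trailing E columns dichotomized at 0
    pi0_sd: float = 0.1                # genetic main-effect scale, pi0 ~ N(0, sd^2)
    env_effect_sd: float = 0.5
    covar_effect_sd: float = 0.5
    nonlin_quad: float = 0.6           # scenario >= 2: coefficient of (E1^2 - 1)
    nonlin_sine_amp: float = 0.8       # scenario >= 2: amplitude of sin(E1)
    nonlin_sine_freq: float = 1.0
    hetero_scale: float = 0.5          # scenarios 3, 5: sd factor 1 + scale*|E1|
    ge_weight: float = 0.35            # scenarios 4, 5: burden weight mixed into E1
    ge_fraction: float = 0.10          # fraction of variants in the burden
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4, 5):
            raise ValueError("scenario must be in 1..5")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"invalid maf_range {self.maf_range}")
        if self.select:
            if self.m_pool is None or self.m_pool < self.m:
                raise ValueError("select=True requires m_pool >= m")


@dataclass(frozen=True)
class PowerConfig:
    """Interaction-effect settings layered on a scenario-1 null cohort."""

    mu_XE: float = 0.05
    sigma_XE: float = 0.01
    p_XE: float = 0.2
    alpha: float = 0.005
    weighted: bool = True   # delta_j = pi0_j * beta_j; False: delta_j = beta_j

    def __post_init__(self) -> None:
        if not (0 <= self.p_XE <= 1):
            raise ValueError("p_XE must lie in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def desk_scale(**overrides) -> ScenarioConfig:
    """Desk-scale preset: n=3000, m=50 (select pool 100), d=5, p=2."""
    base = dict(n=3000, m=50, d=5, p=2)
    base.update(overrides)
    if base.get("select") and "m_pool" not in base:
        base["m_pool"] = 2 * base["m"]
    return ScenarioConfig(**base)


def _generate(config: ScenarioConfig) -> tuple[Cohort, dict]:
    rng = np.random.default_rng(config.seed)
    n, d, p = config.n, config.d, config.p
    m_total = config.m_pool if config.select else config.m
    if m_total is None:
        m_total = config.m

    maf = rng.uniform(*config.maf_range, size=m_total)
    X = rng.binomial(2, maf, size=(n, m_total)).astype(float)
    n_ge = max(1, int(round(config.ge_fraction * m_total)))
    designated = np.sort(rng.choice(m_total, size=n_ge, replace=False))

    # exchangeable-correlation Gaussian exposures
    rho = config.env_correlation
    shared = rng.standard_normal((n, 1))
    E = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, d))
    if config.scenario in (4, 5):
        burden = (X[:, designated] - 2 * maf[designated]).sum(axis=1)
        sd = np.sqrt(np.sum(2 * maf[designated] * (1 - maf[designated])))
        g = config.ge_weight
        E[:, 0] = (E[:, 0] + g * burden / sd) / np.sqrt(1 + g**2)
    if config.n_env_binary:
        E[:, d - config.n_env_binary:] = (E[:, d - config.n_env_binary:] > 0).astype(float)
    Z = rng.standard_normal((n, p))

    mu1 = rng.normal(0, config.env_effect_sd, size=d)
    mu2 = rng.normal(0, config.covar_effect_sd, size=p)
    pi0 = rng.normal(0, config.pi0_sd, size=m_total)

    mu = E @ mu1 + Z @ mu2
    if config.scenario >= 2:
        e1 = E[:, 0]
        mu = mu + config.nonlin_quad * (e1**2 - 1.0)
        mu = mu + config.nonlin_sine_amp * np.sin(config.nonlin_sine_freq * e1)

    if config.scenario in (3, 5):
        chi = (rng.chisquare(4, size=n) - 4.0) / np.sqrt(8.0)
        eps = (1.0 + config.hetero_scale * np.abs(E[:, 0])) * chi
    else:
        eps = rng.standard_normal(n)

    Y = mu + X @ pi0 + eps

    kept = np.arange(m_total)
    if config.select:
        # marginal association of each pool variant with Y in this same cohort
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean()
        denom = np.sqrt(np.sum(Xc**2, axis=0) * float(Yc @ Yc))
        r = np.where(denom > 0, (Xc.T @ Yc) / np.where(denom > 0, denom, 1.0), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
        pvals = 2 * stats.t.sf(np.abs(tstat), n - 2)
        kept = np.sort(np.argsort(pvals, kind="stable")[: config.m])

    width = len(str(n))
    cohort = Cohort(
        sample_ids=[f"S{i:0{width}d}" for i in range(n)],
        Y=Y,
        X=X[:, kept],
        E=E,
        Z=Z,
        variant_ids=[f"rs{j + 1}" for j in kept],
        env_names=[f"E{l + 1}" for l in range(d)],
        covar_names=[f"Z{c + 1}" for c in range(p)],
    )
    truth = {
        "maf": maf,
        "pi0_pool": pi0,
        "pi0": pi0[kept],
        "kept": kept,
        "designated": designated,
        "mu1": mu1,
        "mu2": mu2,
        "mu": mu,
        "eps": eps,
    }
    return cohort, truth


def simulate_null(config: ScenarioConfig, return_truth: bool = False):
    """Generate a null cohort for the configured scenario."""
    cohort, truth = _generate(config)
    return (cohort, truth) if return_truth else cohort


def simulate_power(
    power: PowerConfig,
    base: ScenarioConfig | None = None,
    return_truth: bool = False,
):
    """Generate a cohort with planted score-subcomponent interactions.

    The base cohort is scenario 1 without variant selection; interaction
    effects act through the first exposure only.
    """
    base = base or ScenarioConfig()
    base = replace(base, scenario=1, select=False, m_pool=None)
    cohort, truth = _generate(base)
    # separate stream: the base cohort is untouched when no variant interacts
    rng = np.random.default_rng(np.random.SeedSequence(base.seed).spawn(1)[0])
    mask = rng.binomial(1, power.p_XE, size=cohort.m).astype(float)
    beta = rng.normal(power.mu_XE, power.sigma_XE, size=cohort.m)
    delta = (truth["pi0"] * beta if power.weighted else beta) * mask
    if mask.any():
        cohort.Y = cohort.Y + (cohort.X @ delta) * cohort.E[:, 0]
    truth = dict(truth, interacting=np.where(mask > 0)[0], delta=delta)
    return (cohort, truth) if return_truth else cohort


# ---------------------------------------------------------------------------
# replicate studies


def make_test_fns(
    methods: Sequence[str],
    t: int = 0,
    K: int = 4,
    c=None,
    n_basis: int = 5,
    screen_kwargs: dict | None = None,
) -> dict[str, Callable]:
    """Build named test callables ``f(cohort, seed) -> {name: p_value}``.

    Recognized methods: ritss1, ritss2, d1, d2, gamsv.  A robust test and its
    non-robust twin (e.g. ritss1 + d1) share one pipeline run.
    """
    methods = [m.lower() for m in methods]
    known = {"ritss1", "ritss2", "d1", "d2", "gamsv"}
    unknown = set(methods) - known
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    from .splitting import DEFAULT_FRACTIONS

    c = c or DEFAULT_FRACTIONS
    fns: dict[str, Callable] = {}

    for s in (1, 2):
        wanted = [name for name in (f"ritss{s}", f"d{s}") if name in methods]
        if not wanted:
            continue

        def fn(cohort, seed, _s=s, _wanted=tuple(wanted)):
            cfg = SplitConfig(K=K, c=tuple(c), seed=seed)
            robust, raw = run_pipeline(
                cohort, t, strategy=_s, split_config=cfg,
                n_basis=n_basis, screen_kwargs=screen_kwargs,
            )
            out = {}
            if f"ritss{_s}" in _wanted:
                out[f"ritss{_s}"] = robust.p_value
            if f"d{_s}" in _wanted:
                out[f"d{_s}"] = raw.p_value
            return out

        fns[f"pipeline{s}"] = fn

    if "gamsv" in methods:
        fns["gamsv"] = lambda cohort, seed: {
            "gamsv": gamsv_test(cohort, t, n_basis=n_basis).p_value
        }
    return fns


@dataclass
class StudyResult:
    """Replicate p-values plus calibration/power summaries."""

    p_values: pd.DataFrame        # one row per replicate, one column per method
    alphas: tuple = (0.05,)
    meta: dict = field(default_factory=dict)

    def rejection_summary(self, alphas: Sequence[float] | None = None) -> pd.DataFrame:
        """Empirical rejection rates with exact (Clopper-Pearson) 95% CIs."""
        alphas = tuple(alphas or self.alphas)
        rows = []
        for method in self.p_values.columns:
            p = self.p_values[method].dropna().to_numpy()
            nrep = len(p)
            for a in alphas:
                k = int((p < a).sum())
                lo = stats.beta.ppf(0.025, k, nrep - k + 1) if k > 0 else 0.0
                hi = stats.beta.ppf(0.975, k + 1, nrep - k) if k < nrep else 1.0
                rows.append(
                    {
                        "method": method,
                        "alpha": a,
                        "n_reps": nrep,
                        "n_reject": k,
                        "rate": k / nrep if nrep else np.nan,
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                    }
                )
        return pd.DataFrame(rows)

    def ks_uniformity(self) -> pd.Series:
        """Kolmogorov-Smirnov p-value against Uniform(0,1) per method."""
        out = {}
        for method in self.p_values.columns:
            p = self.p_values[method].dropna().to_numpy()
            out[method] = stats.kstest(p, "uniform").pvalue if len(p) else np.nan
        return pd.Series(out, name="ks_p")

    def qq_table(self) -> pd.DataFrame:
        """QQ-plot coordinates: -log10 expected vs observed per method."""
        rows = []
        for method in self.p_values.columns:
            p = np.sort(self.p_values[method].dropna().to_numpy())
            nrep = len(p)
            expected = (np.arange(1, nrep + 1) - 0.5) / nrep
            for e, o in zip(expected, p):
                rows.append(
                    {
                        "method": method,
                        "expected_neglog10": -np.log10(e),
                        "observed_neglog10": -np.log10(max(o, 1e-300)),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.p_values.to_csv(out_dir / "p_values.tsv", sep="\t", index_label="replicate")
        self.qq_table().to_csv(out_dir / "qq.tsv", sep="\t", index=False)
        summary = {
            "meta": self.meta,
            "rejection": self.rejection_summary().to_dict(orient="records"),
            "ks_uniformity": {
                k: (None if pd.isna(v) else float(v))
                for k, v in self.ks_uniformity().items()
            },
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def run_study(
    test_fns: Mapping[str, Callable],
    config,
    n_reps: int,
    seed: int = 0,
    alphas: Sequence[float] = (0.05,),
    progress: Callable[[int], None] | None = None,
) -> StudyResult:
    """Run a replicate study: fresh cohort per replicate, each test applied.

    ``config`` is a ScenarioConfig, a (PowerConfig, ScenarioConfig) pair, or a
    callable ``seed -> Cohort``.  Replicate r uses seed ``seed + r``; a test
    failure is recorded as NA and never aborts the study.
    """
    records: list[dict] = []
    for rep in range(n_reps):
        rep_seed = seed + rep
        if callable(config):
            cohort = config(rep_seed)
        elif isinstance(config, ScenarioConfig):
            cohort = simulate_null(replace(config, seed=rep_seed))
        else:
            power, base = config
            cohort = simulate_power(power, replace(base, seed=rep_seed))
        row: dict = {}
        for fn in test_fns.values():
            try:
                res = fn(cohort, rep_seed)
            except Exception:
                continue  # missing keys become NA below
            if isinstance(res, Mapping):
                row.update({k: float(v) for k, v in res.items()})
        records.append(row)
        if progress is not None:
            progress(rep)
    p_values = pd.DataFrame.from_records(records)
    return StudyResult(
        p_values=p_values,
        alphas=tuple(alphas),
        meta={"n_reps": n_reps, "seed": seed},
    )
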