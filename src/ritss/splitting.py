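"""Sample splitting: K test folds, each with a 3-way partition of its complement.

Cross-fitted inference needs the screening, main-effect estimation and
orthogonalization steps to run on samples disjoint from the fold in which the
test statistic is evaluated.  ``make_fold_plan`` partitions the n samples into
K test folds ``I_k`` of near-equal size and splits each complement into three
parts ``C1_k, C2_k, C3_k`` according to the splitting fractions
``c = (c1, c2, c3)`` by largest-remainder apportionment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

__all__ = ["SplitConfig", "Fold", "FoldPlan", "make_fold_plan", "apportion"]

DEFAULT_FRACTIONS = (Fraction(1, 3), Fraction(1, 3), Fraction(1, 3))


@dataclass(frozen=True)
class SplitConfig:
    """Number of folds K, complement fractions c=(c1,c2,c3), and RNG seed."""

    K: int = 4
    c: tuple = DEFAULT_FRACTIONS
    seed: int = 0
    min_part_size: int = 50

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if len(self.c) != 3 or any(float(ci) <= 0 for ci in self.c):
            raise ValueError("c must be 3 positive fractions")
        if abs(sum(float(ci) for ci in self.c) - 1.0) > 1e-12:
            raise ValueError("splitting fractions must sum to 1")


@dataclass(frozen=True)
class Fold:
    k: int
    test: np.ndarray   # I_k
    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray

    @property
    def complement(self) -> np.ndarray:
        return np.concatenate([self.c1, self.c2, self.c3])


@dataclass(frozen=True)
class FoldPlan:
    n: int
    config: SplitConfig
    folds: list = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "n": self.n,
            "K": self.config.K,
            "c": [str(ci) for ci in self.config.c],
            "seed": self.config.seed,
            "folds": [
                {
                    "k": f.k,
                    "test": f.test.tolist(),
                    "c1": f.c1.tolist(),
                    "c2": f.c2.tolist(),
                    "c3": f.c3.tolist(),
                }
                for f in self.folds
            ],
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def apportion(total: int, fractions) -> list[int]:
    """Largest-remainder apportionment of `total` over `fractions`.

    Remaining seats go to the largest fractional remainders; ties break to the
    lower part index so the result is deterministic.
    """
    quotas = [total * float(f) for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    left = total - sum(base)
    remainders = [q - b for q, b in zip(quotas, base)]
    # sort by (-remainder, index): biggest remainder first, ties to lower index
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:left]:
        base[i] += 1
    return base


def make_fold_plan(n: int, config: SplitConfig | None = None) -> FoldPlan:
    """Randomly partition n samples into K test folds plus complement parts."""
    config = config or SplitConfig()
    K = config.K
    floor_size = n // K
    min_c = min(float(ci) for ci in config.c)
    if floor_size < 1 or int((n - floor_size) * min_c) < config.min_part_size:
        needed = int(np.ceil(config.min_part_size / min_c / (1 - 1 / K)))
        raise ValueError(
            f"n={n} too small for K={K} with fractions {tuple(map(str, config.c))}; "
            f"need roughly n >= {needed} (min part size {config.min_part_size})"
        )

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    # |I_k| in {floor(n/K), ceil(n/K)}; earlier folds get the extras
    sizes = [floor_size + (1 if k < n % K else 0) for k in range(K)]
    bounds = np.cumsum([0] + sizes)
    test_sets = [np.sort(perm[bounds[k]:bounds[k + 1]]) for k in range(K)]

    folds = []
    all_rows = np.arange(n)
    for k, test in enumerate(test_sets):
        comp = np.setdiff1d(all_rows, test)
        comp = rng.permutation(comp)
        parts = apportion(len(comp), config.c)
        b = np.cumsum([0] + parts)
        folds.append(
            Fold(
                k=k,
                test=test,
                c1=np.sort(comp[b[0]:b[1]]),
                c2=np.sort(comp[b[1]:b[2]]),
                c3=np.sort(comp[b[2]:b[3]]),
            )
        )
    return FoldPlan(n=n, config=config, folds=folds)
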