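"""Cohort container, file I/O and interaction-score evaluation.

A :class:`Cohort` holds the four aligned blocks of a gene-environment
interaction analysis: a quantitative phenotype ``Y`` (length ``n``), an
additive genotype dosage matrix ``X`` (``n x m``, values in [0, 2]), an
environmental exposure matrix ``E`` (``n x d``) and a covariate matrix
``Z`` (``n x p``).  All loaders enforce complete cases and a deterministic
row order (sorted sample ID) so that seed-controlled splits are
reproducible across input file orderings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "InteractionScoreSpec",
    "load_cohort",
    "evaluate_score",
    "write_cohort",
    "cohort_summary",
]

#: Leading non-genotype columns of a PLINK additive-dosage export.
_PLINK_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


@dataclass
class Cohort:
    """Aligned phenotype / genotype / exposure / covariate data for n samples."""

    sample_ids: list[str]
    Y: np.ndarray
    X: np.ndarray
    E: np.ndarray
    Z: np.ndarray
    variant_ids: list[str]
    env_names: list[str]
    covar_names: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = len(self.sample_ids)
        for name, block in (("Y", self.Y), ("X", self.X), ("E", self.E), ("Z", self.Z)):
            if block.shape[0] != n:
                raise ValueError(f"{name} has {block.shape[0]} rows, expected {n}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids are not unique")
        for block in (self.Y, self.X, self.E, self.Z):
            if block.size and not np.all(np.isfinite(block)):
                raise ValueError("Cohort contains missing or non-finite values")
        if self.X.size:
            bad = np.where((self.X < 0) | (self.X > 2))
            if bad[0].size:
                j = int(bad[1][0])
                raise ValueError(
                    f"dosage outside [0, 2] for variant {self.variant_ids[j]!r}"
                )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def d(self) -> int:
        return self.E.shape[1]

    @property
    def p(self) -> int:
        return self.Z.shape[1]


@dataclass
class InteractionScoreSpec:
    """Weighted set of variant-by-exposure product terms.

    The score for sample ``i`` is ``U_i = sum_terms w * X_ij * E_il`` over the
    ``(j, l, w)`` triples in ``terms``.  An empty term list is a legal
    degenerate score evaluating to zero everywhere.
    """

    terms: list[tuple[int, int, float]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        pairs = [(j, l) for j, l, _ in self.terms]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (variant, exposure) pair in score terms")
        if any(not np.isfinite(w) for _, _, w in self.terms):
            raise ValueError("non-finite weight in score terms")

    @property
    def variant_indices(self) -> list[int]:
        return sorted({j for j, _, _ in self.terms})

    def validate(self, cohort: Cohort) -> None:
        for j, l, _ in self.terms:
            if not (0 <= j < cohort.m and 0 <= l < cohort.d):
                raise IndexError(f"score term ({j}, {l}) out of range for cohort")


def evaluate_score(
    spec: InteractionScoreSpec, cohort: Cohort, rows: np.ndarray | Sequence[int] | None = None
) -> np.ndarray:
    """Evaluate ``U_i = sum_jl pi_jl X_ij E_il`` on the requested rows."""
    spec.validate(cohort)
    rows = np.arange(cohort.n) if rows is None else np.asarray(rows, dtype=int)
    u = np.zeros(len(rows))
    for j, l, w in spec.terms:
        u += w * cohort.X[rows, j] * cohort.E[rows, l]
    return u


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a sample-ID column plus data columns")
    df = df.rename(columns={df.columns[0]: "_sid"})
    df["_sid"] = df["_sid"].astype(str)
    if df["_sid"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample IDs")
    return df.set_index("_sid")


def _read_genotypes(path: str | Path, dialect: str) -> pd.DataFrame:
    if dialect == "tsv":
        return _read_table(path)
    if dialect != "plink_raw":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    missing = [c for c in _PLINK_RAW_META if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a PLINK .raw file (missing {missing})")
    # dosage columns are those suffixed with the counted allele, e.g. rs123_A
    dosage_cols = [c for c in df.columns if c not in _PLINK_RAW_META]
    out = df[["IID", *dosage_cols]].rename(columns={"IID": "_sid"})
    out["_sid"] = out["_sid"].astype(str)
    return out.set_index("_sid")


def load_cohort(
    pheno_path: str | Path,
    geno_path: str | Path,
    env_path: str | Path,
    covar_path: str | Path,
    geno_dialect: str = "tsv",
) -> Cohort:
    """Load and align the four input tables into a complete-case Cohort.

    Tables are inner-joined on sample ID, rows with any missing value are
    dropped, and rows are sorted by sample ID.  The phenotype file must have
    exactly one numeric phenotype column.
    """
    pheno = _read_table(pheno_path)
    if pheno.shape[1] != 1:
        raise ValueError(f"{pheno_path}: expected exactly one phenotype column")
    geno = _read_genotypes(geno_path, geno_dialect)
    env = _read_table(env_path)
    covar = _read_table(covar_path)

    ids = pheno.index
    for other in (geno.index, env.index, covar.index):
        ids = ids.intersection(other)
    if len(ids) == 0:
        raise ValueError("no sample IDs shared by all four input files")

    merged = pd.concat(
        [pheno.loc[ids], geno.loc[ids], env.loc[ids], covar.loc[ids]], axis=1
    )
    merged = merged.apply(pd.to_numeric, errors="coerce")
    if merged.iloc[:, 0].isna().all():
        raise ValueError(f"{pheno_path}: phenotype column is non-numeric")
    merged = merged.dropna(axis=0, how="any").sort_index()
    if merged.shape[0] == 0:
        raise ValueError("no complete-case samples after merging")

    ncols = [pheno.shape[1], geno.shape[1], env.shape[1], covar.shape[1]]
    stops = np.cumsum(ncols)
    vals = merged.to_numpy(dtype=float)
    return Cohort(
        sample_ids=[str(s) for s in merged.index],
        Y=vals[:, 0],
        X=vals[:, stops[0]:stops[1]],
        E=vals[:, stops[1]:stops[2]],
        Z=vals[:, stops[2]:stops[3]],
        variant_ids=[str(c) for c in geno.columns],
        env_names=[str(c) for c in env.columns],
        covar_names=[str(c) for c in covar.columns],
    )


def write_cohort(cohort: Cohort, out_dir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
    """Write the cohort back to four TSV files (round-trips with load_cohort)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    blocks = {
        "pheno": (cohort.Y[:, None], ["phenotype"]),
        "geno": (cohort.X, cohort.variant_ids),
        "env": (cohort.E, cohort.env_names),
        "covar": (cohort.Z, cohort.covar_names),
    }
    for key, (mat, cols) in blocks.items():
        df = pd.DataFrame(mat, columns=cols, index=pd.Index(cohort.sample_ids, name="sample_id"))
        path = out_dir / f"{prefix}.{key}.tsv"
        df.to_csv(path, sep="\t", float_format="%.17g")
        paths[key] = path
    return paths


def cohort_summary(cohort: Cohort) -> dict:
    """JSON-ready summary of cohort dimensions and column names."""
    return {
        "n": cohort.n,
        "m": cohort.m,
        "d": cohort.d,
        "p": cohort.p,
        "variant_ids": list(cohort.variant_ids),
        "env_names": list(cohort.env_names),
        "covar_names": list(cohort.covar_names),
    }


def write_summary(cohort: Cohort, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cohort_summary(cohort), indent=2, sort_keys=True))
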