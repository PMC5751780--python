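"""Core containers for expression data, sample covariates, strata and sample pairs.

The analysis operates on a genes x samples matrix of (log-scale) expression
values ``E_im`` together with a per-sample covariate table.  Each sample ``S_m``
carries a factor vector ``B_m = (B_m1, ..., B_mz)`` of binary (-1/+1) or
ordinal small-integer codes.  Samples sharing an identical factor vector form a
*stratum*; only sample pairs drawn from within a stratum enter the pairwise
co-expression statistic, so that the covariates of a pair are unambiguous
(``B_mn = B_m = B_n``).

Expression values are assumed already log-transformed and normalized; no
normalization is performed here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("multidcox")


class LoadError(ValueError):
    """Raised when an input file violates the expected tabular format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of real expression values.

    Parameters
    ----------
    values
        2-D float array, one row per gene, one column per sample. All entries
        must be finite.
    gene_ids, sample_ids
        Unique identifiers for rows and columns respectively.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        ng, ns = self.values.shape
        if ng != len(self.gene_ids):
            raise ValueError(
                f"{ng} rows but {len(self.gene_ids)} gene ids"
            )
        if ns != len(self.sample_ids):
            raise ValueError(
                f"{ns} columns but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class FactorTable:
    """Per-sample covariate codes.

    Each factor column is a binary (-1/+1) or ordinal small-integer code;
    a constant column carries no contrast and is rejected.  Categorical
    covariates should be recoded with :func:`recode_categorical` and real
    covariates discretized with :func:`discretize` before constructing the
    table.
    """

    sample_ids: list[str]
    factor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.factor_names = [str(f) for f in self.factor_names]
        if self.values.ndim != 2:
            raise ValueError("factor values must be a 2-D matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = self.values.astype(int)
            if not np.array_equal(as_int, self.values):
                raise ValueError("factor values must be integer codes")
            self.values = as_int
        ns, nf = self.values.shape
        if ns != len(self.sample_ids):
            raise ValueError(f"{ns} rows but {len(self.sample_ids)} sample ids")
        if nf != len(self.factor_names):
            raise ValueError(f"{nf} columns but {len(self.factor_names)} factor names")
        if nf < 1:
            raise ValueError("at least one factor is required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.factor_names)) != len(self.factor_names):
            raise ValueError("duplicate factor names")
        for j, name in enumerate(self.factor_names):
            if np.unique(self.values[:, j]).size < 2:
                raise ValueError(f"factor {name!r} is constant across samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]

    def reordered(self, sample_ids: list[str]) -> "FactorTable":
        """Return a copy whose rows follow ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValueError(f"samples missing from factor table: {missing[:5]}")
        order = [index[s] for s in sample_ids]
        return FactorTable(list(sample_ids), list(self.factor_names), self.values[order])


@dataclass
class Stratum:
    """A maximal group of samples sharing one factor vector."""

    factor_vector: tuple[int, ...]
    member_samples: list[int]

    @property
    def size(self) -> int:
        return len(self.member_samples)

    @property
    def n_pairs(self) -> int:
        s = self.size
        return s * (s - 1) // 2


@dataclass(frozen=True)
class SamplePair:
    """An unordered within-stratum sample pair, stored with ``m < n``."""

    m: int
    n: int
    stratum_vector: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.m < self.n:
            raise ValueError("sample pair must satisfy m < n")


# ---------------------------------------------------------------------------
# covariate recoding helpers
# ---------------------------------------------------------------------------

def recode_categorical(column: pd.Series | list, name: str) -> pd.DataFrame:
    """Recode a categorical covariate with k levels into k-1 binary -1/+1 columns.

    Level ordering is the sorted order of the observed levels; the first level
    is the reference. Column ``name=level`` is +1 for samples at that level,
    -1 otherwise.
    """
    col = pd.Series(column)
    levels = sorted(col.dropna().unique().tolist(), key=str)
    if len(levels) < 2:
        raise ValueError(f"categorical covariate {name!r} has fewer than 2 levels")
    out = {}
    for level in levels[1:]:
        out[f"{name}={level}"] = np.where(col.values == level, 1, -1)
    return pd.DataFrame(out, index=col.index)


def discretize(column: pd.Series | list, bin_edges: list[float], name: str) -> pd.Series:
    """Discretize a real covariate into ordinal codes centred on zero.

    ``bin_edges`` are the interior cut points; k edges produce k+1 levels coded
    as consecutive integers centred on 0 (e.g. 2 edges -> -1, 0, +1).
    """
    col = pd.Series(column, dtype=float)
    edges = sorted(bin_edges)
    codes = np.digitize(col.values, edges)  # 0 .. len(edges)
    k = len(edges) + 1
    centred = codes - (k - 1) // 2
    return pd.Series(centred.astype(int), index=col.index, name=name)


# ---------------------------------------------------------------------------
# loading and filtering
# ---------------------------------------------------------------------------

def variance_filter(expr: ExpressionMatrix, min_variance_quantile: float) -> ExpressionMatrix:
    """Drop genes whose across-sample variance falls below the given quantile.

    ``min_variance_quantile=0`` keeps every gene; ``0.5`` drops the
    lower-variance half of the genes (non-detectable / flat probes).
    """
    if not 0.0 <= min_variance_quantile <= 1.0:
        raise ValueError("min_variance_quantile must be in [0, 1]")
    if min_variance_quantile == 0.0:
        return expr
    var = expr.values.var(axis=1, ddof=1)
    cut = np.quantile(var, min_variance_quantile)
    keep = var > cut
    if not keep.any():
        # all-equal variances: keep everything rather than empty the matrix
        keep = np.ones_like(keep, dtype=bool)
    kept = [g for g, k in zip(expr.gene_ids, keep) if k]
    logger.info(
        "variance filter (quantile %.2f): %d of %d genes retained",
        min_variance_quantile, len(kept), expr.n_genes,
    )
    return ExpressionMatrix(expr.values[keep], kept, list(expr.sample_ids))


def load_expression(path, min_variance_quantile: float = 0.0) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix (first column gene id, header row
    of sample ids) and apply the variance filter."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise LoadError(f"cannot parse expression file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise LoadError(f"duplicate sample ids in {path}: {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = df.apply(pd.to_numeric, errors="coerce")
        rows = df.index[bad.isna().any(axis=1)].tolist()
        raise LoadError(f"non-numeric cells in {path} at gene rows {rows[:5]}") from exc
    if np.isnan(values).any():
        rows = df.index[np.isnan(values).any(axis=1)].tolist()
        raise LoadError(f"missing values in {path} at gene rows {rows[:5]}")
    expr = ExpressionMatrix(values, df.index.tolist(), df.columns.tolist())
    return variance_filter(expr, min_variance_quantile)


def load_factors(path) -> FactorTable:
    """Load a tab-delimited covariate table (first column sample id, remaining
    columns factors)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover
        raise LoadError(f"cannot parse factor file {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise LoadError(f"duplicate sample ids in {path}")
    try:
        values = df.to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        raise LoadError(
            f"non-integer factor codes in {path}; recode categorical columns first"
        ) from exc
    return FactorTable(df.index.tolist(), df.columns.tolist(), values)


# ---------------------------------------------------------------------------
# stratification and pairing
# ---------------------------------------------------------------------------

def build_strata(factors: FactorTable) -> list[Stratum]:
    """Group samples by exact factor-vector equality.

    Singleton strata are retained (they are part of the partition) but yield no
    sample pairs; a warning is logged for each.
    """
    groups: dict[tuple[int, ...], list[int]] = {}
    for i, row in enumerate(factors.values):
        groups.setdefault(tuple(int(v) for v in row), []).append(i)
    strata = [Stratum(vec, members) for vec, members in sorted(groups.items())]
    for st in strata:
        if st.size == 1:
            logger.warning(
                "stratum %s has a single sample and contributes no pairs", st.factor_vector
            )
    return strata


def enumerate_pairs(
    strata: list[Stratum],
    max_pairs: int | None = None,
    rng_seed: int = 0,
) -> list[SamplePair]:
    """All unordered within-stratum sample pairs, optionally subsampled.

    When the total exceeds ``max_pairs`` a uniform random subset of that size
    is drawn (seeded), constrained to keep at least one pair from every
    non-singleton stratum so no stratum drops out of the model.
    """
    all_pairs: list[SamplePair] = []
    by_stratum: list[list[SamplePair]] = []
    for st in strata:
        ps = [
            SamplePair(m, n, st.factor_vector)
            for m, n in itertools.combinations(sorted(st.member_samples), 2)
        ]
        if ps:
            by_stratum.append(ps)
        all_pairs.extend(ps)
    if not all_pairs:
        raise ValueError(
            "no two samples share a stratum: every factor vector is unique, "
            "so no within-stratum pairs exist"
        )
    if max_pairs is None or len(all_pairs) <= max_pairs:
        return all_pairs
    n_strata = len(by_stratum)
    if max_pairs < n_strata:
        raise ValueError(
            f"max_pairs={max_pairs} cannot cover the {n_strata} strata with pairs"
        )
    rng = np.random.default_rng(rng_seed)
    chosen: set[SamplePair] = set()
    for ps in by_stratum:
        chosen.add(ps[rng.integers(len(ps))])
    remaining = [p for p in all_pairs if p not in chosen]
    extra = max_pairs - len(chosen)
    if extra > 0:
        idx = rng.choice(len(remaining), size=extra, replace=False)
        chosen.update(remaining[i] for i in idx)
    # deterministic order: sort by (m, n)
    return sorted(chosen, key=lambda p: (p.m, p.n))
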