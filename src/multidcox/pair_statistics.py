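"""The pairwise co-expression statistic and the multi-factor linear model.

For a gene set ``I`` and a within-stratum sample pair ``(S_m, S_n)`` the
co-expression statistic is the squared mean expression change

    A_mn(I) = ( (1/|I|) * sum_{i in I} (E_im - E_in) )^2 .

When the genes of ``I`` shift coherently between the two samples (they are
co-expressed and the shared signal differs between the samples) the mean
change is large and so is ``A``; incoherent changes cancel in the mean and
``A`` stays near zero.  Because ``A_mn(I)`` is the squared difference of the
set *centroid* (the per-sample mean expression over ``I``), every statistic in
this package reduces to centroid differences over sample pairs, which is what
makes the greedy search cheap.

Factor influence is quantified by ordinary least squares of the statistic
vector ``A(I)`` (one entry per sample pair) on the pairs' factor vectors with
an intercept:

    A(I) ~ 1 + B .

The intercept absorbs baseline co-expression common to all strata — in
particular a set co-expressed in *every* sample loads entirely on the
intercept and shows no factor coefficient, which is what keeps such sets out
of the differential calls.  The fitted factor coefficients ``F(I)`` form the
differential co-expression profile of the set; each factor's significance is
the single-coefficient partial F-test (df 1, a - z - 1), equivalent to the
squared t-statistic.  P-values are nominal — dependence among pairs sharing a
sample is ignored — and are gated downstream by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import ExpressionMatrix, FactorTable, SamplePair

__all__ = [
    "PairDesign",
    "DCXFit",
    "build_design",
    "pair_statistic",
    "statistic_vector",
    "fit_model",
    "batch_fit_coefficients",
    "batch_fit_full",
]


@dataclass
class PairDesign:
    """Sample pairs plus the regression design matrix.

    ``design`` has one row per pair: an intercept column of ones followed by
    the pair's stratum factor vector ``B_mn``.  The matrix must have full
    column rank; a rank-deficient design (aliased factors) is rejected at
    construction with the offending columns named.
    """

    pairs: list[SamplePair]
    design: np.ndarray
    factor_names: list[str]
    # cached decompositions, filled lazily
    _solver: np.ndarray | None = field(default=None, repr=False, compare=False)
    _xtx_inv_diag: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D")
        a, p = self.design.shape
        if a != len(self.pairs):
            raise ValueError("one design row per pair required")
        if p != len(self.factor_names) + 1:
            raise ValueError("design must be (intercept | factors)")
        if len(self.factor_names) < 1:
            raise ValueError("at least one factor is required (z >= 1)")
        rank = np.linalg.matrix_rank(self.design)
        if rank < p:
            # identify collinear columns from the QR diagonal
            _, r = np.linalg.qr(self.design)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(self.design.shape) * np.finfo(float).eps
            names = ["(intercept)"] + list(self.factor_names)
            bad = [names[j] for j in range(p) if diag[j] <= tol]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    @property
    def n_pairs(self) -> int:
        return self.design.shape[0]

    @property
    def n_factors(self) -> int:
        return self.design.shape[1] - 1

    @property
    def dof(self) -> int:
        """Residual degrees of freedom a - z - 1."""
        return self.n_pairs - self.design.shape[1]

    @property
    def m_index(self) -> np.ndarray:
        return np.array([p.m for p in self.pairs], dtype=np.intp)

    @property
    def n_index(self) -> np.ndarray:
        return np.array([p.n for p in self.pairs], dtype=np.intp)

    @property
    def solver(self) -> np.ndarray:
        """(X'X)^{-1} X', computed once from a single QR factorization."""
        if self._solver is None:
            q, r = np.linalg.qr(self.design)
            self._solver = np.linalg.solve(r, q.T)
        return self._solver

    @property
    def xtx_inv_diag(self) -> np.ndarray:
        if self._xtx_inv_diag is None:
            xtx_inv = np.linalg.inv(self.design.T @ self.design)
            self._xtx_inv_diag = np.diag(xtx_inv).copy()
        return self._xtx_inv_diag


@dataclass
class DCXFit:
    """A fitted differential co-expression model for one gene set."""

    coefficients: np.ndarray  # factor coefficients F(I), length z
    intercept: float
    pvalues: np.ndarray  # per-factor partial F-test p-values, length z
    geneset: list[int]  # gene row indices I (empty for pseudo-profiles)
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.coefficients.shape != self.pvalues.shape:
            raise ValueError("coefficients and pvalues must align")
        if np.any((self.pvalues < 0) | (self.pvalues > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def build_design(
    factors: FactorTable,
    pairs: list[SamplePair],
) -> PairDesign:
    """Assemble the (intercept | B_mn) design matrix for a pair list."""
    rows = np.empty((len(pairs), factors.n_factors + 1))
    rows[:, 0] = 1.0
    for i, p in enumerate(pairs):
        rows[i, 1:] = p.stratum_vector
    return PairDesign(list(pairs), rows, list(factors.factor_names))


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def pair_statistic(
    expr: ExpressionMatrix, geneset, pair: SamplePair
) -> float:
    """A_mn(I): squared mean expression change of the set between two samples."""
    idx = np.asarray(geneset, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("gene set must be nonempty")
    diff = expr.values[idx, pair.m] - expr.values[idx, pair.n]
    return float(diff.mean() ** 2)


def centroid_profile(expr: ExpressionMatrix, geneset) -> np.ndarray:
    """Per-sample mean expression E_C over a gene set (its centroid)."""
    idx = np.asarray(geneset, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("gene set must be nonempty")
    return expr.values[idx].mean(axis=0)


def statistic_vector_from_profile(
    profile: np.ndarray, design: PairDesign
) -> np.ndarray:
    """A(I) computed from a precomputed centroid profile (length n_samples)."""
    d = profile[design.m_index] - profile[design.n_index]
    return d * d


def statistic_vector(
    expr: ExpressionMatrix, geneset, design: PairDesign
) -> np.ndarray:
    """The response vector A(I): one A_mn(I) per sample pair of the design."""
    return statistic_vector_from_profile(centroid_profile(expr, geneset), design)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _pvalues_from(
    coef: np.ndarray,
    sse: np.ndarray,
    design: PairDesign,
    response_scale: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Partial F-test p-values for factor coefficients.

    ``coef`` is (..., z+1) including the intercept; ``sse`` is (...,);
    ``response_scale`` is the mean square of each response, used to detect
    numerically perfect fits.  Returns p-values of shape (..., z) for the
    factor columns only.
    """
    dof = design.dof
    if dof <= 0:
        raise ValueError(
            f"need more pairs than parameters: a={design.n_pairs}, z={design.n_factors}"
        )
    sse = np.asarray(sse, dtype=float)
    scale = np.maximum(np.asarray(response_scale, dtype=float), np.finfo(float).tiny)
    saturated = sse <= 1e-24 * design.n_pairs * scale
    sigma2 = np.where(saturated, 0.0, sse)[..., None] / dof
    var = sigma2 * design.xtx_inv_diag[1:]
    ok = var > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = np.where(ok, coef[..., 1:] ** 2 / np.where(ok, var, 1.0), 0.0)
    pvals = np.asarray(stats.f.sf(fstat, 1, dof))
    # perfect (zero-residual) fits: a numerically nonzero coefficient is
    # maximally significant, a vanishing one is untestable -> p = 1
    scale = np.maximum(1.0, np.abs(coef[..., :1]))
    nonzero = np.abs(coef[..., 1:]) > 1e-10 * scale
    pvals = np.where(~ok, np.where(nonzero, 0.0, 1.0), pvals)
    return pvals


def fit_model(A: np.ndarray, design: PairDesign, geneset=()) -> DCXFit:
    """OLS of the statistic vector on (intercept | factors) with per-factor
    partial F-test p-values."""
    A = np.asarray(A, dtype=float)
    if A.shape != (design.n_pairs,):
        raise ValueError("response length must equal the number of pairs")
    coef = design.solver @ A
    resid = A - design.design @ coef
    sse = float(resid @ resid)
    pvals = _pvalues_from(
        coef[None, :], np.array([sse]), design, np.array([np.mean(A * A)])
    )[0]
    return DCXFit(
        coefficients=coef[1:].copy(),
        intercept=float(coef[0]),
        pvalues=pvals,
        geneset=list(geneset),
        factor_names=list(design.factor_names),
    )


def batch_fit_coefficients(A_rows: np.ndarray, design: PairDesign) -> np.ndarray:
    """Factor coefficients for many responses sharing one design.

    A single QR factorization of the design is reused across all k responses,
    which is what makes the exhaustive gene-pair scans tractable; p-values are
    deliberately not computed here (they are evaluated only for responses that
    survive the coefficient-magnitude filter).

    Returns a (k, z) matrix of factor coefficients (intercept excluded).
    """
    A_rows = np.atleast_2d(np.asarray(A_rows, dtype=float))
    if A_rows.shape[1] != design.n_pairs:
        raise ValueError("each response row must have one entry per pair")
    coef = A_rows @ design.solver.T  # (k, z+1)
    return coef[:, 1:]


def batch_fit_full(
    A_rows: np.ndarray, design: PairDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients (incl. intercept), p-values and SSE for many responses.

    Returns ``(coef (k, z+1), pvalues (k, z), sse (k,))``.
    """
    A_rows = np.atleast_2d(np.asarray(A_rows, dtype=float))
    coef = A_rows @ design.solver.T
    resid = A_rows - coef @ design.design.T
    sse = np.einsum("ij,ij->i", resid, resid)
    pvals = _pvalues_from(coef, sse, design, np.einsum("ij,ij->i", A_rows, A_rows) / A_rows.shape[1])
    return coef, pvals, sse
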