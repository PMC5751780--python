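"""Null calibration of coefficient-magnitude thresholds.

The global significance threshold ``C_T`` is derived from the empirical null
distribution of factor coefficients: fit the pair model to a large number of
randomly sampled gene pairs, pool the absolute coefficients of *all* factors
across all sampled pairs, and take half of the m-th largest pooled value
(m = 10 by default).  Halving deliberately lays a wider net at the start of
the search; m > 1 guards against the handful of sampled pairs that may belong
to genuinely differentially co-expressed sets and would otherwise inflate the
threshold.

From ``C_T`` two signed thresholds follow:

* ``T_oi`` — the directional seed threshold, ``+C_T`` or ``-C_T`` according to
  the sign of the fitted coefficient;
* ``T_ni`` — the relaxed augmentation threshold, interpolating between
  ``T_oi`` and the conservatively expanded set's own coefficient ``F_i(J)``:
  ``Sign(F_iJ) * (alpha*|T_oi| + (1-alpha)*|F_iJ|)`` for significant factors,
  ``|T_oi|`` otherwise.  Since the calibration threshold is normally far
  below a fitted set coefficient, ``alpha = 1`` is the lowest (most
  admissive) bar and ``alpha = 0`` pins the bar at the set's own
  coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix
from .pair_statistics import PairDesign, batch_fit_coefficients

__all__ = [
    "ThresholdSet",
    "sample_gene_pairs",
    "calibrate_CT",
    "directional_threshold",
    "augmentation_threshold",
]


@dataclass
class ThresholdSet:
    """The calibrated global threshold plus the calibration settings."""

    C_T: float
    m: int = 10
    n_random_pairs: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.C_T < 0:
            raise ValueError("C_T must be nonnegative")
        if self.m < 2:
            raise ValueError("order statistic index m must be >= 2")


def sample_gene_pairs(
    n_genes: int, n_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample unordered gene pairs uniformly without replacement.

    Returns an (n_pairs, 2) integer array with column 0 < column 1.
    """
    total = n_genes * (n_genes - 1) // 2
    n_pairs = min(n_pairs, total)
    if total <= 4 * n_pairs:
        flat = rng.choice(total, size=n_pairs, replace=False)
        # invert the row-major upper-triangle linearization
        i = (
            n_genes
            - 2
            - np.floor(
                np.sqrt(-8 * flat + 4 * n_genes * (n_genes - 1) - 7) / 2 - 0.5
            )
        ).astype(np.intp)
        j = (flat + i + 1 - i * (2 * n_genes - i - 1) // 2).astype(np.intp)
        return np.column_stack([i, j])
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_pairs:
        draw = rng.integers(0, n_genes, size=(n_pairs, 2))
        for a, b in draw:
            if a == b:
                continue
            pair = (int(min(a, b)), int(max(a, b)))
            seen.add(pair)
            if len(seen) == n_pairs:
                break
    return np.array(sorted(seen), dtype=np.intp)


def pair_responses(
    expr: ExpressionMatrix, pairs_idx: np.ndarray, design: PairDesign
) -> np.ndarray:
    """Statistic vectors A for many gene pairs at once: rows ((d_i+d_j)/2)^2."""
    d = expr.values[:, design.m_index] - expr.values[:, design.n_index]
    mid = 0.5 * (d[pairs_idx[:, 0]] + d[pairs_idx[:, 1]])
    return mid * mid


def calibrate_CT(
    expr: ExpressionMatrix,
    design: PairDesign,
    n_random_pairs: int = 10_000,
    m: int = 10,
    rng_seed: int = 0,
) -> ThresholdSet:
    """Estimate C_T as half the m-th largest pooled absolute null coefficient."""
    if n_random_pairs < m:
        raise ValueError("n_random_pairs must be at least m")
    rng = np.random.default_rng(rng_seed)
    pairs_idx = sample_gene_pairs(expr.n_genes, n_random_pairs, rng)
    coefs = batch_fit_coefficients(pair_responses(expr, pairs_idx, design), design)
    pooled = np.abs(coefs).ravel()
    if pooled.size < m:
        raise ValueError(
            f"only {pooled.size} pooled coefficients but m={m}; "
            "sample more gene pairs"
        )
    mth_max = np.partition(pooled, pooled.size - m)[pooled.size - m]
    return ThresholdSet(
        C_T=float(mth_max) / 2.0,
        m=m,
        n_random_pairs=int(pairs_idx.shape[0]),
        rng_seed=rng_seed,
    )


def directional_threshold(C_T: float, coefficient_sign: int) -> float:
    """T_oi: the seed threshold carrying the sign of the fitted coefficient."""
    if coefficient_sign not in (-1, 1):
        raise ValueError("coefficient_sign must be -1 or +1")
    return float(coefficient_sign) * C_T


def augmentation_threshold(
    T_oi: float, F_iJ: float, alpha: float, h_i: int
) -> float:
    """T_ni: relaxed threshold for centroid-pair augmentation.

    For a significant factor (|h_i| = 1) this interpolates between the seed
    threshold and the expanded set's coefficient, carrying the coefficient's
    sign; for an insignificant factor the unsigned seed magnitude |T_oi| is
    returned.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if h_i not in (-1, 0, 1):
        raise ValueError("h_i must be -1, 0 or +1")
    if h_i == 0:
        return abs(T_oi)
    sign = np.sign(F_iJ) if F_iJ != 0 else float(h_i)
    return float(sign * (alpha * abs(T_oi) + (1.0 - alpha) * abs(F_iJ)))
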