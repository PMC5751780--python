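"""Post-hoc gating of factor influence for discovered gene sets.

The greedy search optimizes factor coefficients over gene choices, so the
nominal F-test p-values of the reported fits are optimistically biased.  A
factor is accepted as influential on a set's co-expression only if it passes
both of the following:

*Effect-size criterion.*  Coefficients of all factors over all discovered
sets are pooled; most factor/set combinations carry no genuine influence, so
the pooled density shows a central near-zero peak flanked, when real effects
exist, by side modes.  The first density valleys either side of the central
peak give the thresholds ``T_f+`` and ``T_f-``; a coefficient is significant
if it lies beyond them.  A side with no mode falls back to that side's
97.5th percentile (flagged).

*Permutation criterion.*  Factor columns of the covariate table are permuted
across samples (independently per column by default), strata and sample
pairs are rebuilt, and the model is refitted on the same gene set.  The
factor is non-influential if at least a predefined fraction (0.01) of
permutations produce a coefficient beyond the observed one in its direction
with a p-value below min(observed p, 0.01).

Only sets with at least one surviving factor and at least ``min_set_size``
genes (default 6) are reported.  Gating can zero a factor call but never
flips its sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_model import ExpressionMatrix, FactorTable
from .pair_statistics import DCXFit, PairDesign

logger = logging.getLogger("multidcox")

__all__ = [
    "EffectThresholds",
    "PermutationResult",
    "effect_size_thresholds",
    "permutation_test",
    "gate_sets",
    "influence_call",
]


# ---------------------------------------------------------------------------
# effect-size thresholds from the pooled coefficient density
# ---------------------------------------------------------------------------

@dataclass
class EffectThresholds:
    """Valley thresholds beside the central peak of the pooled coefficients."""

    T_f_plus: float
    T_f_minus: float
    density_grid: np.ndarray
    bandwidth: float
    fallback_plus: bool = False
    fallback_minus: bool = False

    def __post_init__(self) -> None:
        if not (self.T_f_minus < 0 < self.T_f_plus):
            raise ValueError("thresholds must bracket zero: T_f- < 0 < T_f+")


def _local_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D array."""
    dy = np.diff(y)
    sign = np.sign(dy)
    # treat flat segments by propagating the previous slope sign
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.diff(sign)
    maxima = np.nonzero(turns < 0)[0] + 1
    minima = np.nonzero(turns > 0)[0] + 1
    return maxima, minima


def effect_size_thresholds(
    pooled_coefficients: np.ndarray,
    bandwidth_rule: str = "silverman",
    grid_size: int = 512,
) -> EffectThresholds:
    """Locate the density valleys flanking the central peak.

    Gaussian KDE (Silverman's rule by default) on a symmetric grid spanning
    ±1.1·max|coefficient|; ``T_f+`` is the abscissa of the first local
    minimum right of the near-zero mode, provided a side mode lies beyond it,
    and analogously for ``T_f-``.
    """
    pooled = np.asarray(pooled_coefficients, dtype=float).ravel()
    if pooled.size < 20:
        raise ValueError(
            f"only {pooled.size} pooled coefficients (< 20); effect-size "
            "thresholds are unreliable — use permutation-only gating"
        )
    r = 1.1 * np.abs(pooled).max()
    if r == 0:
        raise ValueError("all pooled coefficients are zero")
    grid = np.linspace(-r, r, grid_size)
    kde = stats.gaussian_kde(pooled, bw_method=bandwidth_rule)
    dens = kde(grid)
    maxima, minima = _local_extrema(dens)
    if maxima.size == 0:
        maxima = np.array([int(np.argmax(dens))])
    central = maxima[np.argmin(np.abs(grid[maxima]))]

    def _side(sign: int) -> tuple[float, bool]:
        if sign > 0:
            mins = [i for i in minima if i > central and grid[i] > 0]
            for i in mins:
                if any(j > i for j in maxima):  # a side mode beyond the valley
                    return float(grid[i]), False
            vals = pooled[pooled > 0]
            fb = float(np.quantile(vals, 0.975)) if vals.size else float(r)
            return max(fb, np.finfo(float).tiny), True
        mins = [i for i in reversed(minima) if i < central and grid[i] < 0]
        for i in mins:
            if any(j < i for j in maxima):
                return float(grid[i]), False
        vals = pooled[pooled < 0]
        fb = float(np.quantile(vals, 0.025)) if vals.size else float(-r)
        return min(fb, -np.finfo(float).tiny), True

    t_plus, fb_plus = _side(+1)
    t_minus, fb_minus = _side(-1)
    if fb_plus:
        logger.info("no right side mode; T_f+ falls back to the 97.5th percentile")
    if fb_minus:
        logger.info("no left side mode; T_f- falls back to the 2.5th percentile")
    bw = kde.factor * pooled.std(ddof=1)
    return EffectThresholds(
        T_f_plus=t_plus,
        T_f_minus=t_minus,
        density_grid=grid,
        bandwidth=float(bw),
        fallback_plus=fb_plus,
        fallback_minus=fb_minus,
    )


# ---------------------------------------------------------------------------
# permutation criterion
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    factor: str
    n_permutations: int
    n_better: int
    influential: bool

    @property
    def perm_fraction(self) -> float:
        return self.n_better / self.n_permutations


def _within_stratum_pairs(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (m, n) of all within-stratum pairs for factor rows B."""
    _, inverse = np.unique(B, axis=0, return_inverse=True)
    ms, ns = [], []
    for g in range(inverse.max() + 1):
        members = np.nonzero(inverse == g)[0]
        if len(members) < 2:
            continue
        mi, ni = np.triu_indices(len(members), k=1)
        ms.append(members[mi])
        ns.append(members[ni])
    if not ms:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    return np.concatenate(ms), np.concatenate(ns)


def permutation_test(
    genes: list[int],
    factor: int,
    expr: ExpressionMatrix,
    factors: FactorTable,
    observed_fit: DCXFit,
    n_permutations: int = 1000,
    rng_seed: int = 0,
    mode: str = "independent",
    fraction_cutoff: float = 0.01,
    p_cut: float = 0.01,
    centroid: np.ndarray | None = None,
) -> PermutationResult:
    """Permute factor values, rebuild strata and pairs, refit on the set.

    ``mode='independent'`` permutes each factor column on its own;
    ``mode='joint'`` permutes whole sample rows, preserving each sample's
    factor vector.  A permutation "beats" the observed fit when its
    coefficient lies beyond the observed one in its direction and its p-value
    is below min(observed p, ``p_cut``).
    """
    if n_permutations < 100:
        logger.warning(
            "%d permutations give resolution worse than the %.2g cutoff",
            n_permutations, fraction_cutoff,
        )
    if mode not in ("independent", "joint"):
        raise ValueError("mode must be 'independent' or 'joint'")
    if centroid is None:
        idx = np.asarray(genes, dtype=np.intp)
        centroid = expr.values[idx].mean(axis=0)
    obs_coef = float(observed_fit.coefficients[factor])
    obs_p = float(observed_fit.pvalues[factor])
    direction = 1.0 if obs_coef >= 0 else -1.0
    p_thresh = min(obs_p, p_cut)

    rng = np.random.default_rng(rng_seed)
    B = factors.values
    ns_samples, z = B.shape
    n_better = 0
    for _ in range(n_permutations):
        if mode == "independent":
            Bp = np.column_stack(
                [B[rng.permutation(ns_samples), j] for j in range(z)]
            )
        else:
            Bp = B[rng.permutation(ns_samples)]
        m_idx, n_idx = _within_stratum_pairs(Bp)
        if m_idx.size <= z + 1:
            continue
        X = np.empty((m_idx.size, z + 1))
        X[:, 0] = 1.0
        X[:, 1:] = Bp[m_idx]
        d = centroid[m_idx] - centroid[n_idx]
        A = d * d
        coef, res, rank, _ = np.linalg.lstsq(X, A, rcond=None)
        if rank < z + 1:
            continue
        c = float(coef[factor + 1])
        if direction * (c - obs_coef) <= 0:
            continue
        dof = m_idx.size - z - 1
        resid = A - X @ coef
        sse = float(resid @ resid)
        if sse <= 0:
            continue
        try:
            xtx_inv = np.linalg.inv(X.T @ X)
        except np.linalg.LinAlgError:
            continue
        var = sse / dof * xtx_inv[factor + 1, factor + 1]
        pval = float(stats.f.sf(c * c / var, 1, dof)) if var > 0 else 0.0
        if pval < p_thresh:
            n_better += 1
    frac = n_better / n_permutations
    return PermutationResult(
        factor=factors.factor_names[factor],
        n_permutations=n_permutations,
        n_better=n_better,
        influential=frac < fraction_cutoff,
    )


def influence_call(
    coefficient: float,
    effect: EffectThresholds | None,
    perm_fraction: float,
    fraction_cutoff: float = 0.01,
) -> int:
    """Final h for one factor: sign of the coefficient if it passes both the
    effect-size valleys and the permutation criterion, else 0."""
    if effect is not None:
        if not (coefficient > effect.T_f_plus or coefficient < effect.T_f_minus):
            return 0
    if perm_fraction >= fraction_cutoff:
        return 0
    return 1 if coefficient > 0 else -1


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def gate_sets(
    candidate_sets,
    expr: ExpressionMatrix,
    factors: FactorTable,
    design: PairDesign,
    config,
    rng_seed: int = 0,
    ctx=None,
):
    """Gate candidate sets by effect size and permutation; apply the size floor.

    Returns ``(reported_sets, effect_thresholds_or_None)``.  The permutation
    test is only evaluated for factors that already pass the effect-size
    criterion (the two criteria are conjunctive, so the result is identical
    and most null factors are skipped cheaply).
    """
    from .greedy_search import FactorProfile  # local: avoid import cycle

    pooled = np.concatenate(
        [s.fit.coefficients for s in candidate_sets]
    ) if candidate_sets else np.empty(0)
    effect: EffectThresholds | None = None
    try:
        effect = effect_size_thresholds(pooled)
        logger.info(
            "effect-size valleys: T_f+=%.4g T_f-=%.4g", effect.T_f_plus, effect.T_f_minus
        )
    except ValueError as exc:
        logger.warning("effect-size thresholds unavailable (%s); permutation-only gating", exc)

    reported = []
    ss = np.random.SeedSequence(rng_seed)
    for si, cand in enumerate(candidate_sets):
        if cand.size < config.min_set_size:
            continue
        gene_idx = cand.provenance.get("gene_indices")
        if gene_idx is None:
            lookup = {g: i for i, g in enumerate(expr.gene_ids)}
            gene_idx = [lookup[g] for g in cand.genes]
        h_final = np.zeros(design.n_factors, dtype=np.int8)
        gating: dict = {}
        for fk in range(design.n_factors):
            coef = float(cand.fit.coefficients[fk])
            pass_eff = effect is None or (
                coef > effect.T_f_plus or coef < effect.T_f_minus
            )
            if not pass_eff:
                gating[factors.factor_names[fk]] = {"effect": False}
                continue
            perm = permutation_test(
                gene_idx, fk, expr, factors, cand.fit,
                n_permutations=config.n_permutations,
                rng_seed=int(ss.generate_state(1, dtype=np.uint32)[0] + si * design.n_factors + fk) % (2**31),
                mode=config.perm_mode,
                fraction_cutoff=config.perm_fraction_cutoff,
            )
            gating[factors.factor_names[fk]] = {
                "effect": True,
                "perm_fraction": perm.perm_fraction,
                "influential": perm.influential,
            }
            if perm.influential:
                h_final[fk] = 1 if coef > 0 else -1
        if not h_final.any():
            continue
        gated_profile = FactorProfile(
            tuple(zip(factors.factor_names, (int(v) for v in h_final)))
        )
        prov = dict(cand.provenance)
        prov["gating"] = gating
        reported.append(replace(cand, profile=gated_profile, provenance=prov))
    logger.info("gating retained %d of %d candidate sets", len(reported), len(candidate_sets))
    return reported, effect
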