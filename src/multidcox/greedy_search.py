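"""Untargeted greedy search for differentially co-expressed gene sets.

The search runs in four stages, per factor and per optimization direction:

1. *Seed discovery* — every gene pair whose fitted pair model shows at least
   one factor with |coefficient| > C_T and partial F-test p < 0.01 is a seed.
   Coefficients for all candidate pairs are obtained from one shared QR
   factorization; p-values are computed only for pairs surviving the
   coefficient-magnitude filter.  Genes with no significant partner are
   dropped from the expansion stage (they remain augmentation candidates).
2. *Expansion* (conservative set J) — starting from the top unused seed pair,
   genes are visited once in a seeded random order and accepted only if they
   strictly improve the target factor's coefficient in the chosen direction,
   so the acceptance bar rises as the set grows.
3. *Augmentation* (set L = J ∪ K) — the set centroid is paired with every
   gene in the data; a gene joins K when its centroid-pair factor profile
   under the relaxed thresholds T_ni equals the profile of J, recovering true
   members too weak to survive the strictly-improving expansion.
4. *Filtering* (final set R) — each gene is paired against the centroid of
   the rest of L; a gene is removed when that leave-one-out pair no longer
   clears the set's relaxed thresholds on the significant factors, i.e. it
   is a weak contributor riding the set's signal.

Seeds are processed in decreasing order of the target coefficient magnitude;
genes already absorbed into an identified multi-gene set block any remaining
seed containing them.  The whole search is deterministic given the master
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import (
    ThresholdSet,
    augmentation_threshold,
    calibrate_CT,
)
from .data_model import (
    ExpressionMatrix,
    FactorTable,
    build_strata,
    enumerate_pairs,
    variance_filter,
)
from .pair_statistics import (
    DCXFit,
    PairDesign,
    batch_fit_full,
    build_design,
    fit_model,
)

logger = logging.getLogger("multidcox")

P_CUT = 0.01  # seed/profile p-value cutoff

__all__ = [
    "FactorProfile",
    "DCXGeneSet",
    "SeedPairs",
    "SearchContext",
    "find_seed_pairs",
    "expand_seed",
    "augment_set",
    "filter_set",
    "run_search",
    "RunResult",
]


# ---------------------------------------------------------------------------
# profiles and result containers
# ---------------------------------------------------------------------------

def profile_codes(
    coefs: np.ndarray,
    pvals: np.ndarray,
    magnitudes: np.ndarray,
    p_cut: float = P_CUT,
) -> np.ndarray:
    """Signed significance calls h per factor.

    ``h = +1`` where coef > magnitude and p < p_cut, ``-1`` where
    coef < -magnitude and p < p_cut, ``0`` otherwise.  Works on a single
    coefficient vector or row-wise on a matrix.
    """
    coefs = np.asarray(coefs, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    sig = pvals < p_cut
    h = np.zeros(coefs.shape, dtype=np.int8)
    h[(coefs > magnitudes) & sig] = 1
    h[(coefs < -magnitudes) & sig] = -1
    return h


@dataclass(frozen=True)
class FactorProfile:
    """Ordered (factor name, h) entries with h in {-1, 0, +1}."""

    entries: tuple[tuple[str, int], ...]

    @classmethod
    def from_fit(cls, fit: DCXFit, C_T: float, p_cut: float = P_CUT) -> "FactorProfile":
        h = profile_codes(fit.coefficients, fit.pvalues, np.full(len(fit.coefficients), C_T), p_cut)
        return cls(tuple(zip(fit.factor_names, (int(v) for v in h))))

    @property
    def h(self) -> np.ndarray:
        return np.array([v for _, v in self.entries], dtype=np.int8)

    @property
    def factor_names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __str__(self) -> str:
        return ",".join(f"{n}:{v:+d}" if v else f"{n}:0" for n, v in self.entries)


@dataclass
class DCXGeneSet:
    """A discovered gene set with its fit, profile and search provenance."""

    genes: list[str]
    fit: DCXFit
    profile: FactorProfile
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# shared precomputation
# ---------------------------------------------------------------------------

@dataclass
class SearchContext:
    """Per-run cache: pairwise expression differences and candidate masks."""

    expr: ExpressionMatrix
    design: PairDesign
    diffs: np.ndarray  # genes x pairs matrix of E_im - E_in

    @classmethod
    def build(cls, expr: ExpressionMatrix, design: PairDesign) -> "SearchContext":
        d = expr.values[:, design.m_index] - expr.values[:, design.n_index]
        return cls(expr=expr, design=design, diffs=d)

    def fit_profile_diffs(self, pdiffs: np.ndarray, geneset=()) -> DCXFit:
        """Fit the model to the statistic of a centroid given its pair diffs."""
        return fit_model(pdiffs * pdiffs, self.design, geneset)


# ---------------------------------------------------------------------------
# stage 2: seed pairs
# ---------------------------------------------------------------------------

@dataclass
class SeedPairs:
    """Seed gene pairs with their factor coefficients and significance calls."""

    gene_i: np.ndarray  # (n,) row indices, gene_i < gene_j
    gene_j: np.ndarray
    coefficients: np.ndarray  # (n, z)
    pvalues: np.ndarray  # (n, z)
    significant: np.ndarray  # (n, z) bool: |coef| > C_T and p < P_CUT
    halves: tuple[np.ndarray, np.ndarray] | None = None  # split-half partition

    def __len__(self) -> int:
        return len(self.gene_i)

    def __iter__(self):
        for k in range(len(self)):
            yield int(self.gene_i[k]), int(self.gene_j[k]), DCXFit(
                coefficients=self.coefficients[k],
                intercept=np.nan,
                pvalues=self.pvalues[k],
                geneset=[int(self.gene_i[k]), int(self.gene_j[k])],
            )

    @property
    def seed_genes(self) -> np.ndarray:
        """Genes participating in at least one seed pair."""
        return np.unique(np.concatenate([self.gene_i, self.gene_j]))


def _pair_block_coefficients(
    diffs_i: np.ndarray,
    diffs_j: np.ndarray,
    design: PairDesign,
    column: int,
) -> np.ndarray:
    """Coefficients of design column ``column`` for every (i, j) gene pair.

    The pair statistic is ((d_i + d_j)/2)^2 = (d_i^2 + d_j^2 + 2 d_i d_j)/4,
    so each coefficient is a bilinear form in the per-gene difference rows —
    one matrix product per factor instead of one fit per pair.
    """
    w = design.solver[column]
    u_i = (diffs_i * diffs_i) @ w
    u_j = (diffs_j * diffs_j) @ w
    cross = (diffs_i * w) @ diffs_j.T
    return (u_i[:, None] + u_j[None, :] + 2.0 * cross) / 4.0


def find_seed_pairs(
    expr: ExpressionMatrix,
    design: PairDesign,
    thresholds: ThresholdSet,
    split_half: bool = False,
    rng_seed: int = 0,
    ctx: SearchContext | None = None,
    chunk: int = 65536,
) -> SeedPairs:
    """Exhaustive (or split-half) scan for significant seed gene pairs."""
    if ctx is None:
        ctx = SearchContext.build(expr, design)
    d = ctx.diffs
    G = expr.n_genes
    C_T = thresholds.C_T
    z = design.n_factors

    halves = None
    if split_half:
        rng = np.random.default_rng(rng_seed)
        perm = rng.permutation(G)
        half1, half2 = np.sort(perm[: G // 2]), np.sort(perm[G // 2:])
        halves = (half1, half2)
        rows, cols = half1, half2
    else:
        rows = cols = np.arange(G)

    mask = np.zeros((len(rows), len(cols)), dtype=bool)
    for k in range(1, z + 1):
        C = _pair_block_coefficients(d[rows], d[cols], design, k)
        mask |= np.abs(C) > C_T
    if not split_half:
        mask &= np.triu(np.ones((G, G), dtype=bool), k=1)

    ii, jj = np.nonzero(mask)
    gi, gj = rows[ii], cols[jj]
    lo, hi = np.minimum(gi, gj), np.maximum(gi, gj)
    order = np.lexsort((hi, lo))
    lo, hi = lo[order], hi[order]

    keep_i, keep_j, keep_c, keep_p, keep_s = [], [], [], [], []
    for start in range(0, len(lo), chunk):
        bi, bj = lo[start : start + chunk], hi[start : start + chunk]
        mid = 0.5 * (d[bi] + d[bj])
        coef, pvals, _ = batch_fit_full(mid * mid, design)
        sig = (np.abs(coef[:, 1:]) > C_T) & (pvals < P_CUT)
        rowsel = sig.any(axis=1)
        keep_i.append(bi[rowsel])
        keep_j.append(bj[rowsel])
        keep_c.append(coef[rowsel, 1:])
        keep_p.append(pvals[rowsel])
        keep_s.append(sig[rowsel])

    if keep_i:
        seeds = SeedPairs(
            gene_i=np.concatenate(keep_i),
            gene_j=np.concatenate(keep_j),
            coefficients=np.concatenate(keep_c) if keep_c else np.empty((0, z)),
            pvalues=np.concatenate(keep_p) if keep_p else np.empty((0, z)),
            significant=np.concatenate(keep_s) if keep_s else np.empty((0, z), bool),
            halves=halves,
        )
    else:  # pragma: no cover - empty scan
        seeds = SeedPairs(
            np.empty(0, np.intp), np.empty(0, np.intp),
            np.empty((0, z)), np.empty((0, z)), np.empty((0, z), bool), halves,
        )
    logger.info("seed scan: %d significant gene pairs", len(seeds))
    return seeds


# ---------------------------------------------------------------------------
# stage 3.A: expansion
# ---------------------------------------------------------------------------

def expand_seed(
    seed: tuple[int, int],
    factor: int,
    direction: int,
    expr: ExpressionMatrix,
    design: PairDesign,
    gene_order_seed: int = 0,
    candidates: np.ndarray | None = None,
    ctx: SearchContext | None = None,
) -> tuple[list[int], DCXFit, list[float]]:
    """Grow a seed pair into the conservative set J.

    Genes are visited once in a seeded random order; a gene is accepted iff it
    strictly moves the target factor's coefficient in ``direction`` (+1
    maximize, -1 minimize), so the trajectory of accepted coefficients is
    strictly monotone.  Returns (J, fit of J, coefficient trajectory).
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    if ctx is None:
        ctx = SearchContext.build(expr, design)
    d = ctx.diffs
    col = factor + 1  # design column (0 is the intercept)
    w = design.solver[col]

    J = [int(seed[0]), int(seed[1])]
    if candidates is None:
        candidates = np.arange(expr.n_genes)
    cand = candidates[~np.isin(candidates, J)]
    rng = np.random.default_rng(gene_order_seed)
    order = cand[rng.permutation(len(cand))]

    sum_d = d[J[0]] + d[J[1]]
    size = 2
    mid = sum_d / size
    current = float((mid * mid) @ w)
    trajectory = [current]

    pos = 0
    while pos < len(order):
        rest = order[pos:]
        centro = (sum_d[None, :] + d[rest]) / (size + 1)
        coefs = (centro * centro) @ w
        improving = (coefs - current) * direction > 0
        hits = np.nonzero(improving)[0]
        if hits.size == 0:
            break
        t = int(hits[0])
        g = int(rest[t])
        J.append(g)
        sum_d = sum_d + d[g]
        size += 1
        current = float(coefs[t])
        trajectory.append(current)
        pos += t + 1

    fit = ctx.fit_profile_diffs(sum_d / size, geneset=J)
    return J, fit, trajectory


# ---------------------------------------------------------------------------
# stage 3.B: augmentation
# ---------------------------------------------------------------------------

def augment_set(
    J: list[int],
    fit_J: DCXFit,
    thresholds: ThresholdSet,
    alpha: float,
    expr: ExpressionMatrix,
    design: PairDesign,
    candidates: np.ndarray | None = None,
    ctx: SearchContext | None = None,
) -> tuple[list[int], DCXFit, list[int]]:
    """Augment J with genes whose centroid-pair profile matches FP(J, T_oi).

    Every candidate gene is paired with the centroid of J; the pair model is
    fitted and its profile evaluated under the relaxed per-factor thresholds
    T_ni.  Genes whose profile equals that of J join the set.
    Returns (L, fit of L, K).
    """
    if ctx is None:
        ctx = SearchContext.build(expr, design)
    d = ctx.diffs
    C_T = thresholds.C_T

    fp_J = FactorProfile.from_fit(fit_J, C_T)
    h = fp_J.h
    t_ni_mag = np.array(
        [
            abs(
                augmentation_threshold(
                    C_T * (1 if hi >= 0 else -1), fit_J.coefficients[i], alpha, int(hi)
                )
            )
            for i, hi in enumerate(h)
        ]
    )

    if candidates is None:
        candidates = np.arange(expr.n_genes)
    cent_d = d[np.asarray(J, dtype=np.intp)].mean(axis=0)
    mid = 0.5 * (d[candidates] + cent_d[None, :])
    coef, pvals, _ = batch_fit_full(mid * mid, design)
    cand_h = profile_codes(coef[:, 1:], pvals, t_ni_mag)
    match = (cand_h == h[None, :]).all(axis=1)
    K = [int(g) for g in candidates[match] if int(g) not in set(J)]
    L = list(J) + K
    sum_d = d[np.asarray(L, dtype=np.intp)].sum(axis=0)
    fit_L = ctx.fit_profile_diffs(sum_d / len(L), geneset=L)
    return L, fit_L, K


# ---------------------------------------------------------------------------
# stage 3.C: leave-one-out filtering
# ---------------------------------------------------------------------------

def filter_set(
    L: list[int],
    fit_L: DCXFit,
    expr: ExpressionMatrix,
    design: PairDesign,
    thresholds: ThresholdSet | None = None,
    alpha: float = 0.5,
    ctx: SearchContext | None = None,
) -> tuple[list[int], DCXFit, dict]:
    """Remove weak contributors: genes whose leave-one-out centroid pair no
    longer clears the set's relaxed thresholds.

    Gene g is paired with the centroid of L - {g}.  A genuine member rides
    the set's shared signal, so the pair's coefficients stay near the full
    set's; a spurious member carries only half the signal in the pair and
    its coefficients collapse.  g is removed iff |F_i(Q_g)| < |T_ni(L)| on
    *every* significant factor of L's profile — the same admission bar the
    augmentation stage uses, applied leave-one-out.  (Comparing against the
    full-set coefficient |F_i(L)| itself is mis-centred: member pair fits
    fluctuate symmetrically around it, so that bar strips a random half of
    an uncontaminated set; both orientations of that variant are evaluated
    and disagreements logged.)  The set is never filtered below 2 genes.
    """
    if ctx is None:
        ctx = SearchContext.build(expr, design)
    d = ctx.diffs
    info: dict = {}
    C_T = thresholds.C_T if thresholds is not None else 0.0
    fp_L = FactorProfile.from_fit(fit_L, C_T)
    sig = np.abs(fp_L.h) == 1
    if len(L) <= 2 or not sig.any():
        if len(L) <= 2:
            logger.warning("filter: set of size %d left untouched", len(L))
        info["removed"] = []
        info["printed_rule_differs"] = False
        return list(L), fit_L, info

    Lidx = np.asarray(L, dtype=np.intp)
    sum_d = d[Lidx].sum(axis=0)
    loo_cent = (sum_d[None, :] - d[Lidx]) / (len(L) - 1)  # centroid of L - {g}
    mid = 0.5 * (d[Lidx] + loo_cent)
    coef, pvals, _ = batch_fit_full(mid * mid, design)
    q_abs = np.abs(coef[:, 1:])
    l_abs = np.abs(fit_L.coefficients)
    bar = np.array(
        [
            abs(
                augmentation_threshold(
                    C_T * (1 if h >= 0 else -1),
                    fit_L.coefficients[i],
                    alpha,
                    int(h),
                )
            )
            for i, h in enumerate(fp_L.h)
        ]
    )

    remove = (q_abs[:, sig] < bar[None, sig]).all(axis=1)
    remove_printed = (q_abs[:, sig] > l_abs[None, sig]).all(axis=1)
    if (~remove).sum() < 2:
        # degenerate: keep the 2 strongest genes
        margin = (q_abs[:, sig] - bar[None, sig]).min(axis=1)
        keep_order = np.lexsort((Lidx, -margin))
        keep_mask = np.zeros(len(L), dtype=bool)
        keep_mask[keep_order[:2]] = True
        remove = ~keep_mask
        logger.warning("filter: removal rule would empty the set; retaining 2 genes")

    R = [int(g) for g, rm in zip(L, remove) if not rm]
    info["removed"] = [int(g) for g, rm in zip(L, remove) if rm]
    info["printed_rule_differs"] = bool((remove_printed != remove).any())
    if info["printed_rule_differs"]:
        logger.debug(
            "filter: printed full-set-coefficient rule disagrees on %d genes",
            int((remove_printed != remove).sum()),
        )
    sum_r = d[np.asarray(R, dtype=np.intp)].sum(axis=0)
    fit_R = ctx.fit_profile_diffs(sum_r / len(R), geneset=R)
    return R, fit_R, info


# ---------------------------------------------------------------------------
# stage orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Everything a search run produces."""

    reported: list[DCXGeneSet]
    candidates: list[DCXGeneSet]
    thresholds: ThresholdSet
    effect_thresholds: object | None
    metadata: dict


def run_search(expr: ExpressionMatrix, factors: FactorTable, config) -> RunResult:
    """Full pipeline: filter, stratify, calibrate, search, gate.

    ``config`` is a :class:`multidcox.cli_io.RunConfig` (or any object with
    the same attributes).  All randomness derives from ``config.rng_seed``.
    """
    if config is None:
        from .cli_io import RunConfig

        config = RunConfig()

    ss = np.random.SeedSequence(config.rng_seed)
    sub = ss.generate_state(5, dtype=np.uint32)
    pair_seed, cal_seed, split_seed, order_seed0, perm_seed = (int(x) % (2**31) for x in sub)

    expr_f = variance_filter(expr, config.variance_quantile)
    factors = factors.reordered(expr_f.sample_ids)
    strata = build_strata(factors)
    pairs = enumerate_pairs(strata, config.max_pairs, pair_seed)
    design = build_design(factors, pairs)
    ctx = SearchContext.build(expr_f, design)

    thresholds = calibrate_CT(
        expr_f, design, config.n_random_pairs, config.m, cal_seed
    )
    logger.info("calibrated C_T = %.5g", thresholds.C_T)

    seeds = find_seed_pairs(
        expr_f, design, thresholds, split_half=config.split_half,
        rng_seed=split_seed, ctx=ctx,
    )

    seed_genes = seeds.seed_genes
    all_genes = np.arange(expr_f.n_genes)

    gene_ids = expr_f.gene_ids
    identified: set[int] = set()
    candidates: list[DCXGeneSet] = []
    run_counter = 0

    for fk in range(design.n_factors):
        for direction in (1, -1):
            elig = np.nonzero(
                seeds.significant[:, fk]
                & (np.sign(seeds.coefficients[:, fk]) == direction)
            )[0]
            if elig.size == 0:
                continue
            # largest |coefficient| first, ties by lexicographic gene ids
            keys = [
                (-abs(seeds.coefficients[s, fk]),
                 gene_ids[seeds.gene_i[s]], gene_ids[seeds.gene_j[s]])
                for s in elig
            ]
            ordered = [s for _, s in sorted(zip(keys, elig))]
            for s in ordered:
                gi, gj = int(seeds.gene_i[s]), int(seeds.gene_j[s])
                if gi in identified or gj in identified:
                    continue
                if config.exclusive_genes and identified:
                    free = np.fromiter(
                        (g not in identified for g in all_genes), bool, len(all_genes)
                    )
                    expansion_candidates = seed_genes[free[seed_genes]]
                    augment_candidates = (
                        all_genes[free]
                        if config.readmit_dropped_genes
                        else expansion_candidates
                    )
                else:
                    expansion_candidates = seed_genes
                    augment_candidates = (
                        all_genes if config.readmit_dropped_genes else seed_genes
                    )
                J, fit_J, trajectory = expand_seed(
                    (gi, gj), fk, direction, expr_f, design,
                    gene_order_seed=(order_seed0 + run_counter) % (2**31),
                    candidates=expansion_candidates, ctx=ctx,
                )
                L, fit_L, K = augment_set(
                    J, fit_J, thresholds, config.alpha, expr_f, design,
                    candidates=augment_candidates, ctx=ctx,
                )
                R, fit_R, filt_info = filter_set(
                    L, fit_L, expr_f, design, thresholds=thresholds,
                    alpha=config.alpha, ctx=ctx,
                )
                run_counter += 1
                profile = FactorProfile.from_fit(fit_R, thresholds.C_T)
                candidates.append(
                    DCXGeneSet(
                        genes=[gene_ids[g] for g in R],
                        fit=fit_R,
                        profile=profile,
                        provenance={
                            "seed": (gene_ids[gi], gene_ids[gj]),
                            "factor": factors.factor_names[fk],
                            "direction": direction,
                            "sizes": {"J": len(J), "L": len(L), "R": len(R)},
                            "trajectory": trajectory,
                            "filter": filt_info,
                            "gene_indices": R,
                        },
                    )
                )
                if len(R) >= 3:  # a multi-gene set claims its genes
                    identified.update(R)

    logger.info("search produced %d candidate sets", len(candidates))

    from .significance import gate_sets  # deferred: significance is downstream

    reported, eff = gate_sets(
        candidates, expr_f, factors, design, config, rng_seed=perm_seed, ctx=ctx
    )

    metadata = {
        "n_genes_input": expr.n_genes,
        "n_genes_analyzed": expr_f.n_genes,
        "n_samples": expr_f.n_samples,
        "n_strata": len(strata),
        "n_pairs": design.n_pairs,
        "C_T": thresholds.C_T,
        "n_seeds": len(seeds),
        "n_candidates": len(candidates),
        "intercept_included": True,
        "config": config.to_dict() if hasattr(config, "to_dict") else dict(vars(config)),
    }
    return RunResult(reported, candidates, thresholds, eff, metadata)
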