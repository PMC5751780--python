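"""Synthetic expression data with planted differentially co-expressed sets.

The generator emulates a multi-factor microarray study: two binary factors
``B1, B2`` (coded -1/+1) and one three-level ordinal factor ``B3``
(-1/0/+1) define 2·2·3 = 12 strata with a fixed number of samples each.
Expression of gene i in sample m is a sum of condition-gated shared signals
plus independent Gaussian noise:

    E_im = B1_im + B2_im + B3_im + O_im + e_im ,   e_im ~ N(0, sigma^2).

A planted set's genes all receive the *same* per-sample N(0, 1) draw in the
samples that meet the set's condition and 0 elsewhere — shared signal is what
co-expression means here.  The default truth plants three disjoint
20-gene sets:

* ``set1`` — co-expressed only in samples with B1 = -1 (expected profile:
  B1 negative, B2 and B3 null);
* ``set2`` — co-expressed only where B1 = +1 and B2 = +1 (expected profile:
  B1 and B2 positive, B3 null);
* ``control_always`` — co-expressed across *all* samples (O_im = O_m); a
  correct analysis must not report it, because its signal loads on the
  model intercept, not on any factor.

All remaining genes are exchangeable pure noise.  B3 drives no planted set
and serves as a null factor.  ``score_result`` compares any search output
against the truth (Jaccard matching) and yields FDR, FNR, per-set
identification and profile failure indicators, and the count of reported
sets matching no planted set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, FactorTable

logger = logging.getLogger("multidcox")

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "score_result",
    "run_benchmark",
]


@dataclass
class SimulationConfig:
    """Design of one synthetic dataset."""

    n_genes: int = 5000
    samples_per_stratum: int = 10
    sigma: float = 0.2
    set_size: int = 20
    rng_seed: int = 0
    balanced: bool = True  # equal samples per stratum; False draws labels uniformly

    def __post_init__(self) -> None:
        if self.set_size < 0:
            raise ValueError("set_size must be nonnegative (0 plants nothing)")
        if self.set_size and self.n_genes < 3 * self.set_size:
            raise ValueError("n_genes must accommodate the three planted sets")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class SimulationTruth:
    """Planted gene sets and their expected signed factor profiles."""

    set1: list[str]  # co-expressed at B1 = -1
    set2: list[str]  # co-expressed at B1 = +1 and B2 = +1
    control_always: list[str]  # co-expressed in every sample
    expected_profiles: dict = field(default_factory=dict)

    def planted(self) -> dict[str, set[str]]:
        return {"set1": set(self.set1), "set2": set(self.set2)}


def _factor_table(config: SimulationConfig, rng: np.random.Generator) -> FactorTable:
    levels = list(itertools.product((-1, 1), (-1, 1), (-1, 0, 1)))
    spp = config.samples_per_stratum
    if config.balanced:
        rows = np.array([vec for vec in levels for _ in range(spp)], dtype=int)
    else:
        n = len(levels) * spp
        rows = np.column_stack(
            [
                rng.choice((-1, 1), size=n),
                rng.choice((-1, 1), size=n),
                rng.choice((-1, 0, 1), size=n),
            ]
        )
    sample_ids = [f"S{i:03d}" for i in range(rows.shape[0])]
    return FactorTable(sample_ids, ["B1", "B2", "B3"], rows)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, FactorTable, SimulationTruth]:
    """Generate one dataset with the planted truth described above."""
    rng = np.random.default_rng(config.rng_seed)
    factors = _factor_table(config, rng)
    n_samples = factors.n_samples
    B = factors.values

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    placement = rng.permutation(config.n_genes)
    ss = config.set_size
    idx1 = np.sort(placement[:ss])
    idx2 = np.sort(placement[ss : 2 * ss])
    idxc = np.sort(placement[2 * ss : 3 * ss])

    s1 = rng.normal(size=n_samples)  # shared signal for set1's condition
    s2 = rng.normal(size=n_samples)
    o = rng.normal(size=n_samples)  # always-on control signal O_m

    E = np.zeros((config.n_genes, n_samples))
    cond1 = B[:, 0] == -1
    cond2 = (B[:, 0] == 1) & (B[:, 1] == 1)
    E[np.ix_(idx1, np.nonzero(cond1)[0])] += s1[cond1]
    E[np.ix_(idx2, np.nonzero(cond2)[0])] += s2[cond2]
    E[idxc] += o
    if config.sigma > 0:
        E += rng.normal(scale=config.sigma, size=E.shape)

    truth = SimulationTruth(
        set1=[gene_ids[i] for i in idx1],
        set2=[gene_ids[i] for i in idx2],
        control_always=[gene_ids[i] for i in idxc],
        expected_profiles={
            "set1": {"B1": -1, "B2": 0, "B3": 0},
            "set2": {"B1": 1, "B2": 1, "B3": 0},
        },
    )
    expr = ExpressionMatrix(E, gene_ids, list(factors.sample_ids))
    return expr, factors, truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def score_result(
    found_sets,
    truth: SimulationTruth,
    match_threshold: float = 0.5,
) -> dict:
    """Score a search result against the planted truth.

    A planted set is *identified* when some found set matches it at Jaccard
    >= ``match_threshold``; each planted set claims its best-matching found
    set.  FNR is the fraction of planted genes missing from the match (1.0
    when unidentified); FDR is the fraction of reported genes, over matched
    sets, that are not planted in the corresponding truth set; a *profile
    failure* is a matched set whose gated signed profile differs from the
    expected one; every found set matching neither planted set (including
    any matching the always-co-expressed control) counts as a false set.
    """
    planted = truth.planted()
    found = [(set(s.genes), s) for s in found_sets]
    out: dict = {"n_found": len(found)}

    matched_found: dict[int, str] = {}
    reported_genes = 0
    false_genes = 0
    fnrs = []
    for name, genes in planted.items():
        jac = [ _jaccard(genes, fg) for fg, _ in found ]
        best = int(np.argmax(jac)) if jac else -1
        best_j = jac[best] if jac else 0.0
        identified = best_j >= match_threshold
        out[f"{name}_identified"] = bool(identified)
        out[f"{name}_jaccard"] = float(best_j)
        if identified:
            fg, s = found[best]
            matched_found[best] = name
            miss = len(genes - fg)
            fnr = miss / len(genes)
            reported_genes += len(fg)
            false_genes += len(fg - genes)
            expected = truth.expected_profiles[name]
            got = dict(s.profile.entries)
            out[f"{name}_profile_ok"] = all(
                got.get(f, 0) == h for f, h in expected.items()
            )
        else:
            fnr = 1.0
            out[f"{name}_profile_ok"] = False
        fnrs.append(fnr)
        out[f"{name}_fnr"] = float(fnr)

    out["fnr"] = float(np.mean(fnrs))
    out["fdr"] = float(false_genes / reported_genes) if reported_genes else 0.0

    control = set(truth.control_always)
    n_false_sets = 0
    control_reported = False
    for k, (fg, _) in enumerate(found):
        if k in matched_found:
            continue
        n_false_sets += 1
        if _jaccard(control, fg) >= match_threshold:
            control_reported = True
    out["n_false_sets"] = n_false_sets
    out["fpr_sets"] = float(n_false_sets / len(found)) if found else 0.0
    out["control_reported"] = control_reported
    out["geneset_failure"] = float(
        np.mean([not out[f"{n}_identified"] for n in planted])
    )
    out["profile_failure"] = float(
        np.mean(
            [
                out[f"{n}_identified"] and not out[f"{n}_profile_ok"]
                for n in planted
            ]
        )
    )
    return out


# ---------------------------------------------------------------------------
# benchmark grid
# ---------------------------------------------------------------------------

def run_benchmark(
    sigmas=(0.2, 0.5, 0.8),
    samples_per_stratum=(10,),
    replicates: int = 10,
    base_seed: int = 0,
    n_genes: int = 5000,
    run_config=None,
    match_threshold: float = 0.5,
) -> pd.DataFrame:
    """Simulate → search → gate → score over a grid, one row per metric.

    Returns a tidy table with columns sigma, samples_per_stratum, replicate,
    metric, value.  Fully deterministic given ``base_seed``.
    """
    from .greedy_search import run_search

    if run_config is None:
        from .cli_io import RunConfig

        run_config = RunConfig()

    rows = []
    cell = 0
    for sigma in sigmas:
        for spp in samples_per_stratum:
            for rep in range(replicates):
                seed = int(
                    np.random.SeedSequence([base_seed, cell]).generate_state(
                        1, dtype=np.uint32
                    )[0]
                ) % (2**31)
                cell += 1
                sim_cfg = SimulationConfig(
                    n_genes=n_genes,
                    samples_per_stratum=spp,
                    sigma=sigma,
                    rng_seed=seed,
                )
                expr, factors, truth = simulate_dataset(sim_cfg)
                cfg = run_config.with_seed(seed + 1) if hasattr(
                    run_config, "with_seed"
                ) else run_config
                result = run_search(expr, factors, cfg)
                metrics = score_result(result.reported, truth, match_threshold)
                for metric, value in metrics.items():
                    rows.append(
                        {
                            "sigma": sigma,
                            "samples_per_stratum": spp,
                            "replicate": rep,
                            "metric": metric,
                            "value": float(value),
                        }
                    )
    return pd.DataFrame(rows)
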