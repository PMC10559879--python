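"""Validation studies: oracle batteries, null calibration, recovery.

Each function recomputes a verifiable property of the pipeline from
scratch — comparing the statistical primitives against independent oracles
(definitional Benjamini-Hochberg, a numerically integrated t density,
exhaustive hypergeometric enumeration), checking the noise-free
measurement model inverts analytically, measuring false-discovery control
and parameter recovery on simulated data, and checking byte-level
reproducibility of the full pipeline.  The test suite and the acceptance
script both run these.
"""

from __future__ import annotations

import math
import os
import numpy as np
import pandas as pd
from scipy import integrate, stats

from .differential import (
    benjamini_hochberg,
    compute_fold_changes,
    invert_overall_oxidation,
    normalize_site_to_protein,
    test_differential,
)
from .model import FoldChangeMatrix
from .pipeline import differential_stage, run_pipeline
from .quantification import correct_impurities, rollup_sites
from .enrichment import enrich, hypergeom_upper_tail, map_to_genes
from .simulate import SimulationConfig, simulate, truth_report

MAX_SEED = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, MAX_SEED, size=n)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bh_definitional(p: np.ndarray) -> np.ndarray:
    """O(m^2) Benjamini-Hochberg straight from the definition.

    adjusted(p_i) = min over candidate thresholds t >= p_i of
    m * t / #{p_j <= t}, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    out = np.empty(m)
    for i in range(m):
        candidates = [
            m * t / np.sum(p <= t) for t in p if t >= p[i]
        ]
        out[i] = min(1.0, min(candidates))
    return out


def t_sf_integrated(t_value: float, df: int) -> float:
    """Two-sided t p-value by numerical integration of the density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(x: float) -> float:
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2)

    upper, _ = integrate.quad(density, abs(t_value), np.inf, epsabs=1e-13, epsrel=1e-13)
    return 2.0 * upper


def hypergeom_enumerated(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) by exhaustive enumeration with exact integers."""
    total = math.comb(N, n)
    acc = 0
    for x in range(max(k, 0), min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def bh_oracle_battery(seed: int, n_cases: int = 10000, max_len: int = 12) -> float:
    """Max |implementation - definitional BH| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for case in range(n_cases):
        m = int(rng.integers(1, max_len + 1))
        p = rng.random(m)
        if case % 7 == 0 and m > 1:  # exercise ties
            p[rng.integers(0, m)] = p[rng.integers(0, m)]
        diff = np.abs(benjamini_hochberg(p) - bh_definitional(p))
        worst = max(worst, float(diff.max()))
    return worst


def ttest_oracle_battery(seed: int, cases_per_n: int = 40) -> float:
    """Max |pipeline t-test p - numerically integrated t CDF| for n=3..12.

    The pipeline path under test is :func:`test_differential` on a
    replicate fold-change matrix; the oracle integrates the t density.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in range(3, 13):
        data = rng.normal(0.1, 1.0, size=(cases_per_n, n))
        cols = pd.MultiIndex.from_tuples(
            [(1, i + 1) for i in range(n)], names=["run", "replicate"]
        )
        fc = FoldChangeMatrix(
            layer="proteome",
            timepoint="4h",
            values=pd.DataFrame(
                data, index=[f"E{i}" for i in range(cases_per_n)], columns=cols
            ),
        )
        res = test_differential(fc)
        for t_value, p_value in zip(res["t_stat"], res["p"]):
            oracle = t_sf_integrated(float(t_value), n - 1)
            worst = max(worst, abs(float(p_value) - oracle))
    return worst


def hypergeom_oracle_battery(seed: int, n_cases: int = 2000) -> float:
    """Max |hypergeometric tail - exhaustive enumeration| for N <= 12."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        N = int(rng.integers(1, 13))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        if K == 0:
            continue
        got = hypergeom_upper_tail(k, K, n, N)
        worst = max(worst, abs(got - hypergeom_enumerated(k, K, n, N)))
    return worst


# ---------------------------------------------------------------------------
# noise-free measurement-model inversion
# ---------------------------------------------------------------------------

_NOISE_FREE = dict(
    noise_sd=0.0,
    missing_rate=0.0,
    multi_cys_fraction=0.0,
    n_proteins=80,
    cys_sites_per_protein=1.5,
)


def measurement_inversion_check(seed: int) -> dict[str, float]:
    """Noise off: simulate -> correct -> rollup -> FC -> invert must equal
    the analytic value implied by the generator's oxidized fractions, and
    PTM-to-protein normalization must cancel pure abundance effects
    exactly.
    """
    # oxidation effects only: every replicate fold change is the analytic one
    config = SimulationConfig(
        seed=seed,
        protein_effect_fraction=0.0,
        ox_effect_fraction=0.4,
        phospho_effect_fraction=0.0,
        **_NOISE_FREE,
    )
    exp = simulate(config)
    table = correct_impurities(exp.tables["redoxome"], exp.impurity)
    worst_ox = 0.0
    for layer in ("ox_all", "ox_rev"):
        q = rollup_sites(table, exp.design, layer)
        implied = exp.truth.implied[layer]
        for tp in config.timepoints:
            fc = compute_fold_changes(q, exp.design, tp)
            if layer == "ox_all":
                fc = invert_overall_oxidation(fc)
            dev = fc.values.sub(implied.reindex(fc.values.index), axis=0)
            worst_ox = max(worst_ox, float(dev.abs().max().max()))

    # abundance effects only: site fold changes normalize to exactly zero
    config2 = SimulationConfig(
        seed=seed + 1,
        protein_effect_fraction=0.5,
        ox_effect_fraction=0.0,
        phospho_effect_fraction=0.0,
        **_NOISE_FREE,
    )
    exp2 = simulate(config2)
    prot_q = rollup_sites(
        correct_impurities(exp2.tables["proteome"], exp2.impurity),
        exp2.design, "proteome",
    )
    worst_cancel = 0.0
    for layer, table_name in (("ox_rev", "redoxome"), ("phospho", "phospho")):
        q = rollup_sites(
            correct_impurities(exp2.tables[table_name], exp2.impurity),
            exp2.design, layer,
        )
        for tp in config2.timepoints:
            site_fc = compute_fold_changes(q, exp2.design, tp)
            protein_fc = compute_fold_changes(prot_q, exp2.design, tp)
            normalized = normalize_site_to_protein(site_fc, protein_fc)
            worst_cancel = max(
                worst_cancel, float(normalized.values.abs().max().max())
            )
    return {
        "ox_inversion_max_abs_dev": worst_ox,
        "abundance_cancellation_max_abs": worst_cancel,
    }


# ---------------------------------------------------------------------------
# stochastic studies
# ---------------------------------------------------------------------------

def null_calibration_study(
    seed: int, n_runs: int = 200, n_entities: int = 2000
) -> dict[str, float]:
    """Global-null simulations: realized FDP at FDR <= 0.05 and p-value
    uniformity (pooled Kolmogorov-Smirnov)."""
    seeds = _child_seeds(seed, n_runs)
    fdp = np.empty(n_runs)
    pooled: list[np.ndarray] = []
    for i, s in enumerate(seeds):
        config = SimulationConfig(
            seed=int(s),
            n_proteins=n_entities,
            layers=("proteome",),
            timepoints=("4h",),
            peptides_per_protein=1.0,
            protein_effect_fraction=0.0,
            ox_effect_fraction=0.0,
            phospho_effect_fraction=0.0,
            missing_rate=0.0,
            n_gene_sets=1,
        )
        exp = simulate(config)
        _, _, differential = differential_stage(
            exp.tables, exp.design, impurity=exp.impurity
        )
        res = differential[("proteome", "4h")]
        n_sig = int(res["significant"].sum())
        fdp[i] = 1.0 if n_sig else 0.0  # every discovery is false under the null
        pooled.append(res["p"].to_numpy())
    p_all = np.concatenate(pooled)
    p_all = p_all[~np.isnan(p_all)]
    ks = stats.kstest(p_all, "uniform")
    mean_fdp = float(fdp.mean())
    mc_se = float(fdp.std(ddof=1) / np.sqrt(n_runs))
    return {
        "mean_fdp": mean_fdp,
        "mc_se": mc_se,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_runs": n_runs,
        "n_entities": n_entities,
    }


def recovery_study(seed: int, n_runs: int = 5) -> pd.DataFrame:
    """Planted effects |delta| = 1 log2 at noise sd 0.2, 12 replicates:
    bias, RMSE, sensitivity and FDP per layer, pooled over runs.

    Uses single-cysteine peptides so a site's model-implied effect equals
    its planted delta on the ox_rev/phospho scales; the TMT1-derived
    ox_all readout intrinsically compresses a delta on the oxidized
    fraction to -log2((1 - f 2^delta) / (1 - f)) < delta, so its
    sensitivity is reported against that smaller realized effect.
    """
    seeds = _child_seeds(seed, n_runs)
    reports = []
    for s in seeds:
        config = SimulationConfig(
            seed=int(s),
            n_proteins=400,
            protein_effect_fraction=0.15,
            ox_effect_fraction=0.15,
            phospho_effect_fraction=0.15,
            effect_size=1.0,
            noise_sd=0.2,
            missing_rate=0.0,
            multi_cys_fraction=0.0,
        )
        exp = simulate(config)
        _, _, differential = differential_stage(
            exp.tables, exp.design, impurity=exp.impurity
        )
        per_layer = {}
        for (layer, tp), res in differential.items():
            per_layer.setdefault(layer, []).append(res)
        report = truth_report(
            exp.truth,
            {layer: pd.concat(parts, ignore_index=True)
             for layer, parts in per_layer.items()},
        )
        reports.append(report)
    pooled = pd.concat(reports, ignore_index=True)
    agg = (
        pooled.groupby("layer")
        .agg(
            bias=("bias", "mean"),
            rmse=("rmse", "mean"),
            sensitivity=("sensitivity", "mean"),
            fdp=("fdp", "mean"),
            n_entities=("n_entities", "sum"),
        )
        .reset_index()
    )
    return agg


def enrichment_recovery_study(seed: int, n_runs: int = 100) -> dict[str, float]:
    """Planted-pathway recovery: one gene set's members get protein-level
    effects with probability 0.9; the planted set must reach FDR <= 0.05
    while unplanted (null) sets stay controlled."""
    seeds = _child_seeds(seed, n_runs)
    detected = np.zeros(n_runs)
    fdp = np.zeros(n_runs)
    for i, s in enumerate(seeds):
        config = SimulationConfig(
            seed=int(s),
            n_proteins=400,
            layers=("proteome",),
            timepoints=("4h",),
            peptides_per_protein=1.0,
            protein_effect_fraction=0.05,
            ox_effect_fraction=0.0,
            phospho_effect_fraction=0.0,
            n_gene_sets=50,
            gene_set_size=20,
            planted_set_effect_prob=0.9,
            missing_rate=0.0,
        )
        exp = simulate(config)
        _, _, differential = differential_stage(
            exp.tables, exp.design, impurity=exp.impurity
        )
        res = differential[("proteome", "4h")]
        universe = map_to_genes(res["entity"], exp.mapping)
        sig = map_to_genes(res.loc[res["significant"], "entity"], exp.mapping)
        enr = enrich(sig, universe, exp.gene_sets)
        flagged = enr.loc[enr["significant"], "set_name"]
        detected[i] = float(exp.truth.planted_set in set(flagged))
        n_flagged = len(flagged)
        n_false = int((flagged != exp.truth.planted_set).sum())
        fdp[i] = n_false / n_flagged if n_flagged else 0.0
    return {
        "detection_rate": float(detected.mean()),
        "mean_fdp": float(fdp.mean()),
        "fdp_mc_se": float(fdp.std(ddof=1) / np.sqrt(n_runs)),
        "n_runs": n_runs,
    }


def reproducibility_check(seed: int, work_dir: str) -> bool:
    """Same config + seed twice -> byte-identical result tables."""
    params = {
        "simulate": "true",
        "sim_n_proteins": "120",
        "sim_planted_set_effect_prob": "0.9",
    }
    digests = []
    for name in ("a", "b"):
        out = os.path.join(work_dir, name)
        result = run_pipeline(params, out, seed=seed)
        digests.append(result.manifest["outputs"])
    return digests[0] == digests[1]
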