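"""Simulation-based validation experiments at the study conditions.

Each function generates data with the :mod:`splicerank.simulate`
defaults (two conditions, three replicates each, junction depth 50 with
negative-binomial dispersion 0.1, basal PIR ~ Beta(2, 18)), runs the
corresponding analysis stage end to end, and reports summary metrics
against the generator's ground truth. The same functions back the
acceptance test suite and ``scripts/acceptance.py``; problem sizes are
chosen so each experiment runs in seconds on one core (2,000 introns for
the testing experiments, ~1,400 introns for the feature experiment,
500/500 genes for the expression-link experiment).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .events import build_ri_events
from .expression import gene_log2fc, mw_link_test
from .features import GenomeSequence, compute_features, ks_compare
from .pipeline import _groups
from .quantify import apply_coverage_filter, build_inclusion_table
from .rankprod import Contrast, analyze_contrast
from .simulate import (
    SimConfig,
    sample_sheet,
    simulate_annotation,
    simulate_counts,
    simulate_gene_counts,
)


def _ri_analysis(config: SimConfig, null_model: str, n_perm: int) -> tuple:
    """Simulate RI counts and run the full quantify+test path."""
    rng = np.random.default_rng(config.seed)
    sim = simulate_annotation(config, rng)
    events = build_ri_events(sim.models)
    counts, truth = simulate_counts(events, sim, config, rng)
    table = build_inclusion_table(counts, events)
    groups = _groups(sample_sheet(config))
    table = apply_coverage_filter(table, groups, min_coverage=10)
    contrast = Contrast(groups["A"], groups["B"])
    results = analyze_contrast(
        table[table["passed_filter"]],
        contrast,
        n_perm=n_perm,
        seed=config.seed,
        null_model=null_model,
    )
    return results, truth


def null_calibration(seed: int, n_genes: int = 1000, n_perm: int = 100) -> dict:
    """Type-I behavior of the exchangeability-exact (relabeling) null
    under a global null: 2,000 introns, ΔPIR = 0, 3 vs 3 replicates."""
    config = SimConfig(
        n_genes=n_genes,
        exons_per_gene=(3, 3),
        affected_fraction=0.0,
        delta_pir_effect=0.0,
        seed=seed,
    )
    results, _ = _ri_analysis(config, null_model="relabel", n_perm=n_perm)
    inc = results[results["direction"] == "increased"]
    p = inc["p"].to_numpy()
    n = p.size
    frac = float((p < 0.05).mean())
    half_width = 2.5758 * np.sqrt(0.05 * 0.95 / n)  # 99% binomial interval
    return {
        "n_events": int(n),
        "frac_p_lt_05": frac,
        "binom99_lo": 0.05 - float(half_width),
        "binom99_hi": 0.05 + float(half_width),
        "ks_uniform_p": float(kstest(p, "uniform").pvalue),
    }


def power_recovery(seed: int, n_genes: int = 1000, n_perm: int = 100) -> dict:
    """Sensitivity and empirical FDR of the default analysis with 10% of
    2,000 introns at true ΔPIR = +0.3, plus the direction asymmetry."""
    config = SimConfig(
        n_genes=n_genes,
        exons_per_gene=(3, 3),
        affected_fraction=0.1,
        delta_pir_effect=0.3,
        seed=seed,
    )
    results, truth = _ri_analysis(config, null_model="ranks", n_perm=n_perm)
    affected = set(truth.loc[truth["affected"], "event_id"])
    inc = results[results["direction"] == "increased"]
    dec = results[results["direction"] == "decreased"]
    inc_calls = set(inc.loc[inc["significant"], "event_id"])
    tested_affected = affected & set(inc["event_id"])
    tp = len(inc_calls & affected)
    fp = len(inc_calls - affected)
    return {
        "n_events": int(inc["event_id"].nunique()),
        "n_true_affected": len(tested_affected),
        "sensitivity": tp / len(tested_affected) if tested_affected else float("nan"),
        "empirical_fdr": fp / len(inc_calls) if inc_calls else 0.0,
        "n_increased_calls": len(inc_calls),
        "n_decreased_calls": int(dec["significant"].sum()),
    }


def feature_recovery(
    seed: int, n_retained: int = 200, n_background: int = 1000
) -> dict:
    """KS feature analysis on introns simulated with a +0.10 GC shift:
    where does GC content rank among all registry features?"""
    config = SimConfig(
        n_genes=330,
        exons_per_gene=(3, 8),
        gc_shift=0.10,
        affected_fraction=0.18,
        seed=seed,
    )
    sim = simulate_annotation(config)
    affected = sorted(sim.affected_introns)[:n_retained]
    background = sorted(set(sim.introns) - sim.affected_introns)[:n_background]
    if len(affected) < n_retained or len(background) < n_background:
        raise RuntimeError("simulation produced too few introns for the comparison")
    genome = GenomeSequence(sim.genome)
    ret_df = compute_features(affected, genome, sim.models)
    bg_df = compute_features(background, genome, sim.models)
    report = ks_compare(ret_df, bg_df)
    gc_row = report[report["feature"] == "intron_gc"].iloc[0]
    return {
        "n_retained": len(affected),
        "n_background": len(background),
        "top_feature": report.iloc[0]["feature"],
        "gc_rank": int(report.index[report["feature"] == "intron_gc"][0]) + 1,
        "gc_D": float(gc_row["D"]),
        "gc_p_adj": float(gc_row["p_adj"]),
        "gc_shift_sign": int(gc_row["shift_sign"]),
    }


def link_recovery(seed: int, n_ir: int = 500, n_background: int = 500) -> dict:
    """Mann-Whitney link test with an NMD coupling of -1 log2 unit on the
    IR genes (log2FC noise sd 1, 3 vs 3 replicates)."""
    config = SimConfig(nmd_coupling=1.0, expr_noise_sd=1.0, seed=seed)
    genes = [f"G{i:05d}" for i in range(n_ir + n_background)]
    ir_genes = genes[:n_ir]
    counts = simulate_gene_counts(genes, set(ir_genes), config)
    groups = _groups(sample_sheet(config))
    records = gene_log2fc(counts, groups["A"], groups["B"])
    res = mw_link_test(records, ir_genes, genes[n_ir:])
    return {
        "n_ir_genes": res.n_ir_genes,
        "n_background_genes": res.n_background_genes,
        "p": res.p,
        "median_shift": res.median_shift,
    }


def link_null_uniformity(
    seed: int, n_reps: int = 200, n_ir: int = 60, n_background: int = 60
) -> dict:
    """With zero NMD coupling the link-test p-value should be uniform
    over repeated simulations."""
    genes = [f"G{i:05d}" for i in range(n_ir + n_background)]
    ir_genes = genes[:n_ir]
    groups = None
    ps = []
    for rep in range(n_reps):
        config = SimConfig(nmd_coupling=0.0, expr_noise_sd=1.0, seed=seed + rep)
        counts = simulate_gene_counts(genes, set(ir_genes), config)
        if groups is None:
            groups = _groups(sample_sheet(config))
        records = gene_log2fc(counts, groups["A"], groups["B"])
        ps.append(mw_link_test(records, ir_genes, genes[n_ir:]).p)
    return {
        "n_reps": n_reps,
        "ks_uniform_p": float(kstest(np.asarray(ps), "uniform").pvalue),
    }
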