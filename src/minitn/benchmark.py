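"""Ground-truth recovery benchmarks on the synthetic experiment.

These runners freeze the package's benchmark conditions: a
well-separated 200-kb experiment (non-essential insertion density
0.05/bp, essential-region noise 5e-4/bp, read-count means 100 vs 3)
for classification recovery, a 60-kb experiment for threshold
calibration, and small expression studies for the CLR null and power
properties. Problem sizes were chosen for tight statistics at
desk-scale runtimes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .domains import score_all_domains
from .ncrna import classify_pairs, clr_matrix, essentiality_enrichment
from .scoring import EssentialityClassifier, GoldSet, calibrate_read_threshold, essential_landscape, select_timepoint
from .simulate import SimConfig, essential_mask, simulate_expression, simulate_genome, simulate_insertions


def gold_from_truth(truth, n_e: int = 37, n_ne: int = 29) -> GoldSet:
    """Gold sets sampled from the simulator's ground truth (sizes
    default to the classic 37 essential / 29 non-essential genes)."""
    orfs = truth.of_type("ORF")
    return GoldSet(
        list(orfs.loc[orfs["truth"] == "E", "id"][:n_e]),
        list(orfs.loc[orfs["truth"] == "NE", "id"][:n_ne]),
    )


def recovery_benchmark(seed: int) -> dict:
    """One full recovery run under the well-separated conditions.

    Returns ORF-level sensitivity (truth-E called E), specificity of
    the essential call (truth-NE not called E), the strict truth-NE ->
    NE rate, truth and recovered essential genome fractions, and the
    fraction of mixed-domain (truth-F) proteins flagged differential.
    """
    cfg = SimConfig(seed=seed)
    genome, truth = simulate_genome(cfg)
    tables = simulate_insertions(genome, truth, cfg)
    gold = gold_from_truth(truth)
    day, _ = select_timepoint(tables, gold, truth)
    clf = EssentialityClassifier(read_threshold="stringent").fit(
        tables[day], annotation=truth, gold=gold
    )
    landscape = essential_landscape(truth, tables[day], clf.model_)
    calls = landscape.calls
    orfs = truth.of_type("ORF").set_index("id")
    cats = calls.loc[orfs.index, "category"]
    is_e, is_ne = orfs["truth"] == "E", orfs["truth"] == "NE"
    dom = truth.domains.rename(columns={"truth": "source"})
    dom_calls = score_all_domains(truth, dom, clf.scorer_)
    f_ids = orfs.index[orfs["truth"] == "F"]
    diff = dom_calls.groupby("orf_id")["differential"].first()
    return {
        "n_orfs": len(orfs),
        "day": day,
        "relaxed": clf.calibration_.relaxed,
        "stringent": clf.calibration_.stringent,
        "n_sites": clf.model_.N,
        "sensitivity": float((cats[is_e] == "E").mean()),
        "specificity": float((cats[is_ne] != "E").mean()),
        "ne_recovered_ne": float((cats[is_ne] == "NE").mean()),
        "essential_fraction_called": landscape.essential_fraction,
        "essential_fraction_truth": float(essential_mask(cfg.genome_length, truth).mean()),
        "differential_rate": float(diff.loc[f_ids].mean()) if len(f_ids) else float("nan"),
    }


#: calibration benchmark conditions: smaller genome, undecayed first day
CALIBRATION_SIM = dict(genome_length=100_000, n_orfs=64, n_smorfs=4, n_ncrnas=8)


def calibration_benchmark(seed: int) -> tuple[int, int]:
    """Relaxed/stringent thresholds calibrated on the first (undecayed)
    day of a small simulated experiment."""
    cfg = SimConfig(seed=seed, **CALIBRATION_SIM)
    genome, truth = simulate_genome(cfg)
    tables = simulate_insertions(genome, truth, cfg)
    gold = gold_from_truth(truth, n_e=20, n_ne=20)
    day = min(tables)
    cal = calibrate_read_threshold(tables[day], gold, truth)
    return cal.relaxed, cal.stringent


#: CLR property-study conditions: 50 features x 10 timepoints
CLR_NULL_SIM = dict(
    genome_length=40_000, n_orfs=50, orf_len_range=(300, 600), n_smorfs=0,
    n_ncrnas=0, n_convrnas=0, plant_prob=0.0,
)
CLR_PLANTED_SIM = dict(
    genome_length=40_000, n_orfs=50, orf_len_range=(300, 600), n_smorfs=0,
    n_ncrnas=1, n_convrnas=0, frac_anticorrelated=1.0, expression_noise_sd=0.3,
)


def clr_null_fpr(seed: int, threshold: float = 2.5) -> float:
    """Fraction of independent-feature pairs exceeding the CLR
    threshold (one null expression study)."""
    cfg = SimConfig(seed=seed, **CLR_NULL_SIM)
    _, truth = simulate_genome(cfg)
    expr, planted = simulate_expression(truth, cfg)
    assert len(planted) == 0
    net = clr_matrix(expr, threshold=threshold)
    iu = np.triu_indices(len(expr), k=1)
    return float((net.clr_[iu] > threshold).mean())


def clr_planted_detected(seed: int, threshold: float = 2.5) -> bool:
    """Is one planted anti-correlated antisense pair (r ~ -0.9 after
    noise) recovered as a significant anti-correlation?"""
    cfg = SimConfig(seed=seed, **CLR_PLANTED_SIM)
    _, truth = simulate_genome(cfg)
    expr, planted = simulate_expression(truth, cfg)
    anti = planted[planted["sign"] == "anti"]
    if not len(anti):
        return False
    net = clr_matrix(expr, threshold=threshold)
    signed = classify_pairs(net, anti[["ncrna", "orf"]])
    return bool((signed["sign"] == "anti-correlated").all())


#: enrichment power-study conditions (pre-study power analysis:
#: ~5.7 partners per sign over 140 ncRNAs gives Welch t ~ 5)
ENRICHMENT_SIM = dict(
    genome_length=1_800_000, n_orfs=2600, orf_len_range=(300, 600),
    n_smorfs=0, n_ncrnas=140, frac_fitness=0.0, partners_per_ncrna=13,
    p_essential_anti=0.5, p_essential_corr=0.37,
)


def enrichment_benchmark(seed: int) -> float:
    """Welch p-value for essential-partner enrichment of
    anti-correlated ncRNA partners in one planted expression study."""
    cfg = SimConfig(seed=seed, **ENRICHMENT_SIM)
    _, truth = simulate_genome(cfg)
    expr, planted = simulate_expression(truth, cfg)
    net = clr_matrix(expr)
    signed = classify_pairs(net, planted[["ncrna", "orf"]])
    orfs = truth.of_type("ORF").set_index("id")
    calls = pd.DataFrame(
        {"category": np.where(orfs["truth"] == "E", "E", "NE")}, index=orfs.index
    )
    res, _ = essentiality_enrichment(signed, calls)
    return res.pvalue
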