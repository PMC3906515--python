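"""Property benchmarks on synthetic data with known ground truth.

These functions regenerate experiments at the default study conditions and
measure how well each pipeline stage recovers the simulator's truth: the
cold-jet removal rate, selection sensitivity and contamination-filter
specificity, the flatness of normalized null M values, and the null calling
rate of the mean ± 2·SD rule.  They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .arrays import DESIGN_CC_VS_CCCJ, DESIGN_CCCJ_VS_AACJ, MASet, ma_transform
from .evaluate import estimate_removal
from .normalize import decile_means, normalize_array
from .select import (
    DIR_UP,
    collapse_probes,
    compute_thresholds,
    intersect_replicates,
    select_by_threshold,
    select_regulated,
)
from .simulate import (
    LABEL_ASTRO_DOWN,
    LABEL_ASTRO_UP,
    LABEL_NEURON,
    LABEL_NULL,
    SimulationConfig,
    simulate_experiment,
)


def _normalized(experiment):
    norm, fits = [], {}
    for scan in experiment.scans:
        n, f = normalize_array(ma_transform(scan))
        norm.append(n)
        fits[scan.array_id] = f
    return norm, fits


def removal_recovery(r_values=(0.5, 0.7, 0.9, 0.99), n_seeds: int = 10,
                     seed: int = 0, contamination_c: float = 0.4) -> dict:
    """Seed-averaged removal estimates across a grid of true removal rates."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    out = {}
    for r in r_values:
        estimates = []
        for s in seeds:
            cfg = SimulationConfig(removal_r=r, contamination_c=contamination_c,
                                   seed=int(s))
            exp = simulate_experiment(cfg)
            norm, fits = _normalized(exp)
            dep = tuple(ma for ma in norm if ma.design == DESIGN_CC_VS_CCCJ)
            estimates.append(estimate_removal(exp.scans, dep,
                                              trend_fits=fits).removal_percent)
        out[r] = {"mean_estimate": float(np.mean(estimates)),
                  "sd": float(np.std(estimates)),
                  "target": 100.0 * r,
                  "abs_error": float(abs(np.mean(estimates) - 100.0 * r))}
    return out


def selection_truth_audit(seed: int = 0) -> dict:
    """Sensitivity of criteria 1–3 and the contamination filter's hit rates."""
    exp = simulate_experiment(SimulationConfig(seed=seed))
    norm, _ = _normalized(exp)
    reg = tuple(ma for ma in norm if ma.design == DESIGN_CCCJ_VS_AACJ)
    dep = tuple(ma for ma in norm if ma.design == DESIGN_CC_VS_CCCJ)
    regulated = select_regulated(reg, dep)

    truth = exp.truth
    t_up = set(truth.genes_with_label(LABEL_ASTRO_UP))
    t_down = set(truth.genes_with_label(LABEL_ASTRO_DOWN))
    t_neuron = set(truth.genes_with_label(LABEL_NEURON))

    # criteria 1-3 calls, before the contamination filter
    stats = [compute_thresholds(ma) for ma in reg]
    joint = intersect_replicates(*(select_by_threshold(ma, st)
                                   for ma, st in zip(reg, stats)))
    genes13 = collapse_probes(joint)
    up13 = set(genes13.genes(DIR_UP))
    down13 = set(genes13.genes("down"))

    removed = set(regulated.removed_contamination["gene_id"])
    neuron_up13 = up13 & t_neuron
    return {
        "sensitivity_up": len(up13 & t_up) / len(t_up),
        "sensitivity_down": len(down13 & t_down) / len(t_down),
        "neuron_filter_rate": (len(removed & neuron_up13) / len(neuron_up13)
                               if neuron_up13 else float("nan")),
        "astro_up_false_removal_rate": (len(removed & up13 & t_up)
                                        / len(up13 & t_up) if up13 & t_up
                                        else float("nan")),
        "n_up": len(regulated.up_genes),
        "n_down": len(regulated.down_genes),
        "n_neuron_up_before_filter": len(neuron_up13),
    }


def normalization_flatness(seed: int = 0) -> float:
    """Worst per-A-decile mean M over truth-null genes after normalization."""
    exp = simulate_experiment(SimulationConfig(seed=seed))
    norm, _ = _normalized(exp)
    null_genes = set(exp.truth.gene_ids[exp.truth.labels == LABEL_NULL])
    worst = 0.0
    for ma in norm:
        null_ma = MASet(array_id=ma.array_id, design=ma.design,
                        table=ma.table[ma.table["gene_id"].isin(null_genes)])
        worst = max(worst, float(decile_means(null_ma)["mean_M"].abs().max()))
    return worst


def null_call_rate(seed: int = 0, n_probes: int = 20_000) -> dict:
    """Fraction of probes called by mean ± 2·SD under a pure-null simulation.

    Under Gaussian M noise the two 2.3% tails give ≈ 4.55% expected calls;
    the binomial 3σ band at `n_probes` quantifies the allowed fluctuation.
    """
    cfg = SimulationConfig(n_genes=n_probes // 2, frac_neuron_enriched=0.0,
                           frac_astro_up=0.0, frac_astro_down=0.0,
                           contamination_c=0.0, dye_bias_coeffs=(0.0,),
                           seed=seed)
    exp = simulate_experiment(cfg)
    ma = ma_transform(exp.scans[0])
    calls = select_by_threshold(ma, compute_thresholds(ma))
    n = len(calls.table)
    rate = len(calls.called) / n
    from scipy.stats import norm as normal

    expected = 2.0 * normal.sf(2.0)
    sigma = np.sqrt(expected * (1 - expected) / n)
    return {"rate": rate, "expected": expected, "sigma": float(sigma),
            "n_probes": n}
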