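"""Normalize the arrays and select neuron-responsive astrocyte genes.

Runs the four-criterion selection: per-array mean ± 2·SD calling, replicate
agreement, probe consistency, and the contamination filter that removes
up-candidates strongly depleted by the cold jet (residual neuronal RNA).
"""

import coldjet
from coldjet.arrays import ma_transform

exp = coldjet.simulate_experiment(seed=42)
normalized = []
for scan in exp.scans:
    ma = ma_transform(scan)
    norm, _ = coldjet.normalize_array(ma)
    normalized.append(norm)
normalized = coldjet.scale_m_values(normalized)

reg = tuple(ma for ma in normalized if ma.design == coldjet.DESIGN_CCCJ_VS_AACJ)
dep = tuple(ma for ma in normalized if ma.design == coldjet.DESIGN_CC_VS_CCCJ)
regulated = coldjet.select_regulated(reg, dep)

p = regulated.provenance
print(f"probes called on each replicate array: {p['n_probes_called_each']}")
print(f"concordant on both replicates:        {p['n_probes_concordant']}")
print(f"up before contamination filter:       {p['n_up_before_contamination_filter']}")
print(f"removed as residual neuronal RNA:     {p['n_up_removed_contamination']}")
print(f"final regulated genes: {p['n_up']} up, {p['n_down']} down")

top = coldjet.rank_top(regulated.up, 5)
print("\nstrongest upregulated genes (log2 scale):")
print(top.to_string(index=False))

# Truth audit: how many calls are real?
truth = exp.truth
t_up = set(truth.genes_with_label("astro_up"))
print(f"\n{len(set(regulated.up_genes) & t_up)} of {p['n_up']} up calls are "
      f"true astro_up genes ({len(t_up)} simulated)")
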