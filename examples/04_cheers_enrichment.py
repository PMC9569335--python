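"""Cell-state enrichment of risk variants at specific H3K27ac peaks.

Simulates a peak-by-cell-state signal matrix where 5% of peaks are boosted
in each state, plants 50 risk variants so that 80% land in peaks specific
to one target state, and tests every state's mean specificity rank of the
overlapped peaks against the discrete-uniform null.  Only the target state
should survive Bonferroni correction.
"""

from epienrich.cheers import cheers_test, specificity_scores
from epienrich.synthetic import (
    SimulationConfig,
    plant_risk_variants,
    simulate_peak_matrix,
)

TARGET = "state_3"
cfg = SimulationConfig(seed=4, n_peaks=5000, n_cell_states=6,
                       specificity_fraction=0.05,
                       planted_enrichment_pi=0.8, n_lead_variants=50)
pm = simulate_peak_matrix(cfg)
psm = specificity_scores(pm)   # quantile norm, bottom decile dropped
leads = plant_risk_variants(pm, TARGET, cfg)

results, overlaps = cheers_test(psm, leads)
print(f"planted target state: {TARGET} "
      f"(pi = {cfg.planted_enrichment_pi}, {cfg.n_lead_variants} leads)")
print(f"peaks overlapped by variants: {overlaps['peak_id'].nunique()}")
print()
print(results.round(4).to_string(index=False))
print()
print("mean_rank is the mean normalized specificity rank of overlapped")
print("peaks; under no enrichment it sits near 0.5.  The planted state")
print("should be the only one with Bonferroni-significant p.")
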