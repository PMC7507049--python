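"""Race-model analysis of simulated audio-visual reaction times.

Generates a behavioral dataset whose AV responses are 12% faster than the
race of fresh unimodal draws, then tests the empirical AV distribution
against Miller's bound P_A + P_V - P_A * P_V in 10-ms bins.
"""

from avconn import filter_rts, race_difference_curves, summarize_race
from avconn.synthetic import RTGenSpec, generate_rt_dataset

spec = RTGenSpec(coactivation_gain=0.12, seed=42)
table = filter_rts(generate_rt_dataset(spec, n_subjects_per_group=15))

for group in ("elderly", "younger"):
    grid, curves, subjects = race_difference_curves(table, group=group, intensity="high")
    res = summarize_race(curves, grid)
    print(f"{group} (n={len(subjects)}):")
    print(f"  integration window(s) : {res.windows_ms} ms")
    print(f"  peak benefit          : {res.peak_benefit:.3f}")
    print(f"  peak latency          : {res.peak_latency_group_ms:.0f} ms")
    print(f"  positive AUC          : {res.auc:.2f}")

print(
    "\nThe windows are the bins where the AV CDF significantly exceeds the\n"
    "race bound (two-tailed t, p <= .05, positive mean): evidence that the\n"
    "two senses were integrated rather than raced.  Peak benefit is the\n"
    "largest mean exceedance, its latency the time it occurs, and the AUC\n"
    "(bin-sum of positive exceedance) an overall integration-magnitude index."
)
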