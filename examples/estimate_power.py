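"""Compare the power of MGC against global distance correlations.

Estimates Monte-Carlo power (500 replicates) on the 1-D spiral at n=100
for MGC, Dcorr, and Mcorr, sharing the simulated datasets across methods.
"""

from mgcorr import SimulationSpec, estimate_power_multi

spec = SimulationSpec(type_id=8, n=100, p=1, kappa=1)
estimates = estimate_power_multi(["mgc", "dcorr", "mcorr"], spec,
                                 alpha=0.05, r=500, seed=11)

print(f"power at alpha=0.05, spiral, n=100 (500 MC replicates):")
for method, est in estimates.items():
    print(f"  {method:6s}: {est.power:.3f}  (critical value {est.critical_value:.4f})")
print()
print("Power is the fraction of dependent draws whose statistic exceeds the")
print("95th percentile of the statistic under independence. MGC's local scans")
print("detect the spiral far more often than the global statistics.")
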