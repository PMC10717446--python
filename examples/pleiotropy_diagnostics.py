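"""Detect and correct for pleiotropy: MR-Egger, SIMEX, weighted median.

Two scenarios on synthetic data with true causal log-OR 0.2:

A. Every instrument carries a small directional pleiotropic effect
   (mean 0.01 per exposure-increasing allele).  IVW is badly biased;
   the Egger intercept estimates the planted mean and the Egger/SIMEX
   slope moves back toward the truth.

B. 30% of instruments are invalid with a large direct effect (0.05),
   the rest are valid.  The weighted median, which tolerates up to half
   the weight coming from invalid SNPs, stays near the truth while IVW
   is dragged away.
"""

from cannamr import (
    SimulationConfig,
    egger_simex,
    harmonize_pair,
    i2_gx,
    ivw_fixed,
    mr_egger,
    select_instruments,
    simulate_two_sample,
    wald_ratios,
    weighted_median,
)


def analysis_panel(**kwargs):
    pair = simulate_two_sample(SimulationConfig(**kwargs))
    instruments, _ = harmonize_pair(pair.exposure_stats, pair.outcome_stats)
    return select_instruments(instruments, 5e-5)


print("A. directional pleiotropy on every instrument (mean 0.01)")
panel = analysis_panel(seed=21, theta=0.2, pleiotropy_mean=0.01, pleiotropy_sd=0.003)
ivw = ivw_fixed(wald_ratios(panel))
egger = mr_egger(panel, n_boot=10_000, seed=1)
simex = egger_simex(panel, seed=2, n_boot=100)
print(f"   {len(panel)} SNPs, I2_GX {i2_gx(panel):.1f}% (NOME near-satisfied when ~100%)")
for est in (ivw, egger, simex):
    print(f"   {est.method:12s} theta {est.theta:+.3f} (se {est.se:.3f})")
print(
    f"   egger intercept {egger.intercept:+.4f} (se {egger.intercept_se:.4f}, "
    f"p={egger.intercept_p:.2g}) -> estimates the planted 0.01"
)

print("\nB. 30% invalid instruments with large direct effects (0.05)")
panel = analysis_panel(seed=41, theta=0.2, pleiotropy_mean=0.05, invalid_fraction=0.3)
ivw = ivw_fixed(wald_ratios(panel))
wm = weighted_median(wald_ratios(panel), n_boot=10_000, seed=3)
print(f"   ivw          theta {ivw.theta:+.3f} (se {ivw.se:.3f})  <- pulled off 0.2")
print(f"   wtd median   theta {wm.theta:+.3f} (se {wm.se:.3f})  <- anchored by the valid 70%")
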