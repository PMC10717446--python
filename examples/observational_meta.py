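"""Pool observational study estimates and test funnel asymmetry.

Simulates 12 studies (6 CAD, 6 ischemic stroke) reporting ORs for
ever-use of cannabis with substantial between-study heterogeneity, pools
them with DerSimonian-Laird random effects, and runs the Egger-type
funnel-asymmetry regression plus a leave-one-out influence check.
"""

from cannamr import dl_meta, egger_funnel_test, leave_one_out, simulate_observational_studies

cad = simulate_observational_studies(
    6, true_log_or=0.2, tau2=0.16, se_range=(0.05, 0.15), seed=1, outcome_group="CAD"
)
stroke = simulate_observational_studies(
    6, true_log_or=0.2, tau2=0.16, se_range=(0.05, 0.15), seed=2, outcome_group="IS"
)
studies = cad + stroke

pooled = dl_meta(studies)
lo, hi = pooled.or_ci
print(
    f"pooled OR {pooled.odds_ratio:.2f} (95% CI {lo:.2f}-{hi:.2f}), "
    f"I2 {pooled.i2:.1f}%, tau2 {pooled.tau2:.3f}, p={pooled.pvalue:.3g}"
)

funnel = egger_funnel_test(studies)
print(
    f"funnel asymmetry {funnel.coefficient:.2f} "
    f"(95% CI {funnel.ci_low:.2f} to {funnel.ci_high:.2f}, p={funnel.pvalue:.2f})"
)

print("\nleave-one-out pooled ORs (stability under removal of each study):")
for label, est in leave_one_out(studies):
    print(f"  without {label:9s} OR {est.odds_ratio:.2f}")
print(
    "\nhigh I2 means most variation is between studies, so the random-effects "
    "CI is wide; a funnel coefficient compatible with 0 argues against "
    "small-study (publication) bias."
)
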