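"""Group-wise disease-free-survival analysis.

One-vs-rest Cox proportional-hazards fits conditioned on the full
clinico-pathological covariate set, plus Kaplan-Meier 5-year survival per
group.  The generator's default plants a hazard ratio of 1.59 on group 3
and 1.99 on stage III, so group 3 should be the only group flagged.
"""

import crcmolclass as cm

cohort = cm.simulate_cohort(cm.GeneratorConfig(n=906, seed=7))
fits = cm.group_survival_analysis(cohort, mode="one_vs_rest")

print(f"{'group':8s} {'HR':>5s} {'95% CI':>13s} {'p':>8s}")
for name, fit in fits.items():
    if isinstance(fit, str):
        print(f"{name:8s} {fit}")
        continue
    lo, hi = fit.ci(name)
    p = float(fit.terms.loc[name, 'p'])
    print(f"{name:8s} {fit.hr(name):5.2f} {lo:6.2f}-{hi:5.2f} {p:8.3f}")

df = cohort.df
ok = df["group"].notna() & (df["group"] != "unclassifiable")
curves = cm.km_estimate(df.loc[ok, "dfs_years"], df.loc[ok, "dfs_event"],
                        df.loc[ok, "group"])
print("\n5-year Kaplan-Meier disease-free survival:")
for g in sorted(curves):
    print(f"  group {g}: {curves[g].at(5.0):.2f}")
print("\ngroup 3 should show HR near 1.59 with p < 0.05 and the lowest")
print("5-year survival; all other groups should be indistinguishable.")
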