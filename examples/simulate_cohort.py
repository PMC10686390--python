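"""Generate a synthetic longitudinal cohort and inspect its calibration.

Simulates a small version of the default study (fewer eyes for speed),
extracts the per-stimulus record table through registration and ROI
quantification, and prints the cohort summaries the generator is
calibrated to reproduce at full scale: ~73% of stimuli over drusen, ~2%
over hyperreflective foci, baseline mean sensitivity ~25.7 dB.
"""

import mpsf

cfg = mpsf.CohortConfig(n_patients=12, n_eyes=18, n_visits=5)
bundle = mpsf.simulate_cohort(cfg, 123)
table = mpsf.extract_cohort_table(bundle)

print(f"{cfg.n_eyes} eyes of {cfg.n_patients} patients, "
      f"{cfg.n_visits} visits -> {len(table)} stimulus records")
base = table[table["visit"] == 0]
print(f"baseline stimuli over drusen : {100 * base['drusen_present'].mean():.1f}%")
print(f"baseline stimuli over HRF    : {100 * base['hrf_present'].mean():.2f}%")
print(f"baseline mean sensitivity    : {base['sensitivity_db'].mean():.2f} dB")

growth = table.groupby("visit")["drusen_vol_e3mm3"].mean()
print("\nmean drusen volume per stimulus by visit (x10^-3 mm^3):")
for visit, vol in growth.items():
    print(f"  visit {visit}: {vol:.3f}")
print("\nLesions grow quarterly while sensitivity also carries a +0.242")
print("dB/visit learning effect; both are generative ground truth.")
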