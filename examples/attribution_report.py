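"""Split each patient's infiltrate volume into dose-attributable and
dose-independent parts, and compare with the generator's ground truth.

Uses the stratified (oracle) phantom mode, where the generated data realize
the generative expectations exactly, so the recovered attributable fraction
can be checked against the known truth.
"""

from dataclasses import replace

import numpy as np

import pneumovox as pv

base = pv.PhantomParams(stratified_sampling=True, dose_independent_fraction=0.4)
cohort = [pv.generate_patient(replace(base, seed=40 + i), f"P{i}", 3) for i in range(6)]
table = pv.concat_observations([pv.compute_observations(c) for c, _ in cohort])

fit = pv.fit_mixed(table)
report = pv.attributable_fraction(fit, table)

print(report.per_patient.round(1))
truth = 100 * np.mean([t.true_attributable_fraction for _, t in cohort])
print(f"\ncohort mean attributable fraction: {report.cohort['mean_pct']:.1f}% "
      f"(generator truth {truth:.1f}%)")
print(f"dose-independent partial infiltrate volume per dose bin: "
      f"{100 * report.dose_independent_pv:.1f}% +/- {100 * report.dose_independent_se:.1f}%")
# 'Attributable' is the fixed dose effect accumulated over dose bins and
# density strata, relative to the [0,5) Gy reference; the rest of the
# infiltrate is the dose-independent component present across all dose bins.
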