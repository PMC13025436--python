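"""Fit the weighted mixed dose-response model on a six-patient cohort.

The model regresses the partial infiltrate volume per (dose step, density
bin) cell on 5 Gy dose-bin and 50 HU density-bin classification effects,
with an independent random intercept for every (patient, dose bin, density
bin) cell and weights proportional to the lung volume each cell represents.
"""

import numpy as np

import pneumovox as pv

cohort = pv.generate_cohort(n_high=6, n_low=0, seed=1)
table = pv.concat_observations([pv.compute_observations(c) for c, _ in cohort])

fit = pv.fit_mixed(table)
dose, dens = fit.tests["dose"], fit.tests["density"]
print(f"dose effect    : F({dose['ndf']}, {dose['ddf']:.0f}) = {dose['F']:.1f}, "
      f"p = {dose['p']:.2e}")
print(f"density effect : F({dens['ndf']}, {dens['ddf']:.0f}) = {dens['F']:.1f}, "
      f"p = {dens['p']:.2e}")
print(f"monotone dose profile: {fit.monotone_alpha}")
print("fitted dose effects alpha_d (per density stratum, vs [0,5) Gy):")
print("  " + "  ".join(f"{a:.4f}" for a in fit.alpha))
print(f"variance components: sigma2_u = {fit.sigma2_u:.2e}, "
      f"sigma2_e = {fit.sigma2_e:.2e}")

forms = pv.compare_dose_forms(table)
print("\nAIC by dose form (ML fits; lower is better):")
print(forms["aic"].round(1).to_string())
# A significant, monotone dose effect with a clearly worse constant-dose fit
# reproduces the qualitative finding that part of the infiltrate burden
# follows radiation dose while the density profile acts additively.
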