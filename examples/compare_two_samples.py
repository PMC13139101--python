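"""Compare two samples with all four effect-size indices and their 95% CIs.

Group 1 is standard normal; group 2 is skew-normal with mean 2, SD 5 and heavy
right skew — a caricature of a clinical score with floor effects in controls
and a long right tail in patients. The mean-based indices (d and its
transforms) and the distribution-based kernel overlap tell different stories.
"""

import numpy as np

import ovlsim as ov

spec2 = ov.sn_params_from_moments(ov.TargetMoments(mu=2, sigma=5, alpha=10))
y1 = ov.sn_sample(300, ov.SkewNormalSpec(0, 1, 0), seed=1)
y2 = ov.sn_sample(300, spec2, seed=2)

est = ov.estimate_all(y1, y2)
ci_d = ov.ci_d_noncentral(y1, y2)
ci_cles = ov.ci_transform_monotone(ci_d, "cles")
ci_etap = ov.ci_transform_monotone(ci_d, "eta_p")
ci_eta = ov.ci_eta_bootstrap(y1, y2, ov.BootConfig(n_boot=1000, seed=3))

print(f"Cohen's d            : {est.d:7.3f}  [{ci_d.lower:6.3f}, {ci_d.upper:6.3f}]")
print(f"CLES (from d)        : {est.cles:7.3f}  [{ci_cles.lower:6.3f}, {ci_cles.upper:6.3f}]")
print(f"parametric overlap   : {est.eta_p:7.3f}  [{ci_etap.lower:6.3f}, {ci_etap.upper:6.3f}]")
print(f"nonparametric overlap: {est.eta:7.3f}  [{ci_eta.lower:6.3f}, {ci_eta.upper:6.3f}]")
print(f"empirical CLES       : {ov.cles_empirical(y1, y2):7.3f}")

cond = ov.Condition(2, 5, 10, 300)
tv = ov.true_values(cond)
print(f"\npopulation targets   : d={tv.theta_d:.3f}  CLES={tv.theta_cles:.3f}  "
      f"overlap={tv.theta_overlap:.3f}")
print("d sees a modest standardized shift (the 5:1 SD ratio dilutes the mean "
      "difference);\nthe parametric overlap, trusting normal equal-variance "
      "theory, overstates the shared\nmass relative to the kernel estimate, "
      "which tracks the true overlap.")
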