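"""Print the true effect-size targets for the eight population contrasts.

Each contrast pits a standard normal against a skew-normal with prescribed
mean difference (delta), SD (sigma) and slant (alpha). theta_d is the
population standardized mean difference, theta_cles the folded probability of
superiority, theta_overlap the integral of the pointwise minimum of the two
densities — the estimand shared by both overlap estimators.
"""

import pandas as pd

import ovlsim as ov

rows = []
for delta in (0.0, 2.0):
    for sigma in (1.0, 5.0):
        for alpha in (0.0, 10.0):
            tv = ov.true_values(ov.Condition(delta, sigma, alpha, 10))
            rows.append(dict(delta=delta, sigma=sigma, alpha=alpha,
                             theta_d=tv.theta_d, theta_cles=tv.theta_cles,
                             theta_overlap=tv.theta_overlap))

print(pd.DataFrame(rows).to_string(index=False, float_format=lambda v: f"{v:8.4f}"))
print("\nNote how at delta=0, sigma=5 the means agree yet two thirds of the "
      "probability mass\ndoes not overlap — a difference invisible to theta_d.")
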