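"""Direct Bayes factor estimation beats the ratio of marginal likelihoods.

A Bayes factor can be estimated either by one stepping-stone path
connecting the two models directly, or by two independent prior-to-
posterior paths (one marginal likelihood per model) whose difference is
taken afterwards.  When both models share their prior, the direct path
evaluates both powered kernels in the same parameter draws; their
positive covariance cancels shared noise, so the direct estimator has
lower variance.
"""

import numpy as np

from modelswitch.toybench import variance_comparison_experiment

result = variance_comparison_experiment(
    n_replicates=100, rng=np.random.default_rng(1)
)

print(f"analytic log BF                   : {result['analytic_log_bf']:+.4f}")
print(f"direct-path mean / variance       : {result['direct_mean']:+.4f} / "
      f"{result['direct_variance']:.5f}")
print(f"ratio-of-marginals mean / variance: {result['ratio_mean']:+.4f} / "
      f"{result['ratio_variance']:.5f}")
print(f"estimated covariance term         : {result['mean_covariance_term']:+.5f}")
print()
print("The empirical variance of the direct estimator is far below that of")
print("the difference of two independent marginal-likelihood estimates;")
print("the positive covariance term is exactly the cancelled shared noise.")
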