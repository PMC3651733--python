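"""Compare sigmoid shape values for the power-posterior schedule.

At both ends of a model-switch path one model is raised to a vanishing
power, so the integrand changes fastest near beta = 0 and beta = 1.  A
sigmoid grid concentrates steps near the endpoints; larger shape values
alpha concentrate harder.  This sweep runs the standard toy pair at
several alpha values and reports the bidirectional error of each
estimator — the shape with the lowest BDE wastes the least effort.
"""

import numpy as np

from modelswitch import estimators as est
from modelswitch.mcmc import run_path
from modelswitch.schedules import sigmoid_schedule
from modelswitch.toybench import (
    ToySwitchProblem,
    analytic_log_bf,
    default_beta_binomial_pair,
)

spec0, spec1 = default_beta_binomial_pair()
problem = ToySwitchProblem(spec0, spec1)
analytic = analytic_log_bf(spec0, spec1)
print(f"analytic log BF: {analytic:+.4f}\n")
print("alpha   first increments           SS bidir   BDE(SS)")

for alpha in (2.0, 6.0, 10.0, 13.0):
    rng = np.random.default_rng(42)
    sched = sigmoid_schedule(K=40, Q=100, alpha=alpha, n_splits=4)
    tr_a = run_path(problem, sched, mode="ss", rng=rng, save_interval=5)
    tr_m = run_path(problem, sched.reversed(), mode="ss", rng=rng, save_interval=5)
    ss = est.bidirectional_summary(
        est.ss_log_bf(tr_a, sched), est.ss_log_bf(tr_m, sched)
    )
    head = ", ".join(f"{d:.4f}" for d in np.diff(sched.betas)[:3])
    print(f"{alpha:5.1f}   [{head}, ...]   {ss.log_bf:+.4f}   {ss.bidirectional_error:.4f}")

print()
print("Small alpha is nearly a constant grid; large alpha spends most")
print("steps near the endpoints where the prior-dominated kernels change")
print("fastest.  On hard problems shapes around 9-12 give the lowest BDE.")
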