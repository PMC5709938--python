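"""Fit one simulated dataset with FOCE-I and with the Bayesian sampler.

Simulates a single 6-subject dataset at 30% IIV and estimates the
population parameters with both estimator families, starting from the true
values, then prints estimates next to the truth.
"""

import numpy as np

import popsse as p

truth = p.base_truth(30.0)
ds = p.simulate_dataset(
    p.base_design(), truth, replicate_id=0,
    rng=np.random.default_rng(2024), iiv_level=30.0,
)

foce = p.fit_foce(ds, truth)
bayes, chain = p.fit_bayes(
    ds, truth, p.MCMCSettings(n_burn_max=2000, n_stationary=5000, seed=7)
)

names = ["Ka (1/h)", "Vd/F (L)", "CL/F (L/h)"]
print(f"{'parameter':<12}{'truth':>10}{'FOCE-I':>10}{'BAYES':>10}")
for k, nm in enumerate(names):
    print(f"{nm:<12}{truth.theta[k]:>10.3f}{foce.theta_hat[k]:>10.3f}{bayes.theta_hat[k]:>10.3f}")
for key, label, tv in (("v_f", "omega2_V", truth.omega2_v),
                       ("cl_f", "omega2_CL", truth.omega2_cl)):
    print(f"{label:<12}{tv:>10.4f}"
          f"{foce.omega2_hat[key]:>10.4f}{bayes.omega2_hat[key]:>10.4f}")
print(f"{'sigma2':<12}{truth.sigma2:>10.4f}{foce.sigma2_hat:>10.4f}{bayes.sigma2_hat:>10.4f}")

print(f"\nFOCE-I: OFV={foce.ofv:.2f}, minimization success={foce.minimization_success}, "
      f"covariance step={foce.covariance_success}")
print(f"BAYES: burn-in used={chain.burn_in_used} iterations "
      f"(converged={chain.converged_burn_in}), "
      f"acceptance rates eta={chain.acceptance_rates['eta']:.2f} "
      f"theta={chain.acceptance_rates['theta']:.2f}")
print("\nA single 6-subject replicate carries sizable sampling noise, so point")
print("estimates can sit 10-20% from the truth; systematic bias and precision")
print("statements need the replicated SSE sweep (see run_sse_sweep.py).")
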