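"""A scaled-down simulate-then-refit (SSE) sweep with all four methods.

Five replicates at two IIV levels, fit by FOCE-I, BAYES(C), BAYES(F) and
BAYES (reduced chains), then summarized as rRMSE and median REE per
parameter, method and level — the table behind the method-comparison plots.
"""

import popsse as p

design = p.base_design(n_replicates=5, iiv_levels=(10.0, 50.0))
cfg = p.SSEConfig(
    design=design,
    truth=p.base_truth(),
    mcmc_settings=p.MCMCSettings(n_burn_max=500, n_stationary=1000),
    master_seed=42,
)
table = p.run_sse(cfg)
print(f"SSE table: {len(table)} rows "
      f"(2 levels x 5 replicates x 4 methods x 5 parameters)")

metrics = p.summarize(table)
fixed = metrics[metrics["parameter"] == "cl_f"]
print("\nCL/F rRMSE by method and IIV level (lower is better):")
print(fixed.pivot(index="iiv_level", columns="method", values="rrmse").round(3).to_string())

iiv = metrics[metrics["parameter"] == "omega2_cl"]
print("\nomega2_CL median REE (%) by method and IIV level (bias):")
print(iiv.pivot(index="iiv_level", columns="method", values="median_ree").round(1).to_string())

print("\nSuccess-rate bookkeeping per method and level:")
print(p.success_rates(table).to_string(index=False))
print("\nAt 10% IIV the methods track each other; at 50% the Bayesian variants'")
print("posterior means drift above the truth (positive REE) while FOCE-I stays closer.")
print("(5 replicates is a smoke run - use >=30 for stable metric estimates.)")
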