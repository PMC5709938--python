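"""Case study: SSE with a theophylline-derived population model.

The truth is re-parameterized from a published theophylline population fit
(CL/F=2.88 L/h, Vd/F=33.01 L, Ka=1.46 1/h; IIV 25.69%/13.48%/65.39% on
CL/F, Vd/F, Ka) — note this model, unlike the base simulation model, also
carries a random effect on Ka.  A reduced smoke run with FOCE-I only.
"""

import popsse as p

truth = p.theo_truth()
print("case-study truth:")
print(f"  CL/F={truth.cl_f} L/h (IIV {p.omega2_to_cv(truth.omega2_cl):.2f}% CV)")
print(f"  Vd/F={truth.v_f} L   (IIV {p.omega2_to_cv(truth.omega2_v):.2f}% CV)")
print(f"  Ka={truth.ka} 1/h    (IIV {p.omega2_to_cv(truth.omega2_ka):.2f}% CV)")

table = p.run_case_study(n_replicates=5, methods=("FOCE-I",), master_seed=9)
print(f"\nSSE table rows: {len(table)} (5 replicates x 1 method x 6 parameters)")

metrics = p.summarize(table)
print("\nper-parameter recovery (median REE %, rRMSE):")
print(
    metrics[["parameter", "median_ree", "rrmse", "n_used"]]
    .round(3)
    .to_string(index=False)
)
print("\nKa and its IIV are the hard targets here (sparse absorption-phase")
print("information at 65% IIV); CL/F and Vd/F recover much more tightly.")
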