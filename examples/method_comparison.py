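"""Small Monte Carlo comparison of LS, LAD and RSR (takes ~2 minutes).

Runs 15 paired replicates of the contaminated base case (rho = 0.8,
all-positive outliers at p = 0.2) and prints median parameter estimates
and the two bias indicators: long-term (asymptotic recruitment R0) and
short-term (next-year recruitment R_{T+1}) relative bias.
"""

from rsrfit import run_experiment

summary = run_experiment(["S0_rho0.8_positive"],
                         methods=["ls", "lad", "rsr"], n_rep=15, seed=2)

rec = summary.records
print("truth: a=1.2, b=500, rho=0.8; medians over 15 replicates\n")
cols = ["a", "b", "rho", "r0_bias", "rnext_bias"]
med = rec.groupby("method")[cols].median().round(3)
print(med.to_string())
print("\nr0_bias > 0 means the method overestimates long-term maximum "
      "recruitment (LS's typical failure under positive outliers); RSR "
      "retains far more of the residual autocorrelation than LS or LAD, "
      "which is what preserves short-term forecast skill.")
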