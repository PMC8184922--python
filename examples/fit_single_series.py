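"""Fit one contaminated spawner-recruitment series with LS and RSR.

Simulates a 30-year hockey-stick dataset with strong residual
autocorrelation (rho = 0.8) and all-positive gross outliers, then fits
the conventional Gaussian AR(1) estimator (LS) and the robust RSR
estimator with phi chosen by retrospective forecasting. The printed
comparison shows the usual failure mode of LS on one-sided outliers —
an inflated slope a and a collapsed autocorrelation estimate — and how
the down-weighted likelihood avoids both.
"""

import numpy as np

from rsrfit import fit_ls, fit_rsr, generate_replicate, get_scenario, select_phi

cfg = get_scenario("S0_rho0.8_positive")   # truth: a=1.2, b=500, rho=0.8
rep = generate_replicate(cfg, seed=7)
series = rep.series

ls = fit_ls(series)
sel = select_phi(series)
rsr = fit_rsr(series, sel.best_phi)

print(f"truth: a={cfg.a}, b={cfg.b}, rho={cfg.rho}, "
      f"{int(rep.outlier_flags.sum())} outlier years out of {cfg.T}")
print(f"selected phi = {sel.best_phi:.3f} (log phi = "
      f"{np.log(sel.best_phi):+.1f}), RF error = {sel.best_error:.4f}")
print(f"{'':>6} {'a':>7} {'b':>7} {'rho':>6} {'sigma':>6}")
for fit in (ls, rsr):
    print(f"{fit.method:>6} {fit.curve.a:7.3f} {fit.curve.b:7.1f} "
          f"{fit.rho:6.3f} {fit.sigma:6.3f}")
print("\nmin weight year:", int(series.year[np.argmin(rsr.lam)]),
      f"(lambda = {rsr.lam.min():.3g})",
      "-> flagged outlier:" , bool(rep.outlier_flags[np.argmin(rsr.lam)]))
print("A small lambda marks a year the model treats as contaminated; "
      "LS has no such safeguard, so its a and rho absorb the outliers.")
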