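"""Fit the heteroscedastic age model to every connection.

Per connection, MAP estimation of mean-level (alpha_mu, beta_mu),
log-SD-level (alpha_sigma, beta_sigma) and motion (rho) parameters with
weakly informative normal priors.  beta_mu is the per-year change in
mean Fisher-z FC; exp(beta_sigma) is the yearly multiplicative change
in its between-person SD.  Also fits the nodal GMD model.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, run_config

from fcaging.workbench import run_pipeline

run_pipeline(run_config(), stages=["fit-age"])

fits = pd.read_csv(SCRATCH / "fits_fc.tsv", sep="\t")
ok = fits["converged"] & fits["identifiable"]
frac_neg = (fits.loc[ok, "beta_mu"] < 0).mean()
frac_pos = (fits.loc[ok, "beta_sigma"] > 0).mean()

summary = pd.DataFrame(
    {
        "n_connections": [len(fits)],
        "n_converged": [int(ok.sum())],
        "pct_beta_mu_negative": [round(100 * frac_neg, 1)],
        "pct_beta_sigma_positive": [round(100 * frac_pos, 1)],
        "median_abs_beta_mu": [fits.loc[ok, "beta_mu"].abs().median()],
        "median_abs_beta_sigma": [fits.loc[ok, "beta_sigma"].abs().median()],
    }
)
summary.to_csv(RESULTS / "age_fit_summary.tsv", sep="\t", index=False)
fits.nlargest(20, "beta_mu", keep="all").to_csv(
    RESULTS / "top_edges_beta_mu.tsv", sep="\t", index=False
)

print(summary.to_string(index=False))
print(f"\nmean FC declines with age in {frac_neg:.1%} of connections; "
      f"between-person FC variance grows in {frac_pos:.1%}")
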