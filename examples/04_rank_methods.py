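"""Compare deconvolution methods across datasets with Friedman-Nemenyi.

Given a table of per-dataset RMSE values (methods x datasets), the Friedman
test ranks the methods within each dataset (rank 1 = lowest RMSE) and tests
whether the mean ranks differ more than chance would allow; the Nemenyi
critical difference then flags which pairs are significantly separated at
alpha = 0.05.  The toy table below has a consistently best and a
consistently worst method.
"""

import pandas as pd

import simplesig as ss

rmse_table = pd.DataFrame(
    {
        "dataset1": [0.012, 0.034, 0.055, 0.031],
        "dataset2": [0.015, 0.041, 0.062, 0.038],
        "dataset3": [0.011, 0.029, 0.058, 0.035],
        "dataset4": [0.018, 0.036, 0.049, 0.040],
        "dataset5": [0.013, 0.032, 0.051, 0.036],
        "dataset6": [0.010, 0.030, 0.060, 0.033],
    },
    index=["one_cpg", "ten_cpg", "naive", "full_panel"],
)

res = ss.friedman_nemenyi(rmse_table, lower_is_better=True)
print("mean ranks (1 = best):")
print(res.mean_ranks.round(2).to_string())
print(f"\nFriedman chi2 = {res.friedman_statistic:.2f}, "
      f"p = {res.friedman_pvalue:.4f}")
print(f"Nemenyi critical difference = {res.critical_difference:.2f}")
pairs = [
    (a, b)
    for i, a in enumerate(res.significant.index)
    for b in res.significant.columns[i + 1:]
    if res.significant.loc[a, b]
]
print("significantly different pairs:", pairs or "none")
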