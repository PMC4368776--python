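"""Choose the model size d by repeated cross-validation.

For each candidate d, samples are split into 10 folds; the full selection
pipeline (screening, penalty choice, OLS refit) runs inside each training
fold, and the held-out predictions are scored by their Pearson correlation
with the observed responses.  The d maximising that correlation wins
(ties go to the smaller, more parsimonious model).
"""

from disis import generate_synthetic, select_d, sigma_for_r2

X, y, truth = generate_synthetic(
    n=300, p=500, s_strong=3, rho=0.5, sigma=sigma_for_r2(3, 0.8), seed=7
)
sel = select_d(X, y, grid=[2, 4, 8, 12], seed=7, n_repeats=2, n_folds=10)
print("CV correlation by candidate model size d:")
for d in sel.grid:
    marker = "  <- chosen" if d == sel.chosen_d else ""
    print(f"  d={d:2d}: PCC = {sel.pcc_by_d[d]:.3f}{marker}")
print(f"\ntrue support size is {len(truth.support)}; the curve should peak near it")
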