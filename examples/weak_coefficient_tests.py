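"""Significance tests for selected coefficients, flagging the weak ones.

After the final OLS refit, each coefficient gets a two-sided t-test of
H0: beta_j = 0 at alpha = 0.01.  Features that are *marginally weak*
(|Pearson r with the response| < 0.1) yet significant in the joint model
are the interesting class: a correlation screen would have discarded them.
"""

from disis import (
    coef_t_tests,
    generate_synthetic,
    isis_select,
    sigma_for_r2,
    weak_but_significant,
)

X, y, truth = generate_synthetic(
    n=400, p=1000, s_strong=3, rho=0.5, sigma=sigma_for_r2(3, 0.8), seed=11
)
model = isis_select(X, y, d=8, seed=11)
tests = coef_t_tests(model.ols, model.marginal_r, model.feature_ids)

print(f"{'feature':12s} {'coef':>7s} {'t':>8s} {'p':>10s} {'marg r':>7s}  flags")
for t in tests:
    flags = []
    if t.weak_marginal:
        flags.append("weak-marginal")
    if t.significant:
        flags.append("significant")
    print(
        f"{t.feature_id:12s} {t.coef:7.3f} {t.t_statistic:8.2f} "
        f"{t.p_value:10.2e} {t.marginal_r:7.3f}  {', '.join(flags)}"
    )

ws = weak_but_significant(tests)
print(f"\nweak-but-significant features: {[t.feature_id for t in ws]}")
print(f"planted weak feature:          {X.feature_ids[truth.weak_feature]}")
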