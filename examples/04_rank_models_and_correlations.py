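"""Follow-up questions within the 21 test dyads and per-bat statistics.

Did grooming *during* forced proximity predict the later change?  Rank
linear models with one-sided permutation p-values from shuffling the
forced-phase rates within each cage; Spearman correlations of phase rates;
the shift in the proportion of grooming aimed at unfamiliar partners; and
the familiar-vs-unfamiliar trade-off correlation.
"""

from bondperm import (
    SimConfig,
    generate_colony,
    phase_correlations,
    proportion_unfamiliar_shift,
    rank_lm_change,
    rank_lm_post,
    tradeoff_correlation,
)

colony = generate_colony(SimConfig(seed=1))

change_model = rank_lm_change(colony, n_perm=5000, seed=20)
post_model = rank_lm_post(colony, n_perm=5000, seed=21)
print("rank(change) ~ rank(forced):")
print(f"  beta = {change_model.estimate:+.3f}, permutation p = {change_model.p_value:.3f}, "
      f"parametric p = {change_model.parametric_p:.3f}")
print("rank(post) ~ rank(pre) + rank(forced)  [forced coefficient]:")
print(f"  beta = {post_model.estimate:+.3f}, permutation p = {post_model.p_value:.3f}, "
      f"parametric p = {post_model.parametric_p:.3f}")

rho = phase_correlations(colony)
print("\nSpearman correlations of forced-phase rates:")
for key, r in rho.items():
    print(f"  {key:22s} rho = {r.estimate:+.3f}, p = {r.p_value:.3g}")

prop = proportion_unfamiliar_shift(colony, n_boot=5000, seed=22)
print(f"\nmean shift in proportion of grooming to unfamiliar partners: "
      f"{prop.estimate:+.3f}  95% CI [{prop.ci_low:+.3f}, {prop.ci_high:+.3f}]")

trade = tradeoff_correlation(colony, n_boot=5000, seed=23)
print(f"familiar-vs-unfamiliar change correlation: r = {trade.estimate:+.3f} "
      f"[{trade.ci_low:+.3f}, {trade.ci_high:+.3f}], p = {trade.p_value:.3f}")
print()
print("A clearly negative r would mean new relationships were paid for by")
print("withdrawing grooming from familiar partners; a value near zero does not.")
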