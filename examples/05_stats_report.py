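"""The inferential layer: chi-square pattern counts, ANOVA power, KL
divergence between representatives, Spearman correlations."""

import numpy as np

from gazehmm import (
    PowerSpec, anova_sample_size, inflate_sample_size, chisq_gof,
    kl_divergence_mc, make_archetypes, spearman,
)

# 1. How many children does an 8-group ANOVA need (f = 0.25, power 0.90)?
n_min = anova_sample_size(PowerSpec(effect_size_f=0.25, n_groups=8,
                                    alpha=0.05, target_power=0.90))
n_target = inflate_sample_size(n_min, loss_rate=0.15, inclusion_rate=0.50)
print(f"minimum N for the ANOVA: {n_min}; "
      f"recruitment target after 15% attrition at 50% inclusion: {n_target}")

# 2. Do more children show one pattern than the other?
chi2, df, p = chisq_gof([199, 131])
print(f"pattern-count chi-square: chi2({df}) = {chi2:.2f}, p = {p:.2g}")

# 3. Are the two representative gaze models actually different?
holistic, analytic = make_archetypes()
res = kl_divergence_mc(holistic.hmm, analytic.hmm, n_sequences=500,
                       seq_length=20, rng=np.random.default_rng(0))
print(f"KL(holistic || analytic) = {res.d:.1f} nats/sequence "
      f"(t({res.df}) = {res.t_statistic:.1f}, p = {res.p_value:.2g})")

# 4. Does the gaze pattern track a cognitive score?
rng = np.random.default_rng(1)
ha = rng.uniform(-0.3, 0.3, 40)
score = 95 - 40 * ha + rng.normal(0, 8, 40)
rho, p = spearman(ha, score)
print(f"Spearman rho(H-A, score) = {rho:.3f}, p = {p:.3g}")
# A large positive KL with a significant paired t confirms the two
# representatives describe genuinely different viewing behavior; the
# negative rho mirrors the built-in score-pattern relationship.
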