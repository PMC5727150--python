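"""Test whether two binary traits evolved dependently on a phylogeny.

Fits the 4-rate independent and 8-rate dependent Markov models by ML and
by MCMC (exponential priors, mean 10), estimates each model's marginal
likelihood by stepping-stone sampling, and reports the Bayes factor
BF = 2 (logZ_dep - logZ_ind) with the conventional evidence bands
(<2 weak, 2-5 positive, 5-10 strong, >10 very strong).
"""

from cooccurevo import MCMCConfig, pagel_test
from cooccurevo.synthetic import (
    DEFAULT_DEPENDENT_RATES,
    simulate_traits,
    simulate_tree,
)

tree = simulate_tree(n_taxa=80, birth_rate=1.0, seed=5)
traits = simulate_traits(tree, DEFAULT_DEPENDENT_RATES, "dependent",
                         root_state=(0, 0), seed=6)
print(f"tip state counts: {traits.joint_counts()}")

res = pagel_test(tree, traits,
                 MCMCConfig(chain_length=600, burn_in=200, n_stones=8, seed=1))

print(f"logL (ML): independent {res.logl_ml_ind:.2f}, "
      f"dependent {res.logl_ml_dep:.2f}")
print(f"LRT = {res.lrt_stat:.2f} (chi2 df=4, p = {res.lrt_p:.2g})")
print(f"logZ: independent {res.logz_ind:.2f} +- {res.logz_ind_se:.2f}, "
      f"dependent {res.logz_dep:.2f} +- {res.logz_dep_se:.2f}")
print(f"Bayes factor = {res.bf:.2f} -> {res.bf_band} evidence for "
      f"correlated evolution")
# Data were generated under a mutual-avoidance regime, so the dependent
# model should win decisively (BF well above 2).
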