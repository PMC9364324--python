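"""Relate differences between nanomaterials to their nanodescriptors.

Builds a synthetic log k matrix (nanomaterials x compounds) in which one
nanodescriptor ('a', H-bond acidity weight) genuinely drives the between-
material differences while the others are noise.  The matrix is min-
shifted to non-negative values, converted to Bray-Curtis dissimilarities,
and each nanodescriptor's marginal contribution is tested by dbRDA with
permutation F-tests.  A Kruskal-Wallis/Dunn-Holm comparison of two
material classes and a Spearman correlation close the loop.
"""

import numpy as np
import pandas as pd

from nanosorb import bray_curtis, dbrda_marginal, kruskal_dunn, min_shift, spearman

rng = np.random.default_rng(5)
n_enm, n_compounds = 19, 40

nano = pd.DataFrame(
    rng.normal(size=(n_enm, 5)), columns=["r_e", "p_s", "a", "b", "v"],
    index=[f"enm_{i:02d}" for i in range(n_enm)],
)
# log k driven by nanodescriptor 'a' plus compound-level noise
signal = np.outer(nano["a"], np.linspace(0.5, 2.0, n_compounds))
logk = pd.DataFrame(
    1.5 + signal + rng.normal(0, 0.3, size=(n_enm, n_compounds)), index=nano.index
)

dissim = bray_curtis(min_shift(logk))
results = dbrda_marginal(dissim, nano, n_perm=999, seed=0)
print("dbRDA marginal tests (999 permutations):")
for r in results:
    print(f"  {r.predictor:<4s} F_{r.df_num},{r.df_den} = {r.F:6.2f}   p = {r.p_value:.3f}")
print("Only the planted driver should reach the permutation floor p = 0.001.\n")

groups = np.array(["metal"] * 13 + ["carbon"] * 6)
values = logk.mean(axis=1).to_numpy() + np.where(groups == "carbon", 1.0, 0.0)
(H, p_kw), pairs = kruskal_dunn(values, groups)
print(f"Kruskal-Wallis on mean log k by material class: H = {H:.2f}, p = {p_kw:.3f}")
print(pairs.round(3).to_string(index=False))

rho, p_s = spearman(nano["a"], logk.mean(axis=1))
print(f"\nSpearman rho(nanodescriptor a, mean log k) = {rho:.2f} (p = {p_s:.2g})")
print("A large rho confirms the H-bond acidity weight drives mean affinity here.")
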