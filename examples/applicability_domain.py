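"""Assess where log k predictions can be trusted.

Builds a compound set plus a small probe reference set, then applies the
three applicability-domain constructions: the Insubria rule in its three
modes (hat + prediction band, hat only, none), the Williams rule on
model-fitted data, and the NMDS-centroid distance rule.  The in-domain
counts are nested across the Insubria modes by construction -- adding
thresholds can only shrink the domain.
"""

import numpy as np

from nanosorb import (
    GeneratorConfig,
    critical_hat,
    gen_abraham_compounds,
    insubria_filter,
    leverages,
    ordination_centroid_ad,
    williams_flags,
)
from nanosorb.applicability import loo_standardized_residuals

# correlated descriptors: real chemical space is far from isotropic, and
# a 2-D ordination is only meaningful when a few directions dominate
compounds = gen_abraham_compounds(GeneratorConfig(n=120, seed=3, correlation=0.8))
probes = gen_abraham_compounds(GeneratorConfig(n=23, seed=99, correlation=0.8))

# leverages of the query compounds against the probe design space
X_probe = np.column_stack([np.ones(len(probes)), probes.to_numpy()])
XtXi = np.linalg.inv(X_probe.T @ X_probe)
Xq = np.column_stack([np.ones(len(compounds)), compounds.to_numpy()])
h_query = np.sum((Xq @ XtXi) * Xq, axis=1)

h_star = critical_hat(n_descriptors=5, n_reference=len(probes))
print(f"critical hat h* = 3(N+1)/n = {h_star:.2f}  (N=5, n={len(probes)})\n")

rng = np.random.default_rng(1)
pred = rng.normal(3.0, 2.0, len(compounds))
probe_pred = rng.normal(3.0, 1.0, len(probes))

for mode in ("both_thresholds", "hat_only", "none"):
    report = insubria_filter(h_query, pred, h_star, probe_pred, mode=mode)
    print(f"Insubria mode {mode:<16s}: {report.n_in:3d}/{len(compounds)} in domain")

# Williams plot on model-fitted synthetic data
X = np.column_stack([np.ones(60), rng.normal(size=(60, 5))])
y = X @ rng.normal(size=6) + rng.normal(size=60)
res = loo_standardized_residuals(X, y)
flags = williams_flags(res, leverages(X), critical_hat(5, 60))
print(f"\nWilliams rule: {flags.sum()}/60 training compounds in domain")

# ordination-centroid rule
all_pts = np.vstack([probes.to_numpy(), compounds.to_numpy()])
flags_c, _, stress = ordination_centroid_ad(all_pts, probe_idx=range(23), seed=0)
print(f"NMDS-centroid rule (stress {stress:.3f}): "
      f"{flags_c[23:].sum()}/{len(compounds)} query compounds in domain")
print("\nLooser thresholds admit more compounds but extrapolate further from")
print("the chemical space the models were trained on.")
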