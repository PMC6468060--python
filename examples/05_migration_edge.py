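"""Migration-edge allele-frequency covariance model.

Fits the fixed-topology drift model ((SFL, MIA), WCU) with one weighted
migration edge WCU -> MIA to data simulated with a known admixture pulse,
and compares the bifurcating-tree fit: the edge weight estimates the
donor ancestry fraction, the likelihood-ratio test asks whether the edge
is needed, and variance explained summarises model fit.
"""

from anole_admix import DemographicModel, PopulationMap, simulate_dataset
from anole_admix.migration_graph import (allele_frequencies,
                                         covariance_entry_sd,
                                         covariance_matrix, fit_graph,
                                         likelihood_ratio_test,
                                         variance_explained)

samples = PopulationMap(["SFL", "MIA", "WCU"],
                        {"SFL": 100, "MIA": 100, "WCU": 100})
model = DemographicModel(5000, 5000, 5000, t_admix=200, r_admix=0.33,
                         t_split=1.0e7, mu=1e-4)
ds = simulate_dataset(model, samples, n_loci=100, rng=3)

freq = allele_frequencies(ds.genotypes)
cov = covariance_matrix(freq)
esd = covariance_entry_sd(freq)
with_edge = fit_graph(cov, allow_migration=True, seed=0, error_sd=esd)
tree_only = fit_graph(cov, allow_migration=False, seed=0, error_sd=esd)
stat, p = likelihood_ratio_test(tree_only, with_edge)

print(f"True donor ancestry fraction: {model.r_admix}")
print(f"Fitted migration weight w   : {with_edge.w:.3f}")
print(f"LRT for the migration edge  : stat {stat:.1f}, p = {p:.2g}")
print(f"Variance explained          : migration {variance_explained(with_edge, cov):.1%}, "
      f"tree only {variance_explained(tree_only, cov):.1%}")
print("\nA weight near the true fraction, a small p-value and a clear "
      "variance-explained gap indicate the hybrid population's ancestry "
      "cannot be explained by a strictly bifurcating tree.")
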