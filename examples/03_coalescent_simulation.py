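"""The divergence-plus-pulse-admixture coalescent simulator.

Simulates the three-population scenario — parental split long ago, hybrid
population founded by a single admixture pulse — and shows that the
fraction of hybrid maternal lineages tracing to the donor side is an
unbiased estimate of the admixture rate.
"""

import numpy as np

from anole_admix import DemographicModel, PopulationMap, simulate_dataset

model = DemographicModel(n_sfl=4980, n_mia=4410, n_wcu=8570,
                         t_admix=887, r_admix=0.24, t_split=1.03e7)
samples = PopulationMap(["SFL", "MIA", "WCU"],
                        {"SFL": 32, "MIA": 92, "WCU": 54})

fracs = []
for seed in range(50):
    ds = simulate_dataset(model, samples, n_loci=18, rng=seed)
    fracs.append(ds.donor_mtdna_fraction())
print(f"Admixture rate R_A = {model.r_admix}")
print(f"Donor-origin mtDNA fraction over 50 replicate studies: "
      f"mean {np.mean(fracs):.3f}, sd {np.std(fracs, ddof=1):.3f}")
print("Single replicates vary widely (few maternal founders survive the "
      "887 generations since the pulse) but the mean matches R_A.")
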