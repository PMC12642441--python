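"""Connectivity gradients: hierarchy recovery and flattening.

Embeds a noiseless 1-D hierarchy correlation matrix (sparsify 90% -> cosine
affinity -> diffusion map) and shows that a synthetic dataset generated with
gradient_compression = 0.5 halves the recovered principal-gradient range in
meditation states relative to controls.
"""

import numpy as np
from scipy.stats import spearmanr

from medstates import simulate as sim
from medstates.gradients import (ParcelSeries, cosine_affinity,
                                 diffusion_map_embed, functional_connectivity,
                                 gradient_dispersion, sparsify)
from medstates.io import STATES

R = sim.population_hierarchy_correlation(60)
g = diffusion_map_embed(cosine_affinity(sparsify(R, 0.90)), n_components=10)
rho = spearmanr(g.g1, np.linspace(-1, 1, 60)).statistic
print(f"G1 vs latent hierarchy coordinate: Spearman rho = {rho:.3f} "
      "(the principal gradient orders parcels along the planted hierarchy)")

spec = sim.SimulationSpec(n_participants=6, t_per_segment=240, seed=5,
                          gradient_compression={s: 0.5 for s in STATES})
series, _, truth = sim.generate_gradient_dataset(spec)
fc = {k: functional_connectivity(ParcelSeries(v)) for k, v in series.items()}


def cond_range(conds):
    mats = [m for (p, c), m in fc.items() if c in conds]
    emb = diffusion_map_embed(
        cosine_affinity(sparsify(np.mean(mats, 0), 0.90)), 10)
    return gradient_dispersion(emb, 1)[0]


ratio = cond_range(STATES) / cond_range(("counting", "memory"))
print(f"state/control G1 range ratio = {ratio:.3f} "
      "(planted compression 0.5: the hierarchy is flattened by half)")
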