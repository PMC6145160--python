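"""Small-world index of an OMST-filtered brain graph.

Compares the graph's clustering and path length with the means of 300
degree-preserving rewired null networks:

    gamma = C/C_rand,  lambda = L/L_rand,  sigma = gamma/lambda > 1

indicates small-world organization (clustering above random at near-
random path length).
"""

from eegsmallworld import (SimulationConfig, generate_cohort, omst_filter,
                           small_world_index)
from eegsmallworld.pipeline import subject_band_connectivity

cfg = SimulationConfig(n_per_group=1, seed=3)
control, patient = generate_cohort(cfg)

for rec in (control, patient):
    m = subject_band_connectivity(rec, bands=cfg.bands, band_names=["theta"])["theta"]
    g = omst_filter(m)
    res = small_world_index(g, n_nulls=300, seed=1)
    print(f"{rec.group:8s} C={res.C_real:.3f} L={res.L_real:.3f} "
          f"C_rand={res.C_random_mean:.3f} L_rand={res.L_random_mean:.3f} "
          f"gamma={res.gamma:.2f} lambda={res.lam:.2f} sigma={res.sigma:.2f}")

# Both groups come out with sigma > 1 (small-world organization is
# preserved); the group difference shows up in the path length L, not
# in sigma — matching the qualitative pattern this analysis probes.
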