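"""Normalized mutual-information connectivity for one subject.

Preprocesses a recording (0.5-30 Hz bandpass, 10-s epochs, average
reference, per-band filters) and computes the 24 x 24 normalized-MI
matrix in the theta band, then shows that coupled channel pairs carry
more shared information than uncoupled pairs.
"""

import numpy as np

from eegsmallworld import SimulationConfig, channel_coupling_adjacency, generate_cohort
from eegsmallworld.pipeline import subject_band_connectivity

cfg = SimulationConfig(n_per_group=1, seed=3)
control, patient = generate_cohort(cfg)

m = subject_band_connectivity(control, bands=cfg.bands, band_names=["theta"])["theta"]
print(f"theta connectivity matrix: {m.values.shape}, averaged over "
      f"{m.n_epochs_averaged} epochs")

coupled = channel_coupling_adjacency(cfg.source_clusters,
                                     cfg.coupling_graph_control["theta"],
                                     cfg.n_channels).astype(bool)
off_diag = ~np.eye(cfg.n_channels, dtype=bool)
print(f"mean normalized MI, coupled pairs:   {m.values[coupled].mean():.4f}")
uncoupled = off_diag & ~coupled
if uncoupled.any():
    print(f"mean normalized MI, uncoupled pairs: {m.values[uncoupled].mean():.4f}")
else:
    print("(all channel pairs coupled in the control configuration)")

# Values sit well above 0 even for independent pairs: the 100-bin
# histogram estimator is positively biased at 2500 samples per epoch.
# The analysis relies on the *ranking* of pair strengths, which the
# bias (common to all pairs) does not disturb.
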