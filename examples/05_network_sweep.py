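"""Recurrent 150-cell network and the Rett-style parameter sweep.

Cells (Izhikevich fast-spiking reference backend) are coupled with
Tsodyks-Markram synapses at 10% unidirectional / 5% reciprocal
connectivity; a 50-nS stimulus at 100 ms probes the population response.
The sweep scans recurrent excitation scale and connection probability and
scores instability (pre-stimulus APs) and immediate response.
"""

import numpy as np

from surroneuron.network import IzhikevichBackend, NetworkConfig, run_network, run_rett_sweep
from surroneuron.network.engine import sweep_frame

config = NetworkConfig(n_cells=150, duration_ms=250.0, seed=0)
result = run_network(config, IzhikevichBackend(150))
print(f"single run: {len(result.raster)} spikes, "
      f"instability {result.pre_stimulus_count()}, "
      f"immediate response {result.immediate_response()}/150 cells")

results = run_rett_sweep(
    [0.75, 1.0, 1.25], [0.052, 0.10],
    lambda c: IzhikevichBackend(c.n_cells), repeats=2, seed=1,
)
df = sweep_frame(results)
print("\nmean instability by (excitation scale, connectivity):")
print(df.groupby(["excitation_scale", "p_uni"])["instability"].mean().unstack())
# Instability grows with recurrent excitation and falls at the reduced
# (Rett-like) connection probability.
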