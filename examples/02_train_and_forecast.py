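"""Train the linear surrogate on a passive corpus and forecast in closed loop.

Generates a small passive corpus, builds normalized 64-ms windows, trains
the 2.07e4-parameter linear architecture with Nesterov-accelerated Adam and
early stopping, then runs continuous self-reliant predictions on held-out
event trains and scores them by explained variance.
"""

import numpy as np

from surroneuron.experiments import linear_passive_experiment

report = linear_passive_experiment(seed=0, n_traces=4, n_runs=10)
print(f"trained for {report.history_rows} epochs "
      f"({report.model.n_params} free parameters)")
print(f"closed-loop explained variance over {len(report.evs)} x 500 ms: "
      f"mean {report.mean_ev_percent:.2f}% "
      f"(range {100*report.evs.min():.1f}-{100*report.evs.max():.1f}%)")
# ~98-99% means the rollout tracks the ground-truth membrane potential
# almost perfectly for half a second while only seeing the event schedule.
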