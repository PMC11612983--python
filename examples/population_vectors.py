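"""Population-vector correlation between the two running directions.

Simulates one 60-cell session twice: once with mostly bidirectional cells
(both directions share one spatial code) and once with mostly
unidirectional cells (the two directional codes are near-orthogonal).
For each, the per-cell profiles are smoothed (6 cm Gaussian), peak
normalised, stacked into population vectors per spatial bin, and the
rightward bin vectors are Pearson-correlated with the leftward ones. The
peak of the offset-averaged diagonal bands summarises how similar the two
directional codes are.
"""

from dataclasses import replace

import numpy as np

import placecode1d as pc
from placecode1d.pipeline import population_analysis
from placecode1d.synthetic import make_cell_specs, simulate_session

for label, uc_fraction in [("80% bidirectional", 0.2), ("20% bidirectional", 0.8)]:
    spec = pc.CohortSpec(n_cells=60, p_overlap=1.0, kappa_range=(0.0, 0.2), seed=8)
    params = replace(
        pc.DEFAULT_SESSION_PARAMS[("control", "novel")],
        uc_fraction=uc_fraction, gamma_per_lap=0.0,
    )
    rng = np.random.default_rng([8, int(uc_fraction * 10)])
    cells = make_cell_specs(60, params, spec, rng)
    session = simulate_session("demo", "control", "novel", cells, params, spec, rng)
    pv = population_analysis(pc.analyze_session(session))
    print(f"{label}: cross-direction PV score = {pv['score']:.3f} "
          f"at offset {pv['offset']} bins")

print(
    "\nA score near 1 means the population expresses one direction-independent"
    "\nspatial code; a low score means the two directions are stored as"
    "\nnear-orthogonal activity patterns (more unidirectional cells)."
)
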