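"""Overlap index and directional classification on constructed profiles.

Three textbook cells: one firing identically in both running directions,
one with direction-specific but spatially overlapping fields, and one
firing in a single direction only. Shows how the overlap index (computed
after area normalisation of each profile) separates them and how the
1.2 Hz peak criterion and the 0.4 overlap threshold assign classes.
"""

import numpy as np

import placecode1d as pc

grid = pc.make_grid(170.0, 3.0)
cfg = pc.AnalysisConfig()


def field(center_cm, peak_hz, sigma_cm=8.0):
    return peak_hz * np.exp(-((grid.centers - center_cm) ** 2) / (2 * sigma_cm**2))


cells = {
    "direction-blind": (field(80, 4.0), field(80, 4.0)),
    "shifted fields": (field(60, 4.0), field(100, 3.0)),
    "one direction only": (field(80, 4.0), field(80, 0.6)),
}

for name, (right, left) in cells.items():
    cls = pc.classify_cell(right, left, cfg, grid, unit_id=name)
    oi = f"{cls.oi:.3f}" if np.isfinite(cls.oi) else "undefined"
    print(f"{name:20s} OI = {oi:>9s}  class = {cls.label:4s} ({cls.reason})")

print(
    "\nOI = 1 marks identical directional profiles; disjoint fields give 0."
    "\nBoth peaks >= 1.2 Hz makes a cell bidirectional (OBC above OI 0.4,"
    "\nNOBC below); a single supra-threshold peak makes it unidirectional."
)
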