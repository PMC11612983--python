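"""Bootstrap and ANOVA comparison of place-field size between groups.

Simulates the novel-environment sessions of a two-group cohort (5 animals
x 30 cells per group) in which the transgenic group's fields are generated
~1.6x wider, then tests the difference the way unequal cell counts demand:
the transgenic per-cell field sizes are resampled 10000 times and compared
against the fixed control mean. The p-value is the fraction of resample
means that fall on the null-consistent side (strict counting, so complete
separation reports p = 0; the (k+1)/(n+1) estimate is shown alongside).
"""

import numpy as np

import placecode1d as pc

spec = pc.CohortSpec(seed=1)
sessions, _ = pc.simulate_cohort(spec, environments=("novel",))
metrics, _ = pc.analyze_cohort(sessions)

ctrl = metrics.loc[metrics.group == "control", "pfs_cm"].dropna().to_numpy()
tg = metrics.loc[metrics.group == "transgenic", "pfs_cm"].dropna().to_numpy()

print(f"control:    n = {ctrl.size:3d} cells, mean PFs = {ctrl.mean():5.1f} cm "
      f"+- {ctrl.std(ddof=1) / np.sqrt(ctrl.size):.1f} (SEM)")
print(f"transgenic: n = {tg.size:3d} cells, mean PFs = {tg.mean():5.1f} cm "
      f"+- {tg.std(ddof=1) / np.sqrt(tg.size):.1f} (SEM)")

boot = pc.bootstrap_between(tg, float(ctrl.mean()), n_resamples=10000,
                            direction="smaller", seed=1)
print(f"\nbootstrap (10000 resamples of the transgenic cells):")
print(f"  resample means below the control mean: {boot.exceedance}")
print(f"  p (raw proportion) = {boot.p}, corrected = {boot.p_corrected:.2e}")
print(
    "\nA p near 0 means essentially no resampled transgenic mean falls back"
    "\nto the control level: the field-size difference is not a cell-count"
    "\nartifact."
)
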