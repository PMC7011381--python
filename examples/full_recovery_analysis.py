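"""Full disturbance-recovery analysis on a reduced factorial preset.

Simulates control and constant-exposure gut communities through exposure
(T0, T3) and recovery (TR2, T5), runs the complete pipeline and prints the
neutrality summary plus the distance-to-control recovery trajectory.
"""

import warnings

from recoverymics.pipeline import AnalysisConfig, recovery_trajectory, run_full_analysis
from recoverymics.synthetic_data import ExperimentDesign, perch_recovery_preset

design = ExperimentDesign(
    treatments=("Ctrl", "CC"), habitats=("gut",), tanks=8,
    timepoints=("T0", "T3", "TR2", "T5"), replicates=3,
)
res = perch_recovery_preset(seed=11, design=design, S=150, N_local=500, depth=2000)

cfg = AnalysisConfig(n_perm=199, seed=11)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_full_analysis(cfg, counts=res.counts, metadata=res.metadata, tree=res.tree)

print("neutral-model summary (percent of OTUs inside the 95% neutral band):")
cols = ["habitat", "treatment", "timepoint", "n_otus", "pct_neutral", "m", "r2"]
print(report.ncm_summary[cols].round(3).to_string(index=False))
print()
print("recovery trajectory (mean GUniFrac distance to control):")
traj = recovery_trajectory(report, "gut")
print(traj.round(4).to_string(index=False))
print()
print(
    "Selection during exposure depresses the treated %neutral and pushes\n"
    "the community away from control; after the stressor is removed the\n"
    "distance falls back toward the within-control baseline and the\n"
    "terminal PERMANOVA contrast decides the recovered flag."
)
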