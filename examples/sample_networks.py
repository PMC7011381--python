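"""Sample correlation network and centrality contrast under disturbance.

Builds the Spearman sample-sample network for control and treated gut
communities at the end of exposure and compares betweenness centrality:
a coherent control community yields connected modules with intermediary
samples, while a disturbed one fragments.
"""

import warnings

from recoverymics.diversity import alpha_diversity
from recoverymics.networks import (
    build_network,
    centrality_shift_summary,
    spearman_matrix,
)
from recoverymics.synthetic_data import ExperimentDesign, perch_recovery_preset

design = ExperimentDesign(
    treatments=("Ctrl", "CC"), habitats=("gut",), tanks=8,
    timepoints=("T3",), replicates=3,
)
res = perch_recovery_preset(seed=3, design=design, S=150, N_local=500, depth=2000)
meta = res.metadata.set_index("sample_id")

nets = {}
for trt in ("Ctrl", "CC"):
    ids = meta.index[meta["treatment"] == trt].tolist()
    sub = res.counts.select_samples(ids)
    rho, p = spearman_matrix(sub)
    attrs = alpha_diversity(sub)[["richness"]].join(meta.loc[ids])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nets[(trt, "T3")] = build_network(rho, p, rho_min=0.3, fdr_alpha=0.05, node_attrs=attrs)

summary = centrality_shift_summary(nets)
print(summary.to_string(index=False))
print()
print(
    "Each row is one (treatment, time) network of samples; edges join\n"
    "samples whose OTU profiles are rank-correlated (|rho| >= 0.3, BH-FDR\n"
    "5%). A homogeneous group forms a near-complete graph (betweenness ~ 0\n"
    "everywhere); selection reorganizes the treated network, dropping edges\n"
    "and shifting the centrality distribution away from the control's —\n"
    "the contrast the rank-sum p in the last column quantifies."
)
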